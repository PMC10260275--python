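"""Preprocessing: zero-phase FIR filtering, linked-mastoid re-referencing,
30-s epoching and artifact-based epoch exclusion.

The broadband filter reproduces the EEGLAB-style Hamming-windowed sinc design:
−6 dB at the stated cutoff frequencies, applied with group-delay compensation
(odd symmetric kernel convolved in 'same' mode), so the output is zero phase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .io_psg import ArtifactSet, ChannelError, Hypnogram, Recording

logger = logging.getLogger(__name__)

__all__ = [
    "EpochMask",
    "bandpass_zero_phase",
    "design_bandpass",
    "rereference_mastoids",
    "build_epoch_mask",
    "included_minutes",
    "preprocess_recording",
]

#: Hamming-window FIR design rule: transition width ≈ 3.3 / N (normalized)
_HAMMING_TW = 3.3

NREM_STAGES = frozenset({"N2", "N3"})


def design_bandpass(rate: float, low: float, high: float,
                    transition: tuple[float, float] | None = None) -> np.ndarray:
    """Design an odd-length Hamming-windowed sinc band-pass FIR.

    ``low``/``high`` are the −6 dB cutoff frequencies (firwin places the
    half-amplitude point at the cutoff).  The kernel length follows the
    standard Hamming rule from the narrower transition band; for the
    published broadband setting (0.2–35 Hz, −6 dB at 0.1 and 35.1 Hz) the
    transition width is 0.2 Hz on both sides.
    """
    nyq = rate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"band ({low}, {high}) outside (0, {nyq})")
    if transition is None:
        # default: 2×(cutoff − band edge) symmetric transitions of 0.2·low width
        tw = min(low * 2.0, (nyq - high) * 2.0, high - low)
    else:
        tw = min(transition)
    numtaps = int(np.ceil(_HAMMING_TW * rate / tw))
    if numtaps % 2 == 0:
        numtaps += 1
    taps = sp_signal.firwin(numtaps, [low, high], window="hamming",
                            pass_zero=False, fs=rate)
    logger.debug("designed band-pass %g-%g Hz, order %d", low, high, numtaps - 1)
    return taps


def _apply_zero_phase(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Convolve with a symmetric FIR, compensating group delay (same length)."""
    if len(taps) % 2 != 1:
        raise ValueError("zero-phase application requires an odd-length kernel")
    return sp_signal.fftconvolve(x, taps, mode="same")


def bandpass_zero_phase(x: np.ndarray, rate: float, low: float, high: float,
                        transition: tuple[float, float] | None = None) -> np.ndarray:
    """Zero-phase band-pass; −6 dB at ``low`` and ``high``; same length out."""
    taps = design_bandpass(rate, low, high, transition)
    if len(x) < len(taps):
        logger.warning("signal (%d) shorter than filter (%d); edge effects dominate",
                       len(x), len(taps))
    return _apply_zero_phase(np.asarray(x, dtype=float), taps)


def lowpass_zero_phase(x: np.ndarray, rate: float, cutoff: float,
                       transition: float | None = None) -> np.ndarray:
    """Zero-phase low-pass (−6 dB at ``cutoff``)."""
    nyq = rate / 2.0
    if not 0 < cutoff < nyq:
        raise ValueError(f"cutoff {cutoff} outside (0, {nyq})")
    tw = transition if transition is not None else cutoff
    numtaps = int(np.ceil(_HAMMING_TW * rate / tw))
    if numtaps % 2 == 0:
        numtaps += 1
    taps = sp_signal.firwin(numtaps, cutoff, window="hamming", fs=rate)
    return _apply_zero_phase(np.asarray(x, dtype=float), taps)


def rereference_mastoids(recording: Recording) -> Recording:
    """Re-reference every channel to the average of A1 and A2.

    The mastoids themselves are left untouched (re-referencing them would
    zero their mean signal and make the operation non-idempotent).
    """
    for m in ("A1", "A2"):
        if not recording.has_channel(m):
            raise ChannelError(m)
    a_mean = (recording.get("A1") + recording.get("A2")) / 2.0
    mast_idx = {recording.channel_index("A1"), recording.channel_index("A2")}
    data = recording.data.copy()
    for i in range(data.shape[0]):
        if i not in mast_idx:
            data[i] -= a_mean
    return Recording(
        channel_labels=list(recording.channel_labels),
        sampling_rate=recording.sampling_rate,
        data=data,
        start_time=recording.start_time,
    )


@dataclass
class EpochMask:
    """Per-epoch inclusion flags plus within-epoch artifact sub-intervals."""

    included: np.ndarray            # bool per epoch
    stages: list[str]
    epoch_length: float
    artifact_subintervals: list[list[tuple[float, float]]] = field(default_factory=list)
    impedance_fail: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.included = np.asarray(self.included, dtype=bool)
        if len(self.included) != len(self.stages):
            raise ValueError("flags must align 1:1 with hypnogram epochs")

    @property
    def n_epochs(self) -> int:
        return len(self.included)

    def sample_mask(self, rate: float, n_samples: int,
                    exclude_artifacts: bool = True) -> np.ndarray:
        """Boolean per-sample mask of included time (artifact samples off)."""
        mask = np.zeros(n_samples, dtype=bool)
        spe = int(round(self.epoch_length * rate))
        for i, inc in enumerate(self.included):
            if not inc:
                continue
            a, b = i * spe, min((i + 1) * spe, n_samples)
            mask[a:b] = True
            if exclude_artifacts:
                for s, e in self.artifact_subintervals[i]:
                    mask[max(0, int(round(s * rate))): min(n_samples, int(round(e * rate)))] = False
        return mask

    def excluded_time_contains(self, start_s: float, end_s: float) -> bool:
        """True if [start_s, end_s) touches excluded epochs or artifact time."""
        i0 = int(np.floor(start_s / self.epoch_length))
        i1 = int(np.ceil(end_s / self.epoch_length))
        for i in range(max(i0, 0), min(i1, self.n_epochs)):
            if not self.included[i]:
                return True
            for s, e in self.artifact_subintervals[i]:
                if s < end_s and start_s < e:
                    return True
        if i1 > self.n_epochs:  # beyond scored time
            return True
        return False


def build_epoch_mask(hypnogram: Hypnogram, artifacts: ArtifactSet,
                     stages_wanted: set[str] | frozenset[str] = NREM_STAGES,
                     artifact_cutoff_s: float = 8.0,
                     artifact_rule: str = "sum",
                     impedance_fail: np.ndarray | None = None) -> EpochMask:
    """Mark epochs for analysis.

    An epoch is included iff its stage is wanted, the artifact overlap does
    not exceed ``artifact_cutoff_s`` (summed by default; longest single
    interval with ``artifact_rule='single'``), and its impedance flag (an
    optional per-epoch boolean, default all-pass) is clear.  For included
    epochs the artifact sub-intervals are retained for event-level exclusion.
    """
    merged = artifacts.merged()
    included = np.zeros(len(hypnogram), dtype=bool)
    subints: list[list[tuple[float, float]]] = []
    for i, stage in enumerate(hypnogram.stages):
        e0, e1 = hypnogram.epoch_bounds(i)
        clipped = [(max(s, e0), min(e, e1)) for s, e in merged if s < e1 and e > e0]
        if artifact_rule == "single":
            overlap = max((e - s for s, e in clipped), default=0.0)
        else:
            overlap = sum(e - s for s, e in clipped)
        ok = stage in stages_wanted and overlap <= artifact_cutoff_s
        if ok and impedance_fail is not None and impedance_fail[i]:
            ok = False
            logger.info("epoch %d excluded: impedance flag", i)
        if stage in stages_wanted and overlap > artifact_cutoff_s:
            logger.info("epoch %d (%s) excluded: %.1f s artifact > %.1f s cutoff",
                        i, stage, overlap, artifact_cutoff_s)
        included[i] = ok
        subints.append(clipped if ok else [])
    return EpochMask(included=included, stages=list(hypnogram.stages),
                     epoch_length=hypnogram.epoch_length,
                     artifact_subintervals=subints,
                     impedance_fail=impedance_fail)


def included_minutes(mask: EpochMask, artifact_corrected: bool = False) -> float:
    """Minutes of included time (0.5 min per included 30-s epoch).

    With ``artifact_corrected=True``, within-epoch artifact time is
    subtracted from the denominator.
    """
    total_s = float(mask.included.sum()) * mask.epoch_length
    if artifact_corrected:
        for i, inc in enumerate(mask.included):
            if inc:
                total_s -= sum(e - s for s, e in mask.artifact_subintervals[i])
    return total_s / 60.0


def preprocess_recording(recording: Recording, low: float = 0.1, high: float = 35.1,
                         transition: tuple[float, float] = (0.2, 0.2)) -> Recording:
    """Broadband zero-phase filter + linked-mastoid re-reference (all channels).

    ``low``/``high`` are the −6 dB cutoffs: 0.1 and 35.1 Hz for the nominal
    0.2–35 Hz passband (firwin places the half-amplitude point at the cutoff).
    """
    taps = design_bandpass(recording.sampling_rate, low, high, transition)
    data = np.vstack([_apply_zero_phase(ch, taps) for ch in recording.data])
    filtered = Recording(channel_labels=list(recording.channel_labels),
                         sampling_rate=recording.sampling_rate, data=data,
                         start_time=recording.start_time)
    return rereference_mastoids(filtered)
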