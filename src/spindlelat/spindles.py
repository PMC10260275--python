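"""Fast sleep-spindle detection by channel-wise amplitude thresholding.

The detector follows the Ferrarelli-style scheme: the signal is band-pass
filtered to the fast-spindle band (13–16 Hz), rectified, and events are
defined against two channel-wise thresholds derived from the mean rectified
amplitude over included NREM time — an upper (detection) threshold of 5× the
mean and a lower (extent) threshold of 2× the mean.  Event geometry (onset,
offset, flank and gap rules) is evaluated on the envelope of the rectified
trace, i.e. the linear interpolation across its half-wave peaks, since the
rectified trace itself returns to zero every half cycle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .io_psg import AnalysisConfig
from .preprocess import EpochMask, _apply_zero_phase

logger = logging.getLogger(__name__)

__all__ = [
    "SpindleEvent",
    "ChannelThresholds",
    "spindle_band_filter",
    "rectified_envelope",
    "compute_thresholds",
    "detect_spindles",
    "spindle_density",
]


@dataclass
class SpindleEvent:
    channel: str
    start_s: float
    end_s: float
    peak_s: float
    peak_amplitude_uv: float
    duration_s: float

    def __post_init__(self) -> None:
        if not (self.start_s < self.peak_s < self.end_s):
            raise ValueError("spindle peak must lie strictly inside the event")


@dataclass
class ChannelThresholds:
    channel: str
    mean_amplitude_uv: float
    upper_mult: float = 5.0
    lower_mult: float = 2.0

    @property
    def upper(self) -> float:
        return self.upper_mult * self.mean_amplitude_uv

    @property
    def lower(self) -> float:
        return self.lower_mult * self.mean_amplitude_uv


def spindle_band_filter(x: np.ndarray, rate: float,
                        band: tuple[float, float] = (13.0, 16.0),
                        order_at_256: int = 2816) -> np.ndarray:
    """Zero-phase FIR band-pass into the fast-spindle band.

    The filter order is 2816 at 256 Hz and scales proportionally with the
    sampling rate (forced even, so the kernel length is odd and symmetric).
    """
    if not 0 < band[0] < band[1] < rate / 2:
        raise ValueError(f"band {band} outside Nyquist range")
    order = int(round(order_at_256 * rate / 256.0))
    if order % 2 == 1:
        order += 1
    numtaps = order + 1
    if len(x) < 3 * numtaps:
        raise ValueError(
            f"signal length {len(x)} shorter than 3× filter length {numtaps}")
    taps = sp_signal.firwin(numtaps, list(band), window="hamming",
                            pass_zero=False, fs=rate)
    return _apply_zero_phase(np.asarray(x, dtype=float), taps)


def rectified_envelope(filtered: np.ndarray) -> np.ndarray:
    """Instantaneous-amplitude envelope of the band-passed trace (Hilbert).

    The rectified trace itself returns to zero every half cycle, so event
    geometry (onsets, offsets, flanks, gaps) is evaluated on its envelope.
    """
    return np.abs(sp_signal.hilbert(np.asarray(filtered, dtype=float)))


def compute_thresholds(filtered: np.ndarray, epoch_mask: EpochMask, rate: float,
                       channel: str = "", config: AnalysisConfig | None = None) -> ChannelThresholds:
    """Channel-wise thresholds from the mean amplitude over included NREM time.

    The mean is taken over the rectified band-passed trace (or the Hilbert
    envelope with ``config.spindle_amplitude='envelope'``), excluding artifact
    sub-intervals.
    """
    config = config or AnalysisConfig()
    mask = epoch_mask.sample_mask(rate, len(filtered), exclude_artifacts=True)
    if not mask.any():
        raise ValueError("cannot estimate thresholds: no included NREM samples")
    if config.spindle_amplitude == "envelope":
        amp = np.abs(sp_signal.hilbert(filtered))
    else:
        amp = np.abs(filtered)
    mean_amp = float(amp[mask].mean())
    return ChannelThresholds(channel=channel, mean_amplitude_uv=mean_amp,
                             upper_mult=config.upper_mult,
                             lower_mult=config.lower_mult)


def detect_spindles(filtered: np.ndarray, thresholds: ChannelThresholds,
                    epoch_mask: EpochMask, rate: float,
                    config: AnalysisConfig | None = None) -> list[SpindleEvent]:
    """Detect spindle events on a band-passed channel.

    Steps: (1) segments where the envelope of the band-passed trace stays
    ≥ lower; (2) keep segments whose envelope reaches the upper threshold at
    a point at least the flank duration (0.25 s) away from both segment
    edges — i.e. the amplitude holds ≥ lower for ≥ 0.25 s on each side of
    the peak region, giving the 0.5-s minimum duration; (3) merge candidates
    separated by a sub-lower gap shorter than the gap rule (78.1 ms),
    absorbing the later candidate into the earlier one (peak = larger
    maximum); (4) reject events longer than 3.0 s or with peak amplitude
    > 200 μV; (5) drop events overlapping artifacts or excluded epochs.
    """
    config = config or AnalysisConfig()
    rect = np.abs(np.asarray(filtered, dtype=float))
    env = rectified_envelope(filtered)

    above = env >= thresholds.lower
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    seg_starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    seg_ends = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])  # half-open

    flank = int(round(config.spindle_flank_s * rate))
    # candidates: segments with an above-upper envelope sample that keeps the
    # flank duration above lower on both sides (plateau ties -> first sample)
    cands: list[list[int]] = []
    for a, b in zip(seg_starts, seg_ends):
        seg = env[a:b]
        hi = np.flatnonzero(seg >= thresholds.upper)
        hi = hi[(hi >= flank) & (hi <= len(seg) - 1 - flank)]
        if hi.size == 0:
            continue
        seg_peak = a + int(hi[np.argmax(seg[hi])])
        cands.append([int(a), int(b), int(seg_peak)])

    # merge across sub-lower gaps shorter than the gap rule
    gap_samples = config.spindle_gap_ms / 1000.0 * rate
    merged: list[list[int]] = []
    for c in cands:
        if merged and (c[0] - merged[-1][1]) < gap_samples:
            prev = merged[-1]
            prev[1] = c[1]
            if env[c[2]] > env[prev[2]]:
                prev[2] = c[2]
            logger.debug("merged candidate at %.2f s into previous event",
                         c[0] / rate)
        else:
            merged.append(c)

    events: list[SpindleEvent] = []
    for a, b, p in merged:
        duration = (b - a) / rate
        if duration > config.spindle_max_dur_s:
            logger.debug("event at %.2f s rejected: duration %.2f s", a / rate, duration)
            continue
        peak_amp = float(rect[a:b].max())
        if peak_amp > config.spindle_max_amp_uv:
            logger.debug("event at %.2f s rejected: amplitude %.1f μV", a / rate, peak_amp)
            continue
        start_s, end_s = a / rate, b / rate
        if epoch_mask.excluded_time_contains(start_s, end_s):
            logger.debug("event at %.2f s rejected: overlaps excluded time", start_s)
            continue
        events.append(SpindleEvent(channel=thresholds.channel, start_s=start_s,
                                   end_s=end_s, peak_s=p / rate,
                                   peak_amplitude_uv=peak_amp, duration_s=duration))
    events.sort(key=lambda ev: ev.start_s)
    return events


def spindle_density(events: list[SpindleEvent] | int, minutes: float) -> float:
    """Spindle density in events per minute."""
    if not minutes > 0:
        raise ValueError("density undefined: zero included minutes")
    count = events if isinstance(events, int) else len(events)
    return count / minutes
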