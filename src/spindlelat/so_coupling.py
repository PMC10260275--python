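"""Slow-oscillation detection and SO–spindle phase coupling.

SO detection is a zero-crossing scheme on the 3.5-Hz low-passed trace:
candidate cycles run between consecutive positive-to-negative zero-crossings
and must last 0.8–5 s (0.2–1.25 Hz); of those, cycles whose negative peak is
lower than the candidate-mean negative peak AND whose peak-to-peak amplitude
exceeds the candidate-mean peak-to-peak are kept as SOs.

Coupling phase is read from the Hilbert transform of the 0.2–1.25 Hz
band-passed signal at each spindle's amplitude peak; the convention is the
analytic-signal (cosine) phase, 0 rad at the SO positive peak, ±π at the
trough, +π/2 at the falling zero-crossing.  Coupling distance is |phase|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .io_psg import AnalysisConfig
from .preprocess import (_HAMMING_TW, EpochMask, bandpass_zero_phase,
                         lowpass_zero_phase)
from .spindles import SpindleEvent

logger = logging.getLogger(__name__)

__all__ = [
    "SOEvent",
    "SOSpindlePair",
    "CouplingSummary",
    "detect_sos",
    "so_phase",
    "pair_so_spindles",
    "coupling_summary",
    "rayleigh_test",
    "circular_mean",
]


@dataclass
class SOEvent:
    channel: str
    start_s: float       # positive-to-negative zero-crossing
    end_s: float         # next positive-to-negative zero-crossing
    neg_peak_s: float
    neg_peak_uv: float
    pos_peak_s: float
    pos_peak_uv: float

    def __post_init__(self) -> None:
        if not (self.neg_peak_uv < 0 < self.pos_peak_uv):
            raise ValueError("SO needs a negative trough and positive peak")
        if not (self.start_s < self.neg_peak_s < self.end_s):
            raise ValueError("trough must lie inside the cycle")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def p2p_uv(self) -> float:
        return self.pos_peak_uv - self.neg_peak_uv

    # aliases so the shared event-table writer applies
    @property
    def peak_s(self) -> float:
        return self.neg_peak_s


@dataclass
class SOSpindlePair:
    so: SOEvent
    spindle: SpindleEvent
    phase_rad: float

    def __post_init__(self) -> None:
        if not (-np.pi < self.phase_rad <= np.pi):
            raise ValueError("phase must lie in (-pi, pi]")

    @property
    def distance_rad(self) -> float:
        return abs(self.phase_rad)

    @property
    def channel(self) -> str:
        return self.spindle.channel

    @property
    def start_s(self) -> float:
        return self.so.start_s

    @property
    def end_s(self) -> float:
        return self.so.end_s

    @property
    def peak_s(self) -> float:
        return self.spindle.peak_s

    @property
    def duration_s(self) -> float:
        return self.so.duration_s

    @property
    def peak_amplitude_uv(self) -> float:
        return self.spindle.peak_amplitude_uv


@dataclass
class CouplingSummary:
    channel: str
    n_pairs: int
    mean_distance_rad: float
    circ_mean_phase_rad: float
    rayleigh_p: float


def detect_sos(signal: np.ndarray, rate: float, epoch_mask: EpochMask,
               config: AnalysisConfig | None = None,
               channel: str = "") -> list[SOEvent]:
    """Two-pass SO detection (candidate cycles, then amplitude selection)."""
    config = config or AnalysisConfig()
    x = np.asarray(signal, dtype=float)
    lp = lowpass_zero_phase(x, rate, config.so_lowpass_hz)
    # filter edges are invalid (half-kernel transient on each side)
    edge = int(np.ceil(_HAMMING_TW * rate / config.so_lowpass_hz / 2))
    # positive-to-negative zero-crossings: lp[i] > 0 >= lp[i+1]
    pos = lp > 0
    p2n = np.flatnonzero(pos[:-1] & ~pos[1:]) + 1  # first sample at/below zero
    dur_lo, dur_hi = config.so_dur_s

    candidates: list[SOEvent] = []
    for a, b in zip(p2n[:-1], p2n[1:]):
        duration = (b - a) / rate
        if not (dur_lo <= duration <= dur_hi):
            continue
        if a < edge or b > len(lp) - edge:
            continue
        if epoch_mask.excluded_time_contains(a / rate, b / rate):
            continue
        seg = lp[a:b]
        i_neg = int(np.argmin(seg))
        i_pos = int(np.argmax(seg))
        if i_neg in (0, len(seg) - 1):  # noise-dominated cycle, no real trough
            continue
        neg_uv, pos_uv = float(seg[i_neg]), float(seg[i_pos])
        if not (neg_uv < 0 < pos_uv):
            continue
        candidates.append(SOEvent(channel=channel, start_s=a / rate, end_s=b / rate,
                                  neg_peak_s=(a + i_neg) / rate, neg_peak_uv=neg_uv,
                                  pos_peak_s=(a + i_pos) / rate, pos_peak_uv=pos_uv))
    if not candidates:
        return []
    mean_neg = float(np.mean([c.neg_peak_uv for c in candidates]))
    mean_p2p = float(np.mean([c.p2p_uv for c in candidates]))
    # strict inequalities, with a relative guard so numerically identical
    # cycles (float jitter) never pass
    tol = 1e-9 * mean_p2p
    selected = [c for c in candidates
                if c.neg_peak_uv < mean_neg - tol and c.p2p_uv > mean_p2p + tol]
    logger.info("SO detection %s: %d candidates, %d selected",
                channel, len(candidates), len(selected))
    return selected


def so_phase(signal: np.ndarray, rate: float,
             band: tuple[float, float] = (0.2, 1.25)) -> np.ndarray:
    """Instantaneous phase (rad) of the SO-band analytic signal.

    Cosine convention: 0 at the positive peak, +π/2 at the falling
    zero-crossing, ±π at the trough.
    """
    so = bandpass_zero_phase(np.asarray(signal, dtype=float), rate,
                             band[0], band[1])
    # analytic signal of cos(wt) is e^{iwt}: angle is 0 at the positive peak,
    # +pi/2 at the falling zero-crossing, +/-pi at the trough
    return np.angle(sp_signal.hilbert(so))


def pair_so_spindles(sos: list[SOEvent], spindles: list[SpindleEvent],
                     phase: np.ndarray, rate: float) -> list[SOSpindlePair]:
    """Pair each spindle whose amplitude peak falls inside an SO cycle.

    SO cycles are disjoint by construction (consecutive zero-crossing
    intervals), so each spindle matches at most one SO.
    """
    if sos:
        starts = np.array([s.start_s for s in sorted(sos, key=lambda s: s.start_s)])
        sos_sorted = sorted(sos, key=lambda s: s.start_s)
        for prev, nxt in zip(sos_sorted[:-1], sos_sorted[1:]):
            assert prev.end_s <= nxt.start_s + 1e-9, "SO cycles must be disjoint"
    else:
        return []
    pairs: list[SOSpindlePair] = []
    for sp in spindles:
        i = int(np.searchsorted(starts, sp.peak_s, side="right")) - 1
        if i < 0:
            continue
        so = sos_sorted[i]
        if not (so.start_s <= sp.peak_s < so.end_s):
            continue
        k = int(round(sp.peak_s * rate))
        if not 0 <= k < len(phase):
            continue
        ph = float(phase[k])
        if ph <= -np.pi:
            ph += 2 * np.pi
        pairs.append(SOSpindlePair(so=so, spindle=sp, phase_rad=ph))
    return pairs


def circular_mean(phases: np.ndarray) -> float:
    """Circular mean direction via the mean resultant vector."""
    phases = np.asarray(phases, dtype=float)
    return float(np.arctan2(np.sin(phases).mean(), np.cos(phases).mean()))


def rayleigh_test(phases: np.ndarray) -> float:
    """Rayleigh test p-value for circular non-uniformity.

    Uses the standard small-sample approximation
    ``p = exp(sqrt(1 + 4n + 4(n² − R²)) − (1 + 2n))`` with R the resultant
    length n·r̄ (the form used by the classic circular-statistics toolboxes).
    """
    phases = np.asarray(phases, dtype=float)
    n = len(phases)
    r = float(np.hypot(np.sin(phases).mean(), np.cos(phases).mean()))
    R = n * r
    p = np.exp(np.sqrt(1 + 4 * n + 4 * (n**2 - R**2)) - (1 + 2 * n))
    return float(min(p, 1.0))


def coupling_summary(pairs: list[SOSpindlePair], channel: str = "") -> CouplingSummary | None:
    """Summary of coupling distance and circular phase for one channel.

    Returns None (a missing-value marker) when there are no pairs; the
    Rayleigh p is NaN when fewer than 2 pairs exist.
    """
    if not pairs:
        return None
    phases = np.array([p.phase_rad for p in pairs])
    distances = np.abs(phases)
    p_ray = rayleigh_test(phases) if len(phases) >= 2 else float("nan")
    return CouplingSummary(
        channel=channel or pairs[0].channel,
        n_pairs=len(pairs),
        mean_distance_rad=float(distances.mean()),
        circ_mean_phase_rad=circular_mean(phases),
        rayleigh_p=p_ray,
    )
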