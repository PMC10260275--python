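"""Ground-truth-bearing synthetic polysomnography and recognition responses.

No participant data from overnight emotional-memory studies of this design
are publicly available, so every pipeline stage is exercised on synthetic
inputs with known ground truth:

* 1/f (pink-noise) background EEG on six channels (F3/F4/C3/C4 + mastoids);
* slow oscillations injected as single 0.2–1.25 Hz sine cycles large enough
  to pass the detector's amplitude selection against the background;
* fast spindles as Tukey-windowed 13–16 Hz bursts whose peak amplitude is
  parameterized in units of the detector's own threshold (multiples of the
  background's rectified band-passed mean), a configurable fraction of them
  phase-locked to the SO cycle at a target phase φ0 with von Mises
  concentration κ (κ = 0 gives the uniform null);
* hemispherically asymmetric theta oscillations in REM epochs;
* three-retrieval recognition responses from an equal-variance
  signal-detection model (target strength ~ N(d, 1), foil ~ N(bias, 1),
  dual criteria for recollected/familiar), with an emotional false-alarm
  inflation at 24 h implemented as a criterion shift for emotional foils;
* per-subject effect wiring from the true lateralization indices to the
  memory parameters, so that downstream covariate tests have a known sign
  and a known null.

Reduced-night mode (short nights, proportional injection counts) is the
default working scale; ``SimulationSpec.full_night()`` gives an 8-h night.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy.stats import norm

from functools import lru_cache

from .io_psg import AnalysisConfig, ArtifactSet, Hypnogram, Recording
from .memory_scoring import EMOTIONS, RETRIEVALS
from .preprocess import bandpass_zero_phase

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "pink_noise",
    "simulate_night",
    "simulate_responses",
    "simulate_dprime_scores",
    "simulate_cohort_scores",
    "simulate_cohort",
]

CHANNELS = ("F3", "F4", "C3", "C4", "A1", "A2")
SPINDLE_CHANNELS = ("F3", "F4", "C3", "C4")


@dataclass
class SimulationSpec:
    """Study conditions for the synthetic cohort.

    Stage fractions, cohort size, spindle/SO rates, coupling phases and the
    memory-score trajectory follow the observed sample characteristics of
    the emulated study design (32 subjects, N2 36%, N3 24%, REM 18% of the
    night, frontal fast-spindle density ≈ 3.3/min, mean coupling distance
    ≈ 0.95 rad, d' declining from ≈ 2.6 immediately to ≈ 1.8 at 24 h with
    an emotional false-alarm inflation at 24 h).
    """

    n_subjects: int = 32
    sampling_rate: float = 256.0
    n_epochs: int = 40                 # reduced night: 20 min
    epoch_length: float = 30.0
    stage_fractions: dict = field(default_factory=lambda: {
        "N1": 0.057, "N2": 0.363, "N3": 0.240, "REM": 0.184})
    # background
    noise_rms_uv: float = 15.0
    noise_slope: float = 1.0           # 1/f^slope
    # spindles
    spindle_rate_per_min: float = 3.3
    spindle_amp_mult: float = 16.0     # peak amplitude in units of the
    #                                    background's rectified spindle-band mean
    spindle_freq_hz: tuple[float, float] = (13.0, 16.0)
    spindle_dur_s: tuple[float, float] = (0.8, 1.5)
    # slow oscillations
    so_rate_per_min: float = 5.0
    so_amp_uv: float = 75.0
    so_freq_hz: tuple[float, float] = (0.6, 0.9)
    # coupling
    coupled_fraction: float = 0.7
    coupling_phase_rad: float = -0.04  # near the SO positive peak
    coupling_kappa: float = 5.0
    # hemispheric asymmetry (population SDs of the true lateralization indices)
    spindle_lat_mean: float = 0.0
    spindle_lat_sd: float = 0.15
    coupling_dist_base_rad: float = 0.95
    coupling_lat_mean: float = 0.0
    coupling_lat_sd: float = 0.20
    theta_amp_uv: float = 20.0
    theta_lat_mean: float = 0.0
    theta_lat_sd: float = 0.15
    # artifacts
    artifact_fraction: float = 0.02
    # memory model (per retrieval × emotion mean d_true; foil-criterion bias)
    d_true: dict = field(default_factory=lambda: {
        ("immediate", "neutral"): 2.60, ("immediate", "emotional"): 2.55,
        ("12h", "neutral"): 2.10, ("12h", "emotional"): 2.00,
        ("24h", "neutral"): 2.05, ("24h", "emotional"): 1.90})
    fa_bias: dict = field(default_factory=lambda: {
        ("24h", "emotional"): 0.35})
    subject_ability_sd: float = 0.40
    criterion_familiar: float = 1.30
    criterion_recollect: float = 1.90
    n_trials_per_cell: int = 25
    # effect wiring: lateralization -> memory parameters
    wiring_coupling_emotion: float = -1.5   # coupling_lat shifts neutral−emotional d
    wiring_spindle_emotion_24h: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.stage_fractions.values()) > 1.0 + 1e-9:
            raise ValueError("stage fractions must sum to ≤ 1")
        nyq = self.sampling_rate / 2
        for lo, hi in (self.spindle_freq_hz, self.so_freq_hz):
            if not 0 < lo < hi < nyq:
                raise ValueError("injection bands must lie inside Nyquist")
        for v in (self.spindle_rate_per_min, self.so_rate_per_min,
                  self.coupling_kappa, self.spindle_amp_mult):
            if v < 0:
                raise ValueError("rates, amplitudes and κ must be ≥ 0")
        if not self.criterion_recollect > self.criterion_familiar:
            raise ValueError("recollection criterion must exceed familiarity criterion")
        spindle_cap = self.spindle_rate_per_min * max(self.spindle_dur_s)
        if spindle_cap > 60.0:
            raise ValueError("spindle rate × duration exceeds epoch capacity")

    @classmethod
    def full_night(cls, **overrides) -> "SimulationSpec":
        """Paper-scale 8-h night (960 epochs)."""
        return cls(n_epochs=960, **overrides)


@dataclass
class GroundTruth:
    """Injected events and true per-subject parameters."""

    spindles: pd.DataFrame          # channel, peak_s, amplitude_uv, phase_rad (NaN if uncoupled)
    sos: pd.DataFrame               # channel, start_s, end_s, pos_peak_s
    spindle_lat: float = np.nan
    coupling_lat: float = np.nan
    theta_lat: float = np.nan
    d_true: dict | None = None


def pink_noise(n: int, rng: np.random.Generator, slope: float = 1.0,
               rms: float = 1.0) -> np.ndarray:
    """Gaussian 1/f^slope noise with the requested RMS."""
    freqs = np.fft.rfftfreq(n, d=1.0)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-slope / 2.0)
    phases = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    x = np.fft.irfft(amp * phases, n=n)
    x *= rms / max(x.std(), 1e-30)
    return x


def _build_hypnogram(spec: SimulationSpec, rng: np.random.Generator) -> Hypnogram:
    """Epoch sequence realizing the target stage fractions (±1 epoch each),
    arranged in a plausible cycle order (W, N1, N2, N3, N2, REM, ...)."""
    n = spec.n_epochs
    counts = {s: int(round(f * n)) for s, f in spec.stage_fractions.items()}
    counts["W"] = max(0, n - sum(counts.values()))
    stages: list[str] = []
    stages += ["W"] * min(counts["W"], max(1, counts["W"] // 2))
    counts["W"] -= len(stages)
    pool = {s: counts[s] for s in ("N1", "N2", "N3", "REM")}
    order = ("N1", "N2", "N3", "N2", "REM")
    while sum(pool.values()) > 0:
        for s in order:
            if pool[s] > 0:
                take = min(pool[s], 2)
                stages += [s] * take
                pool[s] -= take
    stages += ["W"] * counts["W"]
    return Hypnogram(stages=stages[:n], epoch_length=spec.epoch_length)


@lru_cache(maxsize=128)
def _so_cycle_phase_map(f_so_centihz: int, fs: float) -> np.ndarray:
    """Hilbert phase of an isolated SO cycle (−sin, one period) after the
    0.2–1.25 Hz band-pass, sampled over the cycle.

    Band-passing distorts an isolated cycle, so the filtered waveform's
    positive peak (phase 0) is not exactly at 3T/4 of the raw template;
    phase-locked spindles are therefore placed on this map, making the
    injected ground-truth phase consistent with the convention the analysis
    reads out.
    """
    f_so = f_so_centihz / 100.0
    T = 1.0 / f_so
    n = int(round(T * fs))
    pad = int(30 * fs)
    x = np.zeros(2 * pad + n)
    t = np.arange(n) / fs
    x[pad:pad + n] = -np.sin(2 * np.pi * t / T)
    xf = bandpass_zero_phase(x, fs, 0.2, 1.25)
    return np.angle(sp_signal.hilbert(xf))[pad:pad + n]


def _spindle_burst(duration_s: float, freq: float, rate: float,
                   peak_amp: float, rng: np.random.Generator) -> np.ndarray:
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate
    window = sp_signal.windows.hann(n)
    phase0 = rng.uniform(0, 2 * np.pi)
    return peak_amp * window * np.cos(2 * np.pi * freq * t + phase0)


def simulate_night(spec: SimulationSpec, subject_seed: int,
                   ground_truth_lat: dict | None = None,
                   ) -> tuple[Recording, Hypnogram, ArtifactSet, GroundTruth]:
    """One synthetic night with injected oscillations and known ground truth.

    ``ground_truth_lat`` may pin the subject's true lateralization values
    (keys spindle_lat, coupling_lat, theta_lat); otherwise they are drawn
    from the spec's population distributions.
    """
    rng = np.random.default_rng(subject_seed)
    fs = spec.sampling_rate
    hyp = _build_hypnogram(spec, rng)
    n_samples = int(round(len(hyp) * spec.epoch_length * fs))
    spe = int(round(spec.epoch_length * fs))

    lat = dict(ground_truth_lat or {})
    lat.setdefault("spindle_lat",
                   rng.normal(spec.spindle_lat_mean, spec.spindle_lat_sd))
    lat.setdefault("coupling_lat",
                   rng.normal(spec.coupling_lat_mean, spec.coupling_lat_sd))
    lat.setdefault("theta_lat", rng.normal(spec.theta_lat_mean, spec.theta_lat_sd))

    data = np.vstack([
        pink_noise(n_samples, rng, spec.noise_slope,
                   spec.noise_rms_uv if ch not in ("A1", "A2")
                   else spec.noise_rms_uv * 0.2)
        for ch in CHANNELS
    ])
    rec = Recording(channel_labels=list(CHANNELS), sampling_rate=fs, data=data)

    # the injection amplitude unit: rectified mean of the band-passed background
    # (measured on one clean reference noise trace)
    ref = pink_noise(n_samples, np.random.default_rng(subject_seed + 10_000),
                     spec.noise_slope, spec.noise_rms_uv)
    band = sp_signal.firwin(int(2 * fs) + 1, list(spec.spindle_freq_hz),
                            window="hamming", pass_zero=False, fs=fs)
    bg_mean = float(np.abs(sp_signal.fftconvolve(ref, band, "same")).mean())

    nrem_epochs = [i for i, s in enumerate(hyp.stages) if s in ("N2", "N3")]
    rem_epochs = [i for i, s in enumerate(hyp.stages) if s == "REM"]
    nrem_minutes = len(nrem_epochs) * spec.epoch_length / 60.0

    # --- slow oscillations (identical times on every channel) -------------
    so_rows = []
    so_cycles: list[tuple[float, float, float]] = []  # start, end, period
    n_sos = int(round(spec.so_rate_per_min * nrem_minutes))
    slots = []
    for i in nrem_epochs:
        e0 = i * spec.epoch_length
        slots += [e0 + k * 6.0 for k in range(int(spec.epoch_length // 6))]
    rng.shuffle(slots)
    for t0 in sorted(slots[:n_sos]):
        # centi-Hz grid keeps the per-frequency phase map cacheable
        f_so = round(rng.uniform(*spec.so_freq_hz), 2)
        T = 1.0 / f_so
        amp = spec.so_amp_uv * rng.uniform(0.8, 1.2)
        n_so = int(round(T * fs))
        a = int(round(t0 * fs))
        if a + n_so >= n_samples:
            continue
        t = np.arange(n_so) / fs
        wave = -amp * np.sin(2 * np.pi * t / T)
        for ch in SPINDLE_CHANNELS:
            data[CHANNELS.index(ch), a:a + n_so] += wave
        so_cycles.append((t0, t0 + T, f_so))
        so_rows.append({"channel": "all", "start_s": t0, "end_s": t0 + T,
                        "pos_peak_s": t0 + 0.75 * T})

    # --- spindles ----------------------------------------------------------
    # density asymmetry realizes the true spindle_lat on the frontal pair
    r = lat["spindle_lat"]
    rate_f4 = spec.spindle_rate_per_min * (1 + r / 2)
    rate_f3 = spec.spindle_rate_per_min * (1 - r / 2)
    rates = {"F3": rate_f3, "F4": rate_f4,
             "C3": spec.spindle_rate_per_min, "C4": spec.spindle_rate_per_min}
    # coupling-phase asymmetry realizes coupling_lat via per-channel |φ0|
    c = lat["coupling_lat"]
    dist_f4 = spec.coupling_dist_base_rad * (1 + c / 2)
    dist_f3 = spec.coupling_dist_base_rad * (1 - c / 2)
    phi0 = {"F3": np.sign(spec.coupling_phase_rad or 1) * dist_f3,
            "F4": np.sign(spec.coupling_phase_rad or 1) * dist_f4,
            "C3": spec.coupling_phase_rad, "C4": spec.coupling_phase_rad}

    sp_rows = []
    min_gap_s = 1.0
    for ch in SPINDLE_CHANNELS:
        n_sp = rng.poisson(rates[ch] * nrem_minutes)
        n_coupled = int(round(spec.coupled_fraction * n_sp))
        placements: list[tuple[float, float]] = []  # (peak_s, phase or nan)
        if so_cycles and n_coupled > 0:
            chosen = rng.choice(len(so_cycles), size=n_coupled,
                                replace=n_coupled > len(so_cycles))
            for ci in np.atleast_1d(chosen):
                s0, s1, f_so = so_cycles[int(ci)]
                if spec.coupling_kappa > 0:
                    phi = rng.vonmises(phi0[ch], spec.coupling_kappa)
                else:
                    phi = rng.uniform(-np.pi, np.pi)
                pmap = _so_cycle_phase_map(int(round(f_so * 100)), fs)
                k = int(np.argmin(np.abs(np.angle(np.exp(1j * (pmap - phi))))))
                placements.append((s0 + k / fs, phi))
        n_free = n_sp - len(placements)
        free_slots = []
        for i in nrem_epochs:
            e0 = i * spec.epoch_length
            free_slots += [e0 + 2.0 + k * 3.0
                           for k in range(int((spec.epoch_length - 4) // 3))]
        rng.shuffle(free_slots)
        taken = sorted(p for p, _ in placements)
        for t0 in free_slots:
            if n_free <= 0:
                break
            if any(abs(t0 - tp) < min_gap_s for tp in taken):
                continue
            placements.append((t0, np.nan))
            taken.append(t0)
            n_free -= 1
        ci_data = CHANNELS.index(ch)
        for t_peak, phi in placements:
            dur = rng.uniform(*spec.spindle_dur_s)
            freq = rng.uniform(*spec.spindle_freq_hz)
            amp = spec.spindle_amp_mult * bg_mean * rng.uniform(0.9, 1.1)
            burst = _spindle_burst(dur, freq, fs, amp, rng)
            a = int(round((t_peak - dur / 2) * fs))
            if a < 0 or a + len(burst) >= n_samples:
                continue
            data[ci_data, a:a + len(burst)] += burst
            sp_rows.append({"channel": ch, "peak_s": t_peak,
                            "amplitude_uv": amp, "phase_rad": phi,
                            "duration_s": dur})

    # --- REM theta ----------------------------------------------------------
    th = lat["theta_lat"]
    theta_amp = {"F3": spec.theta_amp_uv * (1 - th / 2),
                 "F4": spec.theta_amp_uv * (1 + th / 2)}
    for i in rem_epochs:
        a = i * spe
        b = min(a + spe, n_samples)
        t = np.arange(b - a) / fs
        f_th = rng.uniform(4.5, 6.5)
        env = 0.6 + 0.4 * np.sin(2 * np.pi * rng.uniform(0.05, 0.15) * t
                                 + rng.uniform(0, 2 * np.pi))
        carrier = np.cos(2 * np.pi * f_th * t + rng.uniform(0, 2 * np.pi))
        for ch in ("F3", "F4"):
            data[CHANNELS.index(ch), a:b] += theta_amp[ch] * env * carrier

    # --- artifacts ----------------------------------------------------------
    intervals = []
    sleep_epochs = nrem_epochs + rem_epochs
    n_art = int(round(spec.artifact_fraction * len(sleep_epochs)))
    for i in rng.choice(sleep_epochs, size=min(n_art, len(sleep_epochs)),
                        replace=False) if n_art else []:
        e0 = i * spec.epoch_length
        s = e0 + rng.uniform(0, spec.epoch_length - 3.0)
        intervals.append((s, s + rng.uniform(1.0, 3.0)))
    artifacts = ArtifactSet(intervals=sorted(intervals))

    truth = GroundTruth(
        spindles=pd.DataFrame(sp_rows, columns=["channel", "peak_s",
                                                "amplitude_uv", "phase_rad",
                                                "duration_s"]),
        sos=pd.DataFrame(so_rows, columns=["channel", "start_s", "end_s",
                                           "pos_peak_s"]),
        spindle_lat=lat["spindle_lat"],
        coupling_lat=lat["coupling_lat"],
        theta_lat=lat["theta_lat"],
    )
    return rec, hyp, artifacts, truth


# ---------------------------------------------------------------------------
# Recognition responses
# ---------------------------------------------------------------------------

def _subject_d_true(spec: SimulationSpec, rng: np.random.Generator,
                    coupling_lat: float = 0.0,
                    spindle_lat: float = 0.0) -> tuple[dict, dict]:
    """Per-subject (d_true, fa_bias) dicts with ability noise and wiring."""
    ability = rng.normal(0.0, spec.subject_ability_sd)
    emo_shift = spec.wiring_coupling_emotion * coupling_lat
    d = {}
    for (ret, emo), base in spec.d_true.items():
        v = base + ability
        v += (emo_shift / 2) * (1 if emo == "neutral" else -1)
        if ret == "24h":
            s24 = spec.wiring_spindle_emotion_24h * spindle_lat
            v += (s24 / 2) * (1 if emo == "neutral" else -1)
        d[(ret, emo)] = max(v, 0.0)
    return d, dict(spec.fa_bias)


def simulate_responses(spec: SimulationSpec, d_true: dict, seed: int,
                       subject: str = "s01",
                       fa_bias: dict | None = None) -> pd.DataFrame:
    """Item-level response table for one subject (3 retrievals × 100 items).

    Equal-variance SDT: target strength ~ N(d, 1), foil ~ N(bias, 1);
    response is recollected above the upper criterion, familiar between the
    criteria, new below.
    """
    rng = np.random.default_rng(seed)
    fa_bias = fa_bias if fa_bias is not None else dict(spec.fa_bias)
    n = spec.n_trials_per_cell
    rows = []
    item = 0
    for ret in RETRIEVALS:
        for emo in EMOTIONS:
            for is_target in (True, False):
                mu = d_true[(ret, emo)] if is_target else fa_bias.get((ret, emo), 0.0)
                strength = rng.normal(mu, 1.0, size=n)
                resp = np.where(strength >= spec.criterion_recollect, "recollected",
                                np.where(strength >= spec.criterion_familiar,
                                         "familiar", "new"))
                for r in resp:
                    rows.append({"subject": subject, "retrieval": ret,
                                 "item_id": f"item{item:05d}", "emotion": emo,
                                 "is_target": is_target, "response": r})
                    item += 1
    return pd.DataFrame(rows)


def simulate_dprime_scores(d_true: np.ndarray, fa_bias: np.ndarray,
                           n_trials: int, rng: np.random.Generator,
                           criterion: float = 1.30,
                           correction: str = "half_count") -> np.ndarray:
    """Vectorized observed-d' simulation via binomial counts.

    ``d_true`` and ``fa_bias`` are broadcastable arrays of per-cell target
    means and foil means; hit/fa counts are Binomial(n, Φ(μ − c)), which is
    distribution-identical to drawing item strengths and thresholding.
    """
    p_hit = norm.cdf(np.asarray(d_true) - criterion)
    p_fa = norm.cdf(np.asarray(fa_bias) - criterion)
    hits = rng.binomial(n_trials, p_hit) / n_trials
    fas = rng.binomial(n_trials, p_fa) / n_trials

    def correct(x):
        if correction == "loglinear":
            return (x * n_trials + 0.5) / (n_trials + 1)
        return np.clip(x, 1.0 / (2 * n_trials), 1.0 - 1.0 / (2 * n_trials))

    return norm.ppf(correct(hits)) - norm.ppf(correct(fas))


def simulate_cohort_scores(spec: SimulationSpec, seed: int | None = None
                           ) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Score-level cohort (no EEG): observed d' array (n, 3, 2), covariate
    table, and per-subject ground-truth parameters.

    The true lateralization indices are drawn from the spec's population
    distributions and wired into the memory parameters; use zero wiring
    weights for a null cohort.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_subjects
    truths = []
    scores = np.empty((n, len(RETRIEVALS), len(EMOTIONS)))
    covs = _covariate_table(spec, rng)
    for i in range(n):
        c_lat = rng.normal(spec.coupling_lat_mean, spec.coupling_lat_sd)
        s_lat = rng.normal(spec.spindle_lat_mean, spec.spindle_lat_sd)
        t_lat = rng.normal(spec.theta_lat_mean, spec.theta_lat_sd)
        d, bias = _subject_d_true(spec, rng, coupling_lat=c_lat, spindle_lat=s_lat)
        d_arr = np.array([[d[(ret, emo)] for emo in EMOTIONS] for ret in RETRIEVALS])
        b_arr = np.array([[bias.get((ret, emo), 0.0) for emo in EMOTIONS]
                          for ret in RETRIEVALS])
        scores[i] = simulate_dprime_scores(d_arr, b_arr, spec.n_trials_per_cell,
                                           rng, criterion=spec.criterion_familiar)
        truths.append({"subject": f"s{i:02d}", "coupling_lat": c_lat,
                       "spindle_lat": s_lat, "theta_lat": t_lat,
                       **{f"d_{ret}_{emo}": d[(ret, emo)]
                          for ret in RETRIEVALS for emo in EMOTIONS}})
    return scores, covs, pd.DataFrame(truths)


def _covariate_table(spec: SimulationSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Subject covariates mirroring the cohort make-up (mostly female,
    roughly half home measurements, ~6.7 h study-night sleep, right-skewed
    BDI/GAD-7 with occasional missing values, mostly right-handed)."""
    n = spec.n_subjects
    sex = np.where(rng.random(n) < 25 / 32, "F", "M")
    location = np.where(rng.random(n) < 0.53, "home", "lab")
    sleep_h = rng.normal(6.73, 0.75, size=n)
    bdi = np.round(rng.lognormal(mean=2.0, sigma=0.9, size=n)).clip(0, 45)
    gad = np.round(rng.lognormal(mean=1.4, sigma=0.7, size=n)).clip(0, 21)
    hand = rng.choice(["right", "left", "ambidextrous", "missing"], size=n,
                      p=[0.82, 0.03, 0.03, 0.12])
    df = pd.DataFrame({
        "subject": [f"s{i:02d}" for i in range(n)],
        "sex": sex, "location": location, "sleep_duration": sleep_h,
        "bdi": bdi, "gad7": gad, "handedness": hand,
    })
    miss = rng.random(n) < 1 / 32           # occasional missing questionnaire
    df.loc[miss, ["bdi", "gad7"]] = np.nan
    df["bdi_ln"] = np.log(df["bdi"] + 1)
    df["gad7_ln"] = np.log(df["gad7"] + 1)
    return df


def simulate_cohort(spec: SimulationSpec, seed: int | None = None) -> dict:
    """Full cohort bundle: nights (Recording/Hypnogram/ArtifactSet), item-level
    response tables, covariates and ground truth."""
    base_seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(base_seed)
    covs = _covariate_table(spec, rng)
    nights = []
    responses = []
    truths = []
    for i in range(spec.n_subjects):
        subj = f"s{i:02d}"
        sseed = int(rng.integers(0, 2**31 - 1))
        rec, hyp, art, truth = simulate_night(spec, sseed)
        d, bias = _subject_d_true(spec, np.random.default_rng(sseed + 1),
                                  coupling_lat=truth.coupling_lat,
                                  spindle_lat=truth.spindle_lat)
        truth.d_true = d
        resp = simulate_responses(spec, d, seed=sseed + 2, subject=subj,
                                  fa_bias=bias)
        nights.append((subj, rec, hyp, art))
        responses.append(resp)
        truths.append(truth)
    return {"nights": nights, "responses": pd.concat(responses, ignore_index=True),
            "covariates": covs, "ground_truth": truths, "spec": spec}
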