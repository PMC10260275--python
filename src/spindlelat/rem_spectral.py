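"""REM power spectral density, band powers and cross-band standardized theta.

Per-epoch PSD is a Welch estimate with 1024-sample Hamming segments at 50%
overlap, in dB (10·log10 μV²/Hz).  Band powers (delta, theta, alpha, sigma,
beta1, beta2 in F3 and F4) are averaged across REM epochs, and the 12-cell
table is z-standardized so that the two theta cells become relative values,
robust to overall amplitude differences between recordings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .io_psg import AnalysisConfig, Recording
from .preprocess import EpochMask, build_epoch_mask

logger = logging.getLogger(__name__)

__all__ = [
    "BandPowerTable",
    "ThetaSummary",
    "epoch_psd",
    "band_means",
    "rem_band_power_table",
    "standardize_theta",
]

FRONTAL = ("F3", "F4")


@dataclass
class BandPowerTable:
    """Mean REM band power (dB) per frontal channel × band."""

    power_db: dict[tuple[str, str], float]  # (channel, band) -> dB
    n_epochs: int

    def cells(self) -> np.ndarray:
        return np.array(list(self.power_db.values()), dtype=float)


@dataclass
class ThetaSummary:
    theta_z_f3: float
    theta_z_f4: float

    @property
    def rem_theta(self) -> float:
        return (self.theta_z_f3 + self.theta_z_f4) / 2.0


def epoch_psd(epoch_samples: np.ndarray, rate: float,
              nperseg: int = 1024, scale: str = "db") -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD of one epoch (freqs, power).

    1024-sample Hamming segments with 50% overlap; power in dB of μV²/Hz
    (or linear with ``scale='linear'``).
    """
    x = np.asarray(epoch_samples, dtype=float)
    if len(x) < nperseg:
        raise ValueError(f"epoch has {len(x)} samples; need ≥ {nperseg}")
    freqs, pxx = sp_signal.welch(x, fs=rate, window="hamming", nperseg=nperseg,
                                 noverlap=nperseg // 2, detrend=False)
    if scale == "db":
        pxx = 10.0 * np.log10(np.maximum(pxx, 1e-20))
    return freqs, pxx


def band_means(freqs: np.ndarray, spectrum: np.ndarray,
               bands: dict[str, tuple[float, float]]) -> dict[str, float]:
    """Mean power per band over bins with center frequency in [low, high)."""
    out: dict[str, float] = {}
    for name, (lo, hi) in bands.items():
        sel = (freqs >= lo) & (freqs < hi)
        if not sel.any():
            raise ValueError(f"band {name} [{lo}, {hi}) contains no frequency bins")
        out[name] = float(spectrum[sel].mean())
    return out


def rem_band_power_table(recording: Recording, rem_mask: EpochMask,
                         config: AnalysisConfig | None = None,
                         channels: tuple[str, str] = FRONTAL) -> BandPowerTable:
    """Per-channel × band mean REM power over included REM epochs."""
    config = config or AnalysisConfig()
    rate = recording.sampling_rate
    spe = int(round(rem_mask.epoch_length * rate))
    power: dict[tuple[str, str], list[float]] = {
        (ch, b): [] for ch in channels for b in config.psd_bands
    }
    n_used = 0
    for i in np.flatnonzero(rem_mask.included):
        a = i * spe
        b = min(a + spe, recording.n_samples)
        if b - a < config.psd_nperseg:
            logger.info("REM epoch %d skipped: %d samples < %d", i, b - a,
                        config.psd_nperseg)
            continue
        n_used += 1
        for ch in channels:
            freqs, pxx = epoch_psd(recording.get(ch)[a:b], rate,
                                   nperseg=config.psd_nperseg, scale=config.psd_scale)
            for band, val in band_means(freqs, pxx, config.psd_bands).items():
                power[(ch, band)].append(val)
    if n_used == 0:
        raise ValueError("no usable REM epochs")
    return BandPowerTable(
        power_db={k: float(np.mean(v)) for k, v in power.items()},
        n_epochs=n_used,
    )


def standardize_theta(table: BandPowerTable,
                      channels: tuple[str, str] = FRONTAL) -> ThetaSummary:
    """Z-score the theta cells against all 12 channel×band cells.

    Sample SD (ddof=1) is used.  A constant table (zero SD) is degenerate
    and raises.
    """
    cells = table.cells()
    mu = cells.mean()
    sd = cells.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a constant band-power table")
    z_f3 = (table.power_db[(channels[0], "theta")] - mu) / sd
    z_f4 = (table.power_db[(channels[1], "theta")] - mu) / sd
    return ThetaSummary(theta_z_f3=float(z_f3), theta_z_f4=float(z_f4))


def rem_theta_summary(recording: Recording, hypnogram, artifacts,
                      config: AnalysisConfig | None = None) -> ThetaSummary:
    """Convenience: REM mask → band table → standardized theta."""
    config = config or AnalysisConfig()
    mask = build_epoch_mask(hypnogram, artifacts, stages_wanted={"REM"},
                            artifact_cutoff_s=config.epoch_artifact_cutoff_s,
                            artifact_rule=config.artifact_rule)
    table = rem_band_power_table(recording, mask, config)
    return standardize_theta(table)
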