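"""End-to-end night analysis: recording → per-channel events → SubjectSummary."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_psg import AnalysisConfig, ArtifactSet, Hypnogram, Recording
from .lateralization_stats import SubjectSummary, lateralization_index
from .preprocess import (NREM_STAGES, build_epoch_mask, included_minutes,
                         preprocess_recording)
from .rem_spectral import rem_band_power_table, standardize_theta
from .so_coupling import (CouplingSummary, coupling_summary, detect_sos,
                          pair_so_spindles, so_phase)
from .spindles import compute_thresholds, detect_spindles, spindle_band_filter

logger = logging.getLogger(__name__)

__all__ = ["NightResult", "analyze_night", "summaries_to_frame"]

ANALYSIS_CHANNELS = ("F3", "F4", "C3", "C4")


@dataclass
class NightResult:
    summary: SubjectSummary
    spindles: dict = field(default_factory=dict)       # channel -> list[SpindleEvent]
    sos: dict = field(default_factory=dict)            # channel -> list[SOEvent]
    pairs: dict = field(default_factory=dict)          # channel -> list[SOSpindlePair]
    coupling: dict = field(default_factory=dict)       # channel -> CouplingSummary|None
    densities: dict = field(default_factory=dict)      # channel -> events/min
    nrem_minutes: float = 0.0


def analyze_night(recording: Recording, hypnogram: Hypnogram,
                  artifacts: ArtifactSet, config: AnalysisConfig | None = None,
                  subject: str = "s01", preprocess: bool = True) -> NightResult:
    """Run the full oscillatory analysis of one night.

    Broadband filtering + mastoid re-referencing, NREM spindle and SO
    detection with SO–spindle coupling on F3/F4/C3/C4, REM theta
    standardization, and the three frontal lateralization indices.
    """
    config = config or AnalysisConfig()
    hypnogram.check_against(recording)
    rec = preprocess_recording(recording, config.broadband_transition[0],
                               config.broadband_transition[1]) if preprocess else recording
    fs = rec.sampling_rate

    nrem_mask = build_epoch_mask(hypnogram, artifacts, NREM_STAGES,
                                 config.epoch_artifact_cutoff_s,
                                 config.artifact_rule)
    minutes = included_minutes(
        nrem_mask, artifact_corrected=config.density_denominator == "artifact_corrected")

    result = NightResult(summary=SubjectSummary(subject=subject),
                         nrem_minutes=minutes)
    for ch in ANALYSIS_CHANNELS:
        x = rec.get(ch)
        xf = spindle_band_filter(x, fs, config.spindle_band,
                                 config.spindle_filter_order_at_256)
        thr = compute_thresholds(xf, nrem_mask, fs, channel=ch, config=config)
        events = detect_spindles(xf, thr, nrem_mask, fs, config)
        result.spindles[ch] = events
        result.densities[ch] = len(events) / minutes if minutes > 0 else np.nan

        sos = detect_sos(x, fs, nrem_mask, config, channel=ch)
        result.sos[ch] = sos
        phase = so_phase(x, fs, config.so_band)
        pairs = pair_so_spindles(sos, events, phase, fs)
        result.pairs[ch] = pairs
        result.coupling[ch] = coupling_summary(pairs, channel=ch)

    s = result.summary
    s.spindle_density_frontal = float(np.mean([result.densities["F3"],
                                               result.densities["F4"]]))
    s.spindle_density_central = float(np.mean([result.densities["C3"],
                                               result.densities["C4"]]))

    def dist(ch: str) -> float:
        cs: CouplingSummary | None = result.coupling[ch]
        return cs.mean_distance_rad if cs is not None else np.nan

    s.coupling_distance_frontal = float(np.nanmean([dist("F3"), dist("F4")]))
    s.coupling_distance_central = float(np.nanmean([dist("C3"), dist("C4")]))

    rem_mask = build_epoch_mask(hypnogram, artifacts, {"REM"},
                                config.epoch_artifact_cutoff_s,
                                config.artifact_rule)
    try:
        table = rem_band_power_table(rec, rem_mask, config)
        theta = standardize_theta(table)
        s.rem_theta = theta.rem_theta
        s.theta_lat = lateralization_index(theta.theta_z_f4, theta.theta_z_f3,
                                           config.lat_guard_eps)
    except ValueError as exc:
        logger.warning("REM spectral analysis unavailable: %s", exc)

    s.spindle_lat = lateralization_index(result.densities["F4"],
                                         result.densities["F3"],
                                         config.lat_guard_eps)
    s.coupling_lat = lateralization_index(dist("F4"), dist("F3"),
                                          config.lat_guard_eps)
    return result


def summaries_to_frame(summaries: list[SubjectSummary]) -> pd.DataFrame:
    from dataclasses import asdict

    return pd.DataFrame([asdict(s) for s in summaries])
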