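"""I/O layer for the polysomnography pipeline.

Signals travel as EDF (read through MNE, written by a minimal built-in
16-bit EDF writer); hypnograms, artifact annotations, event tables and
subject summaries are plain delimited text.  All time coordinates are
seconds from recording start and intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import datetime as _dt
import struct
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Recording",
    "Hypnogram",
    "ArtifactSet",
    "AnalysisConfig",
    "STAGES",
    "ChannelError",
    "FormatError",
    "HypnogramParseError",
    "read_recording",
    "write_recording",
    "read_hypnogram",
    "write_hypnogram",
    "read_artifacts",
    "write_artifacts",
    "write_event_tables",
    "read_event_table",
    "load_config",
]

STAGES = ("W", "N1", "N2", "N3", "REM")

#: default hypnogram token normalization (DOMINO-style and numeric dialects)
DEFAULT_STAGE_TOKENS: Mapping[str, str] = {
    "W": "W", "WAKE": "W", "0": "W",
    "N1": "N1", "S1": "N1", "1": "N1", "NREM1": "N1",
    "N2": "N2", "S2": "N2", "2": "N2", "NREM2": "N2",
    "N3": "N3", "S3": "N3", "S4": "N3", "3": "N3", "4": "N3", "NREM3": "N3", "SWS": "N3",
    "REM": "REM", "R": "REM", "5": "REM",
}


class ChannelError(KeyError):
    """A required channel label could not be resolved."""


class FormatError(ValueError):
    """A file could not be parsed in the expected format."""


class HypnogramParseError(ValueError):
    """A hypnogram token was not recognized."""


def _norm_label(label: str) -> str:
    """Normalize an EDF channel label: case-insensitive, strip 'EEG ' prefix
    and reference decorations like '-A1' / '-A2' / '-REF'."""
    s = label.strip().upper()
    if s.startswith("EEG "):
        s = s[4:]
    for suffix in ("-A1", "-A2", "-M1", "-M2", "-REF", "-LE"):
        if s.endswith(suffix):
            s = s[: -len(suffix)]
            break
    return s.strip()


@dataclass
class Recording:
    """Multichannel EEG in microvolts at a fixed sampling rate."""

    channel_labels: list[str]
    sampling_rate: float
    data: np.ndarray  # (n_channels, n_samples), μV
    start_time: _dt.datetime | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise ValueError("data must be (n_channels, n_samples) matching labels")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel_index(self, label: str) -> int:
        want = _norm_label(label)
        for i, lab in enumerate(self.channel_labels):
            if _norm_label(lab) == want:
                return i
        raise ChannelError(label)

    def get(self, label: str) -> np.ndarray:
        return self.data[self.channel_index(label)]

    def has_channel(self, label: str) -> bool:
        try:
            self.channel_index(label)
            return True
        except ChannelError:
            return False


@dataclass
class Hypnogram:
    """Ordered 30-s sleep-stage labels."""

    stages: list[str]
    epoch_length: float = 30.0

    def __post_init__(self) -> None:
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        if not self.epoch_length > 0:
            raise ValueError("epoch_length must be positive")

    def __len__(self) -> int:
        return len(self.stages)

    def epoch_bounds(self, i: int) -> tuple[float, float]:
        return i * self.epoch_length, (i + 1) * self.epoch_length

    def check_against(self, recording: Recording) -> None:
        """Hypnogram may not exceed the recording by more than one epoch."""
        if len(self) * self.epoch_length > recording.duration_s + self.epoch_length:
            raise ValueError(
                f"hypnogram covers {len(self) * self.epoch_length:.0f} s but "
                f"recording lasts {recording.duration_s:.0f} s"
            )


@dataclass
class ArtifactSet:
    """Artifact intervals in recording time; overlaps are merged on use."""

    intervals: list[tuple[float, float]] = field(default_factory=list)
    channel_scope: list[str | None] | None = None

    def __post_init__(self) -> None:
        for s, e in self.intervals:
            if not s < e:
                raise ValueError(f"artifact interval must satisfy start < end: ({s}, {e})")

    def merged(self) -> list[tuple[float, float]]:
        """Return non-overlapping intervals sorted by start."""
        if not self.intervals:
            return []
        ivs = sorted(self.intervals)
        out = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        return [(s, e) for s, e in out]

    def overlap_s(self, start: float, end: float) -> float:
        """Total artifact time inside [start, end)."""
        return sum(max(0.0, min(e, end) - max(s, start)) for s, e in self.merged())


def _band(lo: float, hi: float) -> tuple[float, float]:
    if not 0 <= lo < hi:
        raise ValueError(f"invalid band ({lo}, {hi})")
    return (lo, hi)


@dataclass
class AnalysisConfig:
    """All tunable constants of the detection/spectral pipeline.

    Defaults follow the published analysis settings; see docs/methods.md.
    """

    broadband: tuple[float, float] = (0.2, 35.0)
    broadband_transition: tuple[float, float] = (0.1, 35.1)  # −6 dB points
    spindle_band: tuple[float, float] = (13.0, 16.0)
    spindle_filter_order_at_256: int = 2816
    so_band: tuple[float, float] = (0.2, 1.25)
    so_lowpass_hz: float = 3.5
    psd_bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "delta": (0.5, 4.0),
            "theta": (4.0, 7.0),
            "alpha": (8.0, 12.0),
            "sigma": (12.0, 16.0),
            "beta1": (16.0, 22.0),
            "beta2": (22.0, 30.0),
        }
    )
    upper_mult: float = 5.0
    lower_mult: float = 2.0
    spindle_min_dur_s: float = 0.5
    spindle_max_dur_s: float = 3.0
    spindle_flank_s: float = 0.25
    spindle_gap_ms: float = 78.1
    spindle_max_amp_uv: float = 200.0
    spindle_amplitude: str = "rectified"  # mean over 'rectified' trace or 'envelope'
    so_dur_s: tuple[float, float] = (0.8, 5.0)
    epoch_artifact_cutoff_s: float = 8.0
    artifact_rule: str = "sum"  # 'sum' or 'single'
    density_denominator: str = "epochs"  # 'epochs' or 'artifact_corrected'
    psd_nperseg: int = 1024
    psd_scale: str = "db"  # 'db' or 'linear'
    dprime_correction: str = "half_count"  # '1/(2n)' rule, or 'loglinear'
    lat_guard_eps: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        for b in (self.broadband, self.spindle_band, self.so_band, self.so_dur_s,
                  *self.psd_bands.values()):
            _band(*b)
        for v in (self.upper_mult, self.lower_mult, self.spindle_min_dur_s,
                  self.spindle_max_dur_s, self.spindle_flank_s, self.spindle_gap_ms,
                  self.spindle_max_amp_uv, self.so_lowpass_hz,
                  self.epoch_artifact_cutoff_s):
            if not v > 0:
                raise ValueError("all limits must be strictly positive")
        if not self.spindle_min_dur_s < self.spindle_max_dur_s:
            raise ValueError("spindle duration min must be < max")


def load_config(path: str | Path | None = None, **overrides) -> AnalysisConfig:
    """Load an AnalysisConfig from YAML/JSON, with keyword overrides."""
    params: dict = {}
    if path is not None:
        with open(path) as fh:
            params = yaml.safe_load(fh) or {}
    params.update(overrides)
    # YAML gives lists where tuples are expected
    for key in ("broadband", "broadband_transition", "spindle_band", "so_band", "so_dur_s"):
        if key in params:
            params[key] = tuple(params[key])
    if "psd_bands" in params:
        params["psd_bands"] = {k: tuple(v) for k, v in params["psd_bands"].items()}
    return AnalysisConfig(**params)


def save_config(config: AnalysisConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# EDF I/O
# ---------------------------------------------------------------------------

REQUIRED_CHANNELS = ("F3", "F4", "C3", "C4", "A1", "A2")


def write_recording(recording: Recording, path: str | Path) -> None:
    """Write a Recording as plain EDF (16-bit, one 1-s data record per second).

    Physical range per channel is the symmetric data extremum; digital range
    is ±32767, so quantization error is at most one step of the scaling.
    """
    path = Path(path)
    fs = recording.sampling_rate
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    nchan = len(recording.channel_labels)
    nrec = int(np.ceil(recording.n_samples / spr))
    data = np.zeros((nchan, nrec * spr))
    data[:, : recording.n_samples] = recording.data

    phys_max = np.maximum(np.abs(data).max(axis=1), 1.0)
    dig_max = 32767

    start = recording.start_time or _dt.datetime(2020, 6, 15, 23, 0, 0)
    hdr = b""
    hdr += b"0       "                                      # version
    hdr += f"{'synthetic subject':<80.80}".encode()
    hdr += f"{'Startdate ' + start.strftime('%d-%b-%Y').upper():<80.80}".encode()
    hdr += start.strftime("%d.%m.%y").encode()
    hdr += start.strftime("%H.%M.%S").encode()
    hdr += f"{256 * (nchan + 1):<8d}".encode()              # header bytes
    hdr += b" " * 44                                        # reserved
    hdr += f"{nrec:<8d}".encode()
    hdr += f"{1:<8g}".encode()                              # record duration (s)
    hdr += f"{nchan:<4d}".encode()

    def pad(values: Sequence, width: int) -> bytes:
        return b"".join(f"{v:<{width}.{width}}".encode() for v in map(str, values))

    hdr += pad(recording.channel_labels, 16)
    hdr += pad(["AgAgCl cup electrode"] * nchan, 80)
    hdr += pad(["uV"] * nchan, 8)
    hdr += pad([f"{-m:.6g}" for m in phys_max], 8)
    hdr += pad([f"{m:.6g}" for m in phys_max], 8)
    hdr += pad([-dig_max] * nchan, 8)
    hdr += pad([dig_max] * nchan, 8)
    hdr += pad([""] * nchan, 80)                            # prefiltering
    hdr += pad([spr] * nchan, 8)
    hdr += b" " * (32 * nchan)                              # reserved
    assert len(hdr) == 256 * (nchan + 1)

    gains = dig_max / phys_max
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(nrec):
            block = data[:, r * spr : (r + 1) * spr]
            dig = np.rint(block * gains[:, None]).astype("<i2")
            fh.write(dig.tobytes())


def read_recording(path: str | Path, strict: bool = True,
                   required: Sequence[str] = REQUIRED_CHANNELS) -> Recording:
    """Read an EDF/EDF+ file into a Recording (μV).

    With ``strict=True`` every channel in ``required`` must be resolvable
    (case-insensitively, ignoring 'EEG ' prefixes), else ChannelError.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises a mix of types on malformed files
        raise FormatError(f"cannot parse {path} as EDF: {exc}") from exc
    data_uv = raw.get_data() * 1e6
    meas_date = raw.info.get("meas_date")
    start = None
    if meas_date is not None:
        start = _dt.datetime(meas_date.year, meas_date.month, meas_date.day,
                             meas_date.hour, meas_date.minute, meas_date.second)
    rec = Recording(
        channel_labels=list(raw.ch_names),
        sampling_rate=float(raw.info["sfreq"]),
        data=data_uv,
        start_time=start,
    )
    if strict:
        for label in required:
            if not rec.has_channel(label):
                raise ChannelError(label)
    return rec


# ---------------------------------------------------------------------------
# Hypnogram / artifact tables
# ---------------------------------------------------------------------------

def read_hypnogram(path: str | Path, epoch_length: float = 30.0,
                   token_map: Mapping[str, str] | None = None,
                   delimiter: str | None = None) -> Hypnogram:
    """Read a hypnogram from delimited text (one token per 30-s epoch).

    Tokens may be separated by newlines, commas, tabs or spaces.  Unknown
    tokens raise HypnogramParseError with the line number.
    """
    mapping = dict(DEFAULT_STAGE_TOKENS)
    if token_map:
        mapping.update({k.upper(): v for k, v in token_map.items()})
    stages: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split(delimiter) if delimiter else line.replace(",", " ").replace("\t", " ").split()
            for tok in tokens:
                key = tok.strip().upper()
                if key not in mapping:
                    raise HypnogramParseError(f"unknown stage token {tok!r} at line {lineno}")
                stages.append(mapping[key])
    return Hypnogram(stages=stages, epoch_length=epoch_length)


def write_hypnogram(hyp: Hypnogram, path: str | Path) -> None:
    Path(path).write_text("\n".join(hyp.stages) + "\n")


def read_artifacts(path: str | Path) -> ArtifactSet:
    """Read artifact intervals from TSV with columns start_s, end_s[, channel]."""
    df = pd.read_csv(path, sep="\t")
    intervals = list(zip(df["start_s"].astype(float), df["end_s"].astype(float)))
    scope = list(df["channel"]) if "channel" in df.columns else None
    return ArtifactSet(intervals=intervals, channel_scope=scope)


def write_artifacts(artifacts: ArtifactSet, path: str | Path) -> None:
    rows = {"start_s": [s for s, _ in artifacts.intervals],
            "end_s": [e for _, e in artifacts.intervals]}
    if artifacts.channel_scope is not None:
        rows["channel"] = artifacts.channel_scope
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------

EVENT_COLUMNS = ["subject", "channel", "start_s", "end_s", "peak_s",
                 "amplitude_uv", "duration_s"]
PAIR_COLUMNS = EVENT_COLUMNS + ["phase_rad", "distance_rad"]


def write_event_tables(events: Sequence, path: str | Path,
                       subject: str = "s01") -> None:
    """Write detected events (spindles, SOs or SO–spindle pairs) as TSV.

    Column order is fixed; floats carry 6 decimals, so a write→read round
    trip reproduces times to 1e-6 s.
    """
    rows = []
    has_phase = False
    for ev in events:
        row = {
            "subject": getattr(ev, "subject", subject),
            "channel": ev.channel,
            "start_s": ev.start_s,
            "end_s": ev.end_s,
            "peak_s": ev.peak_s,
            "amplitude_uv": getattr(ev, "peak_amplitude_uv", getattr(ev, "p2p_uv", np.nan)),
            "duration_s": ev.duration_s,
        }
        if hasattr(ev, "phase_rad"):
            has_phase = True
            row["phase_rad"] = ev.phase_rad
            row["distance_rad"] = ev.distance_rad
        rows.append(row)
    cols = PAIR_COLUMNS if has_phase else EVENT_COLUMNS
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_event_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
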