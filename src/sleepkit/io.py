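"""Readers and writers for the formats the pipeline touches.

EDF reading goes through MNE (EDF/EDF+, case-insensitive channel selection).
EDF *writing* is a minimal built-in single-channel 16-bit writer sufficient
for synthetic recordings (1-s data records); signals are expressed in
microvolts on both paths. Hypnograms, activity counts and index tables use
plain CSV (comma-separated, UTF-8, mandatory header). Pipeline settings are
a JSON config that round-trips bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .actigraphy import NAT_BAND, SADEH_COEFFS, ActivitySeries
from .exceptions import ChannelNotFoundError
from .stages import STAGE_CODES, Hypnogram

__all__ = [
    "RecordingBundle",
    "read_edf",
    "write_edf",
    "read_reference_hypnogram",
    "write_hypnogram_csv",
    "read_hypnogram_csv",
    "read_activity_csv",
    "write_activity_csv",
    "PipelineConfig",
]

#: reference annotation alphabet (R&K plus movement/unscored)
REFERENCE_ALPHABET = {"W", "R", "1", "2", "3", "4", "M", "?"}


@dataclass
class RecordingBundle:
    """One subject-night: EEG samples plus optional companions."""

    signal: np.ndarray
    sampling_rate_hz: float
    channel: str
    annotations: list | None = None  # raw per-epoch reference labels
    activity: ActivitySeries | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        self.signal = np.asarray(self.signal, dtype=float).ravel()
        if self.annotations is not None:
            span = len(self.annotations) * 30.0
            if span > self.signal.size / self.sampling_rate_hz + 30.0:
                raise ValueError("annotation span exceeds signal span")


# ---------------------------------------------------------------------------
# EDF


def read_edf(path, channel: str | None = None) -> RecordingBundle:
    """Load one channel of an EDF/EDF+ file (case-insensitive label match).

    Returns samples in microvolts. With ``channel=None`` the first channel is
    used. A missing channel raises :class:`ChannelNotFoundError` listing the
    available labels.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    names = raw.ch_names
    if channel is None:
        picked = names[0]
    else:
        matches = [n for n in names if n.lower() == channel.lower()]
        if not matches:
            raise ChannelNotFoundError(
                f"channel {channel!r} not found; available: {names}"
            )
        picked = matches[0]
    data = raw.get_data(picks=[picked])[0] * 1e6  # MNE loads volts
    return RecordingBundle(
        signal=data, sampling_rate_hz=float(raw.info["sfreq"]), channel=picked
    )


def write_edf(path, signal, sampling_rate_hz: float, channel: str = "EEG Fpz-Cz") -> None:
    """Write a single-channel 16-bit EDF file (1-second data records).

    ``signal`` is interpreted as microvolts. The sampling rate must be a
    positive integer (samples per 1-s record); a trailing partial second is
    dropped.
    """
    fs = int(round(sampling_rate_hz))
    if fs <= 0 or abs(fs - sampling_rate_hz) > 1e-9:
        raise ValueError("EDF writer needs an integer sampling rate")
    x = np.asarray(signal, dtype=float).ravel()
    n_records = x.size // fs
    if n_records < 1:
        raise ValueError("signal shorter than one 1-s EDF record")
    x = x[: n_records * fs]

    pmax = float(np.max(np.abs(x)))
    pmax = pmax if pmax > 0 else 1.0
    dig_min, dig_max = -32768, 32767
    scaled = np.round((x / pmax) * dig_max).clip(dig_min, dig_max).astype("<i2")

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),  # patient id
            pad("Startdate X X X X", 80),  # recording id
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 * 2), 8),  # header bytes: fixed + 1 signal
            pad("", 44),
            pad(str(n_records), 8),
            pad("1", 8),  # record duration, seconds
            pad("1", 4),  # number of signals
            pad(channel, 16),
            pad("", 80),  # transducer
            pad("uV", 8),
            pad(f"{-pmax:.6g}", 8),
            pad(f"{pmax:.6g}", 8),
            pad(str(dig_min), 8),
            pad(str(dig_max), 8),
            pad("", 80),  # prefiltering
            pad(str(fs), 8),
            pad("", 32),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(scaled.tobytes())


# ---------------------------------------------------------------------------
# reference hypnograms


def _expand_annotations(onsets, durations, labels, epoch_seconds: float) -> list[str]:
    order = np.argsort(onsets)
    out: list[str] = []
    prev_end = None
    for i in order:
        onset, dur, lab = float(onsets[i]), float(durations[i]), str(labels[i])
        if prev_end is not None and onset < prev_end - 1e-6:
            raise ValueError(
                f"overlapping annotations at {onset:.1f}s (previous ends {prev_end:.1f}s)"
            )
        prev_end = onset + dur
        token = lab.strip().upper()
        if token.startswith("SLEEP STAGE"):
            token = token.split()[-1]
        elif token == "MOVEMENT TIME":
            token = "M"
        if token not in REFERENCE_ALPHABET:
            raise ValueError(f"unrecognized reference label {lab!r}")
        out.extend([token] * int(dur // epoch_seconds))
    if not out:
        raise ValueError("no complete scoring epochs in annotation file")
    return out


def read_reference_hypnogram(path, epoch_seconds: float = 30.0) -> list[str]:
    """Expand a reference annotation file into per-epoch stage labels.

    Accepts EDF+ annotation files (Sleep-EDFx style, via MNE) or a CSV with
    columns ``onset_seconds, duration_seconds, stage``. Labels are returned
    over the alphabet {W, R, 1, 2, 3, 4, M, ?}; movement/unscored epochs are
    retained for pairwise exclusion downstream.
    """
    p = Path(path)
    if p.suffix.lower() == ".csv":
        df = pd.read_csv(p)
        required = {"onset_seconds", "duration_seconds", "stage"}
        if not required.issubset(df.columns):
            raise ValueError(f"annotation CSV needs columns {sorted(required)}")
        return _expand_annotations(
            df["onset_seconds"].to_numpy(),
            df["duration_seconds"].to_numpy(),
            df["stage"].tolist(),
            epoch_seconds,
        )
    import mne

    ann = mne.read_annotations(str(p))
    return _expand_annotations(ann.onset, ann.duration, ann.description, epoch_seconds)


# ---------------------------------------------------------------------------
# hypnogram / activity CSV


def write_hypnogram_csv(hyp: Hypnogram, path) -> None:
    """Columns: epoch_index (0-based), onset_seconds, stage in {W,R,L,D}."""
    df = pd.DataFrame(
        {
            "epoch_index": np.arange(len(hyp)),
            "onset_seconds": np.arange(len(hyp)) * hyp.epoch_seconds,
            "stage": hyp.codes,
        }
    )
    df.to_csv(path, index=False)


def read_hypnogram_csv(path) -> Hypnogram:
    df = pd.read_csv(path)
    if "stage" not in df.columns:
        raise ValueError("hypnogram CSV needs a 'stage' column")
    code_to_idx = {c: i for i, c in enumerate(STAGE_CODES)}
    try:
        stages = [code_to_idx[str(s).strip().upper()] for s in df["stage"]]
    except KeyError as exc:
        raise ValueError(f"unknown stage code {exc.args[0]!r}") from exc
    epoch_seconds = 30.0
    if "onset_seconds" in df.columns and len(df) > 1:
        epoch_seconds = float(df["onset_seconds"].iloc[1] - df["onset_seconds"].iloc[0])
    return Hypnogram(np.asarray(stages, dtype=np.int8), epoch_seconds=epoch_seconds)


def write_activity_csv(series: ActivitySeries, path) -> None:
    df = pd.DataFrame(
        {
            "timestamp_min": series.start_time_min + np.arange(len(series)),
            "axis1_counts": series.counts,
        }
    )
    df.to_csv(path, index=False)


def read_activity_csv(path) -> ActivitySeries:
    df = pd.read_csv(path)
    if "axis1_counts" not in df.columns:
        raise ValueError("activity CSV needs an 'axis1_counts' column")
    start = float(df["timestamp_min"].iloc[0]) if "timestamp_min" in df.columns else 0.0
    return ActivitySeries(df["axis1_counts"].to_numpy(dtype=float), start_time_min=start)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """JSON-serializable settings for the scoring pipeline."""

    bands: list = field(
        default_factory=lambda: [
            ["wake", 35.0, 50.0],
            ["rem", 20.0, 30.0],
            ["light", 10.15, 15.75],
            ["deep", 1.0, 3.0],
        ]
    )
    epoch_seconds: float = 30.0
    em_max_iter: int = 100
    em_tol: float = 1e-6
    update_startprob: bool = True
    rnr_include_wake: bool = False
    ssi_within_sleep_only: bool = False
    sadeh_coeffs: dict = field(default_factory=lambda: dict(SADEH_COEFFS))
    nat_band: list = field(default_factory=lambda: list(NAT_BAND))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_json(Path(path).read_text())
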