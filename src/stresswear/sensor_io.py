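"""On-disk artifacts: E4-style channel CSVs, stress traces, feature tables, reports.

The channel dialect is the Empatica E4 export convention: one CSV per
channel (``EDA.csv``/``HR.csv``/``TEMP.csv``), row 1 the UNIX start time in
seconds, row 2 the sampling rate in Hz, rows 3+ one sample each.  A blank
field or the literal ``NaN`` marks a missing sample; missing values are
written back as empty fields.  All timestamps are plain epoch seconds — no
time-zone handling.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from stresswear.errors import (
    FormatError,
    OrderingError,
    RangeError,
    SchemaError,
    ValidationError,
)
from stresswear.features import FeatureTable, META_COLUMNS, validate_feature_columns

CHANNELS = ("EDA", "HR", "TEMP")
CHANNEL_UNITS = {"EDA": "µS", "HR": "bpm", "TEMP": "°C"}


@dataclasses.dataclass
class ChannelRecording:
    """One sensor channel: EDA (µS), HR (beats/min) or TEMP (°C).

    ``samples`` is a float vector with NaN as the missing marker.
    """

    channel: str
    start_time: float
    rate: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValidationError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")
        if not self.rate > 0:
            raise ValidationError(f"sampling rate must be positive, got {self.rate}")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size < 1:
            raise ValidationError("a recording needs at least one sample")
        finite_ok = np.isfinite(self.samples) | np.isnan(self.samples)
        if not finite_ok.all():
            raise ValidationError("non-missing samples must be finite")
        if self.channel == "EDA":
            observed = self.samples[~np.isnan(self.samples)]
            if observed.size and (observed < 0).any():
                raise ValidationError("EDA (skin conductance) cannot be negative")

    @property
    def units(self) -> str:
        return CHANNEL_UNITS[self.channel]

    @property
    def duration(self) -> float:
        """Time span covered by the samples, in seconds."""
        return (self.samples.size - 1) / self.rate

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration


@dataclasses.dataclass
class StressTrace:
    """Continuous observer-style stress annotation on [0, 1]."""

    timestamps: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.size != self.values.size:
            raise ValidationError("timestamps and values must have equal length")
        if np.any(np.diff(self.timestamps) <= 0):
            raise OrderingError("stress-trace timestamps must be strictly increasing")
        if np.any((self.values < 0) | (self.values > 1)) or not np.isfinite(self.values).all():
            raise RangeError("stress values must lie in [0, 1]")


@dataclasses.dataclass
class SessionRecording:
    """All three channels for one subject plus optional scenario metadata.

    ``segment_boundaries``, when present, is a strictly increasing list of
    7 timestamps delimiting the six scenario segments; ``success`` is the
    subject's treatment-success flag from the debriefing.
    """

    subject_id: str
    channels: dict[str, ChannelRecording]
    segment_boundaries: Optional[list[float]] = None
    success: Optional[bool] = None

    def __post_init__(self) -> None:
        missing = set(CHANNELS) - set(self.channels)
        if missing:
            raise ValidationError(f"session {self.subject_id}: missing channels {sorted(missing)}")
        start = max(rec.start_time for rec in self.channels.values())
        end = min(rec.end_time for rec in self.channels.values())
        if end <= start:
            raise ValidationError(f"session {self.subject_id}: channel spans do not overlap")
        if self.segment_boundaries is not None:
            b = np.asarray(self.segment_boundaries, dtype=float)
            if b.size != 7 or np.any(np.diff(b) <= 0):
                raise ValidationError("segment_boundaries must be 7 strictly increasing timestamps")


def _parse_float(token: str, path, line_no: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise FormatError(f"{path}, line {line_no}: cannot parse {token!r} as a number") from None


def read_channel_csv(path, channel: str) -> ChannelRecording:
    """Read one E4-style channel CSV.

    Row 1 is the UNIX start time, row 2 the sampling rate (Hz), remaining
    rows one sample each.  Blank fields or ``NaN`` become missing samples;
    no data line is ever dropped, so ``samples`` has exactly one entry per
    data row.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 2:
        raise FormatError(f"{path}: expected a start-time row and a rate row")
    start_time = _parse_float(lines[0].strip(), path, 1)
    rate = _parse_float(lines[1].strip(), path, 2)
    if rate <= 0:
        raise ValidationError(f"{path}: sampling rate must be positive, got {rate}")
    samples = np.empty(len(lines) - 2, dtype=float)
    for i, raw in enumerate(lines[2:], start=3):
        token = raw.strip()
        if token == "" or token.lower() == "nan":
            samples[i - 3] = np.nan
        else:
            samples[i - 3] = _parse_float(token, path, i)
    if samples.size == 0:
        raise FormatError(f"{path}: no sample rows")
    return ChannelRecording(channel=channel, start_time=start_time, rate=rate, samples=samples)


def write_channel_csv(rec: ChannelRecording, path) -> None:
    """Write a ChannelRecording in the E4 export dialect (missing → empty field)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{rec.start_time:.12g}\n{rec.rate:.12g}\n")
        for x in rec.samples:
            fh.write("\n" if np.isnan(x) else f"{x:.12g}\n")


def read_stress_trace(path) -> StressTrace:
    """Read a two-column (timestamp, value) CSV stress annotation.

    Values outside [0, 1] are rejected, not clipped; tied or decreasing
    timestamps raise an ordering error.
    """
    df = pd.read_csv(path, header=None, names=["timestamp", "value"])
    if df.shape[1] != 2 or df.isna().any().any():
        raise FormatError(f"{path}: expected a two-column numeric (timestamp, value) CSV")
    return StressTrace(timestamps=df["timestamp"].to_numpy(), values=df["value"].to_numpy())


def write_stress_trace(trace: StressTrace, path) -> None:
    pd.DataFrame({"timestamp": trace.timestamps, "value": trace.values}).to_csv(
        path, header=False, index=False, float_format="%.12g"
    )


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a feature table as headered CSV (12 significant digits)."""
    frame = table.frame
    if frame.columns.duplicated().any():
        raise SchemaError("feature table column names must be unique")
    frame.to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path) -> FeatureTable:
    """Read a feature-table CSV written by :func:`write_feature_table`.

    The header must carry the canonical feature names (``EDA_Mean``,
    ``HR_Std``, ``TEMP_Max``, ``EDA_Mean_lag3``, ...); any unknown column is
    a schema error.
    """
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # malformed / empty file
        raise SchemaError(f"{path}: cannot parse feature table ({exc})") from exc
    feature_cols = [c for c in frame.columns if c not in META_COLUMNS]
    if not feature_cols:
        raise SchemaError(f"{path}: no feature columns found (missing header?)")
    validate_feature_columns(feature_cols)
    if not all(np.issubdtype(frame[c].dtype, np.number) for c in feature_cols):
        raise SchemaError(f"{path}: non-numeric feature column (missing header?)")
    return FeatureTable(frame=frame)


def write_report_json(report: dict, path) -> None:
    """Write a machine-readable report (plain JSON, keys sorted)."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True, default=float) + "\n")
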