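"""Bring EDA/HR/TEMP to a common 4 Hz grid and impute missing values.

The three E4 channels arrive at different native rates (EDA/TEMP 4 Hz, HR
1 Hz).  Each channel is linearly interpolated onto a uniform grid — the
lower-rate HR stream is upsampled rather than the others downsampled, to
avoid discarding signal — and missing runs are then filled with the
channel's session median.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from stresswear.errors import AlignmentError, InsufficientDataError
from stresswear.sensor_io import ChannelRecording, SessionRecording

DEFAULT_GRID_RATE = 4.0


@dataclasses.dataclass
class AlignedSignals:
    """Session-level matrix of EDA/HR/TEMP on a common uniform time grid."""

    subject_id: str
    grid_start: float
    grid_rate: float
    eda: np.ndarray
    hr: np.ndarray
    temp: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.eda)
        if not (len(self.hr) == len(self.temp) == n) or n < 1:
            raise ValueError("aligned channels must have equal, nonzero length")
        for name in ("eda", "hr", "temp"):
            if not np.isfinite(getattr(self, name)).all():
                raise ValueError(f"aligned {name} contains missing or non-finite values")

    def __len__(self) -> int:
        return len(self.eda)

    @property
    def times(self) -> np.ndarray:
        return self.grid_start + np.arange(len(self)) / self.grid_rate

    def channel(self, name: str) -> np.ndarray:
        return {"EDA": self.eda, "HR": self.hr, "TEMP": self.temp}[name]


def _interp_to_grid(rec: ChannelRecording, grid_times: np.ndarray) -> np.ndarray:
    """Linear interpolation of a recording onto explicit grid times.

    Interpolation uses non-missing samples only.  A grid point whose
    bracketing input samples (at the native rate) are all missing lies
    inside a missing run and stays missing, so gaps are not silently
    invented by interpolation.
    """
    observed = ~np.isnan(rec.samples)
    if observed.sum() < 2:
        raise InsufficientDataError(
            f"channel {rec.channel}: need >= 2 non-missing samples to resample"
        )
    times = rec.start_time + np.arange(rec.samples.size) / rec.rate
    out = np.interp(grid_times, times[observed], rec.samples[observed])

    # Re-mark grid points that fall inside a run of missing input samples.
    rel = (grid_times - rec.start_time) * rec.rate
    lo = np.clip(np.floor(rel + 1e-9).astype(int), 0, rec.samples.size - 1)
    hi = np.clip(np.ceil(rel - 1e-9).astype(int), 0, rec.samples.size - 1)
    in_gap = np.isnan(rec.samples[lo]) & np.isnan(rec.samples[hi])
    out[in_gap] = np.nan
    return out


def resample_channel(rec: ChannelRecording, target_rate: float = DEFAULT_GRID_RATE) -> ChannelRecording:
    """Resample one channel to ``target_rate`` by linear interpolation.

    The output grid starts at the recording start, includes both endpoints
    and is truncated to the last full grid point:
    ``length = floor(span * target_rate) + 1`` where span is the input
    duration.  Grid points inside missing runs remain missing.
    """
    span = rec.duration
    n_out = int(np.floor(span * target_rate + 1e-9)) + 1
    grid_times = rec.start_time + np.arange(n_out) / target_rate
    return ChannelRecording(
        channel=rec.channel,
        start_time=rec.start_time,
        rate=target_rate,
        samples=_interp_to_grid(rec, grid_times),
    )


def impute_median(values: np.ndarray) -> np.ndarray:
    """Replace missing entries by the median of the non-missing entries.

    Idempotent; non-missing entries are untouched.
    """
    values = np.asarray(values, dtype=float)
    mask = np.isnan(values)
    if mask.all():
        raise InsufficientDataError("cannot impute an all-missing vector")
    if not mask.any():
        return values.copy()
    out = values.copy()
    out[mask] = np.median(values[~mask])
    return out


def align_session(session: SessionRecording, grid_rate: float = DEFAULT_GRID_RATE) -> AlignedSignals:
    """Resample all three channels onto one grid, then impute per channel.

    The grid is anchored at the latest channel start and truncated to the
    intersection of the three spans (``length = floor(span * rate) + 1``,
    both endpoints included).
    """
    start = max(rec.start_time for rec in session.channels.values())
    end = min(rec.end_time for rec in session.channels.values())
    if end <= start:
        raise AlignmentError(f"session {session.subject_id}: channel spans do not overlap")
    n = int(np.floor((end - start) * grid_rate + 1e-9)) + 1
    grid_times = start + np.arange(n) / grid_rate
    resampled = {
        name: impute_median(_interp_to_grid(rec, grid_times))
        for name, rec in session.channels.items()
    }
    return AlignedSignals(
        subject_id=session.subject_id,
        grid_start=start,
        grid_rate=grid_rate,
        eda=resampled["EDA"],
        hr=resampled["HR"],
        temp=resampled["TEMP"],
    )
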