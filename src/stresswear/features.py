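"""Sliding-window feature engineering for aligned EDA/HR/TEMP signals.

Windows are 40 samples with a 20-sample step (50% overlap at 4 Hz, i.e.
10 s windows every 5 s).  Each window yields 19 features:

* min / max / mean / population std for each of EDA, HR, TEMP (12);
* EDA sample skewness and excess kurtosis (2);
* EDA peak analysis — number of skin-conductance responses, total peak
  prominence ("amplitude", µS) and total peak duration in seconds (3);
* RMS of first differences for HR and TEMP (2).

Lag features append the channel means of the previous 1..max_lag windows
(30 extra columns at the default lag depth of 10), and min-max scaling maps
every column to [0, 1] using training-fold statistics only.
"""

from __future__ import annotations

import dataclasses
import re
import warnings
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import find_peaks, peak_widths

from stresswear.errors import InsufficientDataError, SchemaError

META_COLUMNS = ("subject_id", "segment_id", "window_start")

_CHANNEL_STATS = ("Min", "Max", "Mean", "Std")
_FEATURE_NAME_RE = re.compile(
    r"^(?:(?:EDA|HR|TEMP)_(?:Min|Max|Mean|Std)"
    r"|EDA_(?:Skew|Kurtosis|Peaks|Amplitude|Duration)"
    r"|(?:HR|TEMP)_RMS"
    r"|(?:EDA|HR|TEMP)_Mean_lag[1-9]\d*)$"
)


def current_window_columns() -> list[str]:
    """Canonical order of the 19 current-window feature names."""
    cols = [f"EDA_{s}" for s in _CHANNEL_STATS]
    cols += ["EDA_Skew", "EDA_Kurtosis", "EDA_Peaks", "EDA_Amplitude", "EDA_Duration"]
    cols += [f"HR_{s}" for s in _CHANNEL_STATS] + ["HR_RMS"]
    cols += [f"TEMP_{s}" for s in _CHANNEL_STATS] + ["TEMP_RMS"]
    return cols


def lag_columns(max_lag: int) -> list[str]:
    return [f"{sig}_Mean_lag{k}" for k in range(1, max_lag + 1) for sig in ("EDA", "HR", "TEMP")]


def validate_feature_columns(columns: Iterable[str]) -> None:
    unknown = [c for c in columns if not _FEATURE_NAME_RE.match(c)]
    if unknown:
        raise SchemaError(f"unknown feature columns: {unknown}")


@dataclasses.dataclass
class FeatureConfig:
    """Windowing and EDA peak-detection parameters.

    window_size/step are in samples on the 4 Hz grid; max_lag counts
    windows; peak_prominence is the minimum topographic prominence (µS) for
    a local maximum to count as a skin-conductance response, and
    peak_width_fraction is the fraction of the prominence below the peak
    height at which the peak's duration is measured (0.5 = width at half
    prominence).
    """

    window_size: int = 40
    step: int = 20
    max_lag: int = 10
    peak_prominence: float = 0.01
    peak_width_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.step <= self.window_size):
            raise ValueError("need 0 < step <= window_size")
        if self.max_lag < 0:
            raise ValueError("max_lag must be >= 0")
        if self.peak_prominence <= 0:
            raise ValueError("peak_prominence must be > 0")


@dataclasses.dataclass
class FeatureTable:
    """Per-window feature vectors plus subject/segment/window metadata.

    Backed by a DataFrame whose leading columns are the metadata
    (``subject_id``, ``segment_id``, ``window_start`` in epoch seconds)
    followed by canonically named feature columns, rows ordered by window
    start within each subject.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if "window_start" not in self.frame.columns:
            raise SchemaError("feature table needs a window_start column")
        validate_feature_columns(self.feature_columns)
        feats = self.frame[self.feature_columns]
        if len(feats) and not np.isfinite(feats.to_numpy(dtype=float)).all():
            raise ValueError("feature table contains non-finite entries")

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in META_COLUMNS]

    @property
    def features(self) -> pd.DataFrame:
        return self.frame[self.feature_columns]

    @property
    def window_start(self) -> np.ndarray:
        return self.frame["window_start"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.frame)

    def with_features(self, values: np.ndarray) -> "FeatureTable":
        """Copy of the table with feature values replaced (same columns)."""
        frame = self.frame.copy()
        frame[self.feature_columns] = values
        return FeatureTable(frame=frame)


def make_windows(n_samples: int, cfg: FeatureConfig) -> list[tuple[int, int]]:
    """Index ranges of the sliding windows over a signal of ``n_samples``.

    Window k covers samples [k*step, k*step + window_size); there are
    floor((N - window_size)/step) + 1 windows.
    """
    if n_samples < cfg.window_size:
        raise InsufficientDataError(
            f"signal has {n_samples} samples, need at least {cfg.window_size}"
        )
    n_win = (n_samples - cfg.window_size) // cfg.step + 1
    return [(k * cfg.step, k * cfg.step + cfg.window_size) for k in range(n_win)]


def rms_first_diff(x: Sequence[float]) -> float:
    """Root mean square of successive differences (short-term variability)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("rms_first_diff needs at least 2 samples")
    return float(np.sqrt(np.mean(np.diff(x) ** 2)))


def eda_peak_features(
    eda: Sequence[float], cfg: FeatureConfig, rate: float = 4.0
) -> tuple[int, float, float]:
    """Skin-conductance-response summary of one EDA window.

    Peaks are strict local maxima with topographic prominence at least
    ``cfg.peak_prominence``.  Returns (count, total prominence in µS, total
    duration in seconds) where each peak's duration is its width at
    ``peak height - peak_width_fraction * prominence``.
    """
    eda = np.asarray(eda, dtype=float)
    peaks, props = find_peaks(eda, prominence=cfg.peak_prominence)
    if peaks.size == 0:
        return 0, 0.0, 0.0
    widths = peak_widths(
        eda,
        peaks,
        rel_height=cfg.peak_width_fraction,
        prominence_data=(props["prominences"], props["left_bases"], props["right_bases"]),
    )[0]
    return int(peaks.size), float(props["prominences"].sum()), float(widths.sum() / rate)


def _moment_shape(windows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sample skewness (Fisher-Pearson) and excess kurtosis per window row.

    Zero-variance windows are defined to have skewness = kurtosis = 0.
    """
    centred = windows - windows.mean(axis=1, keepdims=True)
    m2 = np.mean(centred**2, axis=1)
    m3 = np.mean(centred**3, axis=1)
    m4 = np.mean(centred**4, axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        skew = np.where(m2 > 0, m3 / np.where(m2 > 0, m2, 1.0) ** 1.5, 0.0)
        kurt = np.where(m2 > 0, m4 / np.where(m2 > 0, m2, 1.0) ** 2 - 3.0, 0.0)
    return skew, kurt


def extract_window_features(signals, cfg: FeatureConfig = FeatureConfig()) -> FeatureTable:
    """Compute the 19 current-window features for every sliding window.

    ``signals`` is an :class:`~stresswear.preprocess.AlignedSignals`; the
    result carries the window start times and the session's subject id.
    """
    n = len(signals)
    windows = make_windows(n, cfg)
    starts = np.array([w[0] for w in windows])

    data: dict[str, np.ndarray] = {}
    for name, vec in (("EDA", signals.eda), ("HR", signals.hr), ("TEMP", signals.temp)):
        w = sliding_window_view(vec, cfg.window_size)[:: cfg.step][: len(windows)]
        data[f"{name}_Min"] = w.min(axis=1)
        data[f"{name}_Max"] = w.max(axis=1)
        data[f"{name}_Mean"] = w.mean(axis=1)
        data[f"{name}_Std"] = w.std(axis=1)  # population denominator
        if name == "EDA":
            data["EDA_Skew"], data["EDA_Kurtosis"] = _moment_shape(w)
            peak_stats = np.array(
                [eda_peak_features(row, cfg, rate=signals.grid_rate) for row in w]
            )
            data["EDA_Peaks"] = peak_stats[:, 0]
            data["EDA_Amplitude"] = peak_stats[:, 1]
            data["EDA_Duration"] = peak_stats[:, 2]
        else:
            data[f"{name}_RMS"] = np.sqrt(np.mean(np.diff(w, axis=1) ** 2, axis=1))

    frame = pd.DataFrame({c: data[c] for c in current_window_columns()})
    frame.insert(0, "window_start", signals.grid_start + starts / signals.grid_rate)
    frame.insert(0, "subject_id", signals.subject_id)
    return FeatureTable(frame=frame)


def add_lags(table: FeatureTable, cfg: FeatureConfig = FeatureConfig()) -> FeatureTable:
    """Append lagged channel means and drop windows with incomplete history.

    For lag k in 1..max_lag and each channel, ``{ch}_Mean_lag{k}`` holds the
    channel mean of the window k positions earlier *within the same
    subject*; the first max_lag windows of each subject are dropped rather
    than zero-padded.  A subject with fewer than max_lag + 1 windows
    contributes no rows (warning).
    """
    if cfg.max_lag == 0:
        return FeatureTable(frame=table.frame.copy())
    frame = table.frame.copy()
    if "subject_id" not in frame.columns:
        frame["subject_id"] = ""
    groups = frame.groupby("subject_id", sort=False, group_keys=False)
    for k in range(1, cfg.max_lag + 1):
        for sig in ("EDA", "HR", "TEMP"):
            frame[f"{sig}_Mean_lag{k}"] = groups[f"{sig}_Mean"].shift(k)
    sizes = groups.size()
    short = sizes[sizes < cfg.max_lag + 1]
    if len(short):
        warnings.warn(
            f"subjects with fewer than {cfg.max_lag + 1} windows contribute no rows: "
            f"{list(short.index)}",
            stacklevel=2,
        )
    lag_cols = lag_columns(cfg.max_lag)
    frame = frame.dropna(subset=lag_cols).reset_index(drop=True)
    ordered = [c for c in frame.columns if c in META_COLUMNS]
    ordered += current_window_columns() + lag_cols
    return FeatureTable(frame=frame[ordered])


def minmax_scale(
    train: FeatureTable, others: Sequence[FeatureTable] = (), params: Optional[dict] = None
) -> tuple[FeatureTable, list[FeatureTable], dict[str, tuple[float, float]]]:
    """Min-max scale features to [0, 1] using training statistics only.

    Per column x' = (x - min_train)/(max_train - min_train); a zero-range
    column maps to 0.0 everywhere.  ``others`` are scaled with the training
    parameters and may fall outside [0, 1].  Pass ``params`` to reuse a
    previously fitted scaler.
    """
    if len(train) == 0:
        raise InsufficientDataError("cannot fit a scaler on an empty table")
    cols = train.feature_columns
    if params is None:
        params = {c: (float(train.frame[c].min()), float(train.frame[c].max())) for c in cols}

    def apply(table: FeatureTable) -> FeatureTable:
        values = table.features.to_numpy(dtype=float).copy()
        for j, c in enumerate(table.feature_columns):
            lo, hi = params[c]
            values[:, j] = 0.0 if hi == lo else (values[:, j] - lo) / (hi - lo)
        return table.with_features(values)

    return apply(train), [apply(t) for t in others], params
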