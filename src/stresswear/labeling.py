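"""Convert a continuous [0, 1] stress annotation into classes {0, 1, 2}.

A window's label is the thresholded mean of the stress-trace values falling
inside it: class 0 ("no stress") below theta1, class 1 ("medium") in
[theta1, theta2), class 2 ("high") at or above theta2.  The thresholds
default to the tertile cut-points 1/3 and 2/3 of the annotation scale and
are fully configurable; intervals are left-closed so boundary values are
deterministic.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional

import numpy as np

from stresswear.errors import CoverageError
from stresswear.features import FeatureTable
from stresswear.sensor_io import StressTrace

log = logging.getLogger(__name__)


@dataclasses.dataclass
class LabelConfig:
    theta1: float = 1.0 / 3.0
    theta2: float = 2.0 / 3.0

    def __post_init__(self) -> None:
        if not (0 < self.theta1 < self.theta2 < 1):
            raise ValueError("need 0 < theta1 < theta2 < 1")


@dataclasses.dataclass
class LabeledDataset:
    """Scaled feature rows paired with stress classes and subject/segment ids."""

    features: FeatureTable
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size != len(self.features):
            raise ValueError("labels length must match feature rows")
        if self.labels.size and not np.isin(self.labels, (0, 1, 2)).all():
            raise ValueError("labels must lie in {0, 1, 2}")

    @property
    def X(self) -> np.ndarray:
        return self.features.features.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.labels

    @property
    def subject_id(self) -> np.ndarray:
        return self.features.frame["subject_id"].to_numpy()

    def __len__(self) -> int:
        return len(self.labels)


def classify_level(mean_stress: float, cfg: LabelConfig = LabelConfig()) -> int:
    """Threshold a mean stress value into {0, 1, 2} (left-closed intervals)."""
    if mean_stress < cfg.theta1:
        return 0
    if mean_stress < cfg.theta2:
        return 1
    return 2


def label_window(
    trace: StressTrace, window_start: float, window_end: float, cfg: LabelConfig = LabelConfig()
) -> int:
    """Label one window [window_start, window_end) by its mean stress."""
    mask = (trace.timestamps >= window_start) & (trace.timestamps < window_end)
    if not mask.any():
        raise CoverageError(
            f"no stress-trace points in window [{window_start}, {window_end})"
        )
    return classify_level(float(trace.values[mask].mean()), cfg)


def label_dataset(
    features: FeatureTable,
    trace: Optional[StressTrace],
    cfg: LabelConfig = LabelConfig(),
    window_duration: Optional[float] = None,
    traces_by_subject: Optional[dict[str, StressTrace]] = None,
) -> LabeledDataset:
    """Label every feature row by the mean stress inside its window.

    ``window_duration`` defaults to the spacing implied by a 40-sample
    window at 4 Hz (10 s).  For multi-subject tables pass
    ``traces_by_subject`` mapping subject id to that subject's trace
    (``trace`` is then ignored for covered subjects).
    """
    if window_duration is None:
        window_duration = 10.0
    frame = features.frame
    labels = np.empty(len(frame), dtype=int)
    for i, (subject, start) in enumerate(zip(frame["subject_id"], frame["window_start"])):
        t = trace
        if traces_by_subject is not None and subject in traces_by_subject:
            t = traces_by_subject[subject]
        if t is None:
            raise CoverageError(f"row {i}: no stress trace for subject {subject}")
        try:
            labels[i] = label_window(t, float(start), float(start) + window_duration, cfg)
        except CoverageError as exc:
            raise CoverageError(f"row {i} (subject {subject}): {exc}") from exc
    counts = np.bincount(labels, minlength=3)
    log.info("label counts: class0=%d class1=%d class2=%d", *counts)
    return LabeledDataset(features=features, labels=labels)
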