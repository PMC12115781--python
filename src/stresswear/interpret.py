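"""Post-hoc analysis: feature importance, correlations, group statistics.

* Mean-decrease-in-impurity (MDI) importance for tree ensembles: for each
  feature f, the Gini-impurity decrease of every node splitting on f is
  summed within each tree, averaged over the T trees, and the resulting
  vector is normalized to sum to one.
* Pearson correlation matrix of the window features.
* Per-stress-level physiological means with Welch two-sample t-tests
  (subject-paired variant available) for level 1 vs 0 and 2 vs 0.
* Per-subject time-in-level fractions with a high-stress flag (> 25% of
  windows at level 2) and an emergency-segment validation check.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from stresswear.errors import CoverageError, UnsupportedModelError, ValidationError
from stresswear.features import FeatureTable

SIGNAL_MEANS = ("HR_Mean", "TEMP_Mean", "EDA_Mean")
ALPHA = 0.001
HIGH_STRESS_FRACTION = 0.25


def _tree_feature_totals(tree, n_features: int) -> np.ndarray:
    """Total weighted Gini-impurity decrease per feature for one fitted tree.

    The decrease at an internal node n splitting on feature f is
    w(n)*i(n) - w(l)*i(l) - w(r)*i(r), with node weights w the fraction of
    training samples reaching the node.
    """
    t = tree.tree_
    totals = np.zeros(n_features)
    root_weight = t.weighted_n_node_samples[0]
    for node in range(t.node_count):
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:  # leaf
            continue
        w = t.weighted_n_node_samples
        decrease = (
            w[node] * t.impurity[node]
            - w[left] * t.impurity[left]
            - w[right] * t.impurity[right]
        ) / root_weight
        totals[t.feature[node]] += decrease
    return totals


def mdi_importance(model, feature_names: Optional[Sequence[str]] = None) -> pd.Series:
    """Normalized mean-decrease-in-impurity importance of a tree ensemble.

    Per-feature impurity decreases are summed over nodes, averaged over
    trees, then divided by their grand total so the importances sum to 1.
    Accepts a single decision tree, a random forest, a gradient-boosting
    ensemble, or an AdaBoost ensemble.
    """
    if hasattr(model, "tree_"):
        trees = [model]
    elif hasattr(model, "estimators_"):
        trees = [t for t in np.asarray(model.estimators_, dtype=object).ravel()]
        if not all(hasattr(t, "tree_") for t in trees):
            raise UnsupportedModelError("ensemble members do not expose a tree structure")
    else:
        raise UnsupportedModelError(f"{type(model).__name__} is not a tree model/ensemble")
    n_features = trees[0].tree_.n_features
    per_tree = np.stack([_tree_feature_totals(t, n_features) for t in trees])
    raw = per_tree.mean(axis=0)
    total = raw.sum()
    importance = raw / total if total > 0 else raw
    if feature_names is None:
        feature_names = [f"feature_{i}" for i in range(n_features)]
    return pd.Series(importance, index=list(feature_names), name="mdi_importance")


def feature_correlations(table: FeatureTable) -> pd.DataFrame:
    """Pearson correlation matrix of the feature columns.

    Constant columns (undefined correlation) are excluded from the matrix.
    """
    feats = table.features
    if len(feats) < 2:
        raise ValidationError("need at least 2 rows to correlate features")
    keep = [c for c in feats.columns if feats[c].nunique() > 1]
    return feats[keep].corr(method="pearson")


@dataclasses.dataclass
class LevelTests:
    """Per-level mean table plus t-test rows (comparison, t, p, significant)."""

    means: pd.DataFrame  # signals x levels
    tests: pd.DataFrame  # columns: comparison, t_statistic, p_value, significant

    def to_dict(self) -> dict:
        return {
            "means": self.means.to_dict(),
            "tests": self.tests.to_dict(orient="records"),
        }


def level_comparison_tests(
    table: FeatureTable,
    labels: Sequence[int],
    paired_by_subject: bool = False,
    alpha: float = ALPHA,
) -> LevelTests:
    """Compare HR/TEMP/EDA window means across stress levels.

    For each signal mean and each comparison (level 1 vs 0, level 2 vs 0)
    a Welch unequal-variance two-sample t-test is run on the window values
    (direction: elevated-level mean minus level-0 mean).  With
    ``paired_by_subject`` the test is instead a paired t-test on
    per-subject level means, using subjects that have windows at both
    levels.
    """
    labels = np.asarray(labels)
    frame = table.frame
    means = pd.DataFrame(
        {
            level: {s: float(frame.loc[labels == level, s].mean()) for s in SIGNAL_MEANS}
            for level in (0, 1, 2)
        }
    )
    rows = []
    for level in (1, 2):
        for signal in SIGNAL_MEANS:
            if paired_by_subject:
                per_subject = frame.assign(label=labels).groupby("subject_id").apply(
                    lambda g: pd.Series(
                        {
                            "a": g.loc[g["label"] == level, signal].mean(),
                            "b": g.loc[g["label"] == 0, signal].mean(),
                        }
                    ),
                    include_groups=False,
                ).dropna()
                if len(per_subject) < 2:
                    raise ValidationError(
                        f"fewer than 2 subjects observed at both levels {level} and 0"
                    )
                t, p = stats.ttest_rel(per_subject["a"], per_subject["b"])
            else:
                a = frame.loc[labels == level, signal].to_numpy()
                b = frame.loc[labels == 0, signal].to_numpy()
                if a.size < 2 or b.size < 2:
                    raise ValidationError(
                        f"level {level if a.size < 2 else 0} has < 2 observations for {signal}"
                    )
                t, p = stats.ttest_ind(a, b, equal_var=False)
            rows.append(
                {
                    "comparison": f"Stress Level {level} vs. Stress Level 0 ({signal})",
                    "t_statistic": float(t),
                    "p_value": float(p),
                    "significant": bool(p < alpha),
                }
            )
    return LevelTests(means=means, tests=pd.DataFrame(rows))


def time_in_levels(
    labels_by_subject: dict[str, Sequence[int]],
    success_flags: Optional[dict[str, bool]] = None,
    high_fraction: float = HIGH_STRESS_FRACTION,
) -> pd.DataFrame:
    """Per-subject fraction of windows at each stress level.

    ``flag_high_stress`` is True when strictly more than ``high_fraction``
    of a subject's windows are at level 2.  When success flags are given
    the result carries them alongside for cross-tabulation.
    """
    rows = []
    for subject, labels in labels_by_subject.items():
        labels = np.asarray(labels)
        if labels.size == 0:
            raise ValidationError(f"subject {subject} has no labeled windows")
        frac = np.bincount(labels, minlength=3) / labels.size
        row = {
            "subject_id": subject,
            "frac_level0": frac[0],
            "frac_level1": frac[1],
            "frac_level2": frac[2],
            "flag_high_stress": bool(frac[2] > high_fraction),
        }
        if success_flags is not None:
            row["success"] = success_flags.get(subject)
        rows.append(row)
    return pd.DataFrame(rows)


def segment_validation(
    labels: Sequence[int],
    segment_ids: Sequence[int],
    subject_ids: Sequence[str],
    emergency_segment: int = 4,
    min_fraction: float = 0.5,
) -> pd.DataFrame:
    """Check that subjects are classified as stressed during the emergency.

    A subject passes when at least ``min_fraction`` of its windows in the
    emergency scenario segment are labeled level 1 or 2.
    """
    df = pd.DataFrame(
        {"label": np.asarray(labels), "segment": np.asarray(segment_ids), "subject": subject_ids}
    )
    rows = []
    for subject, g in df.groupby("subject", sort=False):
        in_seg = g[g["segment"] == emergency_segment]
        if len(in_seg) == 0:
            raise CoverageError(f"subject {subject} has no windows in segment {emergency_segment}")
        frac = float((in_seg["label"] >= 1).mean())
        rows.append(
            {"subject_id": subject, "stressed_fraction": frac, "passes": frac >= min_fraction}
        )
    out = pd.DataFrame(rows)
    out.attrs["n_passing"] = int(out["passes"].sum())
    return out
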