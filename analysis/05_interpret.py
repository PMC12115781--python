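"""Post-hoc analysis of the fitted models and labeled windows.

Reports mean-decrease-in-impurity feature importance from the selected
random forest, the feature correlation structure, per-stress-level
physiological means with Welch t-tests, per-subject time-in-level
fractions with the >25%-at-high-stress flag, and the emergency-segment
validation, writing each table under results/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

import stresswear as sw
from stresswear.features import minmax_scale
from stresswear.labeling import LabeledDataset

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 7

table = sw.read_feature_table(ROOT / "features.csv")
meta = pd.read_csv(ROOT / "labels.csv")
labels = meta["label"].to_numpy()

# refit the selected RF on all rows for a descriptive importance table
best_rf = json.loads((ROOT / "cv_rf.json").read_text())["best_hyperparameters"][0]
scaled, _, _ = minmax_scale(table)
model = sw.train_learner(
    "RF", best_rf, LabeledDataset(features=scaled, labels=labels), seed=SEED
)
importance = sw.mdi_importance(model, table.feature_columns).sort_values(ascending=False)
importance.to_csv(ROOT / "importance_rf.csv")
print("top-5 MDI features:",
      ", ".join(f"{k}={v:.3f}" for k, v in importance.head(5).items()))
print(f"importance sum: {importance.sum():.6f}")

corr = sw.feature_correlations(table)
corr.to_csv(ROOT / "correlations.csv")
print(f"corr(EDA_Mean, TEMP_Mean) = {corr.loc['EDA_Mean', 'TEMP_Mean']:+.3f}, "
      f"corr(EDA_Mean, HR_Mean) = {corr.loc['EDA_Mean', 'HR_Mean']:+.3f}")

tests = sw.level_comparison_tests(table, labels)
tests.means.to_csv(ROOT / "level_means.csv")
tests.tests.to_csv(ROOT / "level_tests.csv", index=False)
print("per-level means:")
print(tests.means.round(2).to_string())
for _, row in tests.tests.iterrows():
    print(f"  {row['comparison']}: t = {row['t_statistic']:+.2f}"
          + (" *" if row["significant"] else ""))

labels_by_subject = {
    s: labels[meta["subject_id"] == s] for s in meta["subject_id"].unique()
}
levels = sw.time_in_levels(labels_by_subject)
levels.to_csv(ROOT / "time_in_levels.csv", index=False)
flagged = levels.loc[levels["flag_high_stress"], "subject_id"].tolist()
print(f"subjects > 25% of windows at high stress: {flagged or 'none'}")

validation = sw.segment_validation(
    labels, meta["segment_id"].to_numpy(), meta["subject_id"]
)
validation.to_csv(ROOT / "segment_validation.csv", index=False)
print(f"emergency-segment validation: {validation.attrs['n_passing']}"
      f"/{len(validation)} subjects classified as stressed")
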