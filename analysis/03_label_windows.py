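"""Label every feature window from the stress annotations (classes 0/1/2).

Reads results/features.csv and the per-subject stress traces, applies the
tertile thresholds (1/3, 2/3) to each window's mean annotation, reports the
class balance and agreement with the generator's ground truth, and writes
results/labels.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import stresswear as sw

ROOT = Path(__file__).resolve().parent.parent / "results"

table = sw.read_feature_table(ROOT / "features.csv")
traces = {
    d.name: sw.read_stress_trace(d / "stress.csv")
    for d in sorted((ROOT / "cohort").iterdir())
    if d.is_dir()
}
dataset = sw.label_dataset(table, None, traces_by_subject=traces)

out = table.frame[["subject_id", "segment_id", "window_start"]].copy()
out["label"] = dataset.labels
out.to_csv(ROOT / "labels.csv", index=False)

counts = np.bincount(dataset.labels, minlength=3)
print(f"class balance: no-stress={counts[0]}, medium={counts[1]}, high={counts[2]}")

truth = {
    d.name: pd.read_csv(d / "ground_truth.csv")
    for d in sorted((ROOT / "cohort").iterdir())
    if d.is_dir()
}
agree = total = 0
for label, subject, start in zip(
    dataset.labels, out["subject_id"], out["window_start"]
):
    gt = truth[subject]
    match = gt[np.isclose(gt["window_start"], start)]
    if len(match):
        total += 1
        agree += int(match["true_class"].iloc[0] == label)
print(f"agreement with generator ground truth: {agree}/{total} "
      f"({100 * agree / total:.1f}%)")
print(f"wrote {ROOT / 'labels.csv'}")
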