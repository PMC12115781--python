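"""Select and evaluate the stress classifiers on the labeled windows.

Protocol: stratified 80/20 split; nested 5x5 cross-validation with
randomized search (10 draws here; the package default is 100) selects
random-forest and gradient-boosting configurations on the training part;
the stacking classifier combines them; one evaluation on the untouched
20%.  Also runs the exhaustive k-NN grid as a cheap non-ensemble baseline.
Writes CV results and classification reports under results/.
"""

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

import stresswear as sw
from stresswear.features import minmax_scale
from stresswear.labeling import LabeledDataset
from stresswear.pipeline import train_test_split_stratified
from stresswear.sensor_io import write_report_json

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 7
N_ITER = 10

table = sw.read_feature_table(ROOT / "features.csv")
labels = pd.read_csv(ROOT / "labels.csv")["label"].to_numpy()
dataset = LabeledDataset(features=table, labels=labels)

train, test = train_test_split_stratified(dataset, 0.2, SEED)
scaled_train, (scaled_test,), _ = minmax_scale(train.features, [test.features])
train_s = LabeledDataset(features=scaled_train, labels=train.labels)
test_s = LabeledDataset(features=scaled_test, labels=test.labels)

best = {}
for kind in ("RF", "GB"):
    space = dataclasses.replace(sw.default_space(kind), n_iterations=N_ITER)
    result = sw.nested_cv(train, space, seed=SEED)
    write_report_json(result.to_dict(), ROOT / f"cv_{kind.lower()}.json")
    best[kind] = result.best_hyperparameters[
        int(np.argmax(result.outer_fold_accuracies))
    ]
    print(f"{kind}: outer-CV accuracy {result.mean_accuracy:.4f} "
          f"(folds {['%.3f' % a for a in result.outer_fold_accuracies]}), "
          f"inner/outer gap {result.inner_outer_gap:.4f}")

models = {
    "RF": sw.train_learner("RF", best["RF"], train_s, seed=SEED),
    "GB": sw.train_learner("GB", best["GB"], train_s, seed=SEED),
    "STACK": sw.train_stacking(train_s, best["RF"], best["GB"], seed=SEED),
}
for kind, model in models.items():
    report = sw.evaluate(model, test_s)
    write_report_json(report.to_dict(), ROOT / f"report_{kind.lower()}.json")
    print(f"{kind}: holdout accuracy {report.accuracy:.4f}, "
          f"macro F1 {report.macro_avg['f1']:.4f}")

knn, n_fits = sw.grid_search(train, sw.default_space("KNN"), seed=SEED)
report = sw.evaluate(knn, test)
write_report_json(
    {"n_fits": n_fits, "best_params": knn.best_params_,
     "best_cv_accuracy": knn.best_score_, **report.to_dict()},
    ROOT / "report_knn.json",
)
print(f"KNN grid: {n_fits} fits, best {knn.best_params_}, "
      f"holdout accuracy {report.accuracy:.4f}")
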