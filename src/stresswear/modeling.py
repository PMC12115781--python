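"""Model selection and evaluation under nested stratified cross-validation.

The protocol mirrors common practice for imbalanced 3-class biosignal data:
one stratified 80/20 train/test split; on the training part, nested
cross-validation (stratified 5-fold inner search over randomized
hyperparameter draws, stratified 5-fold outer evaluation) selects and
scores random-forest and gradient-boosting base learners; a stacking
classifier combines their out-of-fold class probabilities through a
multinomial logistic meta-learner; the chosen models are refit on the full
training part and evaluated once on the held-out 20%.

Min-max scaling is fit inside each training split (never on data used for
evaluation), so no scaling leakage can inflate the reported scores.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
    StackingClassifier,
)
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from stresswear.errors import StratificationError, ValidationError
from stresswear.labeling import LabeledDataset

LEARNERS = ("RF", "GB", "LR", "SVM", "KNN", "ADA")

# Domain encodings: ("int", lo, hi) uniform integers inclusive of both ends,
# ("float", lo, hi) uniform reals, or an explicit tuple of choices.
Domain = tuple


@dataclasses.dataclass
class SearchSpace:
    """Hyperparameter space: randomized (n_iterations draws) or full grid."""

    learner: str
    params: dict[str, Domain]
    n_iterations: Optional[int] = None  # None -> exhaustive grid

    def __post_init__(self) -> None:
        if self.learner not in LEARNERS:
            raise ValidationError(f"unknown learner {self.learner!r}")

    def contains(self, config: dict) -> bool:
        for name, domain in self.params.items():
            if name not in config:
                return False
            value = config[name]
            if isinstance(domain, tuple) and len(domain) == 3 and domain[0] in ("int", "float"):
                _, lo, hi = domain
                if not (lo <= value <= hi):
                    return False
                if domain[0] == "int" and int(value) != value:
                    return False
            elif value not in domain:
                return False
        return not (set(config) - set(self.params))


def default_space(learner: str) -> SearchSpace:
    """The default hyperparameter space for each learner.

    RF and GB are randomized searches with 100 iterations; the remaining
    learners are exhaustive grids (45 / 24 / 16 / 125 candidates for
    LR / SVM / KNN / ADA).
    """
    if learner == "RF":
        return SearchSpace(
            "RF",
            {
                "n_estimators": ("int", 50, 300),
                "max_depth": ("int", 10, 30),
                "max_features": ("sqrt", "log2"),
                "min_samples_split": ("int", 2, 20),
                "min_samples_leaf": ("int", 1, 10),
                "bootstrap": (True, False),
            },
            n_iterations=100,
        )
    if learner == "GB":
        return SearchSpace(
            "GB",
            {
                "n_estimators": ("int", 50, 300),
                "max_depth": ("int", 3, 10),
                "learning_rate": ("float", 0.01, 0.31),
            },
            n_iterations=100,
        )
    if learner == "LR":
        return SearchSpace(
            "LR",
            {
                "C": (0.001, 0.01, 0.1, 1.0, 10.0),
                "solver": ("liblinear", "lbfgs", "saga"),
                "max_iter": (100, 500, 1000),
            },
        )
    if learner == "SVM":
        return SearchSpace(
            "SVM",
            {
                "C": (0.1, 1.0, 10.0, 100.0),
                "gamma": ("scale", "auto", 0.01),
                "kernel": ("rbf", "linear"),
            },
        )
    if learner == "KNN":
        return SearchSpace(
            "KNN",
            {
                "metric": ("manhattan", "euclidean"),
                "n_neighbors": (3, 5, 7, 9),
                "weights": ("uniform", "distance"),
            },
        )
    if learner == "ADA":
        return SearchSpace(
            "ADA",
            {
                "max_depth": (1, 3, 5, 7, 9),
                "learning_rate": (0.01, 0.05, 0.1, 0.5, 1.0),
                "n_estimators": (50, 100, 200, 300, 400),
            },
        )
    raise ValidationError(f"unknown learner {learner!r}")


def sample_configurations(space: SearchSpace, seed: int) -> list[dict]:
    """Draw the candidate configurations for a search space.

    Randomized spaces yield exactly ``n_iterations`` configurations with
    integers uniform on their inclusive ranges and reals uniform on their
    intervals; grid spaces yield the full cross-product in a deterministic
    order.  The same seed always yields the same list.
    """
    names = list(space.params)
    if space.n_iterations is None:
        values = []
        for name in names:
            domain = space.params[name]
            if isinstance(domain, tuple) and len(domain) == 3 and domain[0] in ("int", "float"):
                raise ValidationError(f"grid space cannot contain continuous domain {name!r}")
            values.append(list(domain))
        return [dict(zip(names, combo)) for combo in itertools.product(*values)]

    rng = np.random.default_rng(seed)
    configs = []
    for _ in range(space.n_iterations):
        config = {}
        for name in names:
            domain = space.params[name]
            if isinstance(domain, tuple) and len(domain) == 3 and domain[0] == "int":
                config[name] = int(rng.integers(domain[1], domain[2] + 1))
            elif isinstance(domain, tuple) and len(domain) == 3 and domain[0] == "float":
                config[name] = float(rng.uniform(domain[1], domain[2]))
            else:
                config[name] = domain[int(rng.integers(len(domain)))]
        configs.append(config)
    return configs


def stratified_folds(labels: Sequence[int], k: int, seed: int = 0) -> list[np.ndarray]:
    """Partition indices into k stratified folds (shuffled, seeded).

    Per-fold class counts differ from exact proportional allocation by at
    most one.  k = 1 returns the single fold of all indices.
    """
    labels = np.asarray(labels)
    if k == 1:
        return [np.arange(labels.size)]
    classes, counts = np.unique(labels, return_counts=True)
    too_small = classes[counts < k]
    if too_small.size:
        raise StratificationError(
            f"classes {too_small.tolist()} have fewer than k={k} members"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % 2**31)
    return [test for _, test in skf.split(np.zeros(labels.size), labels)]


def build_estimator(kind: str, config: dict, seed: int = 0):
    """Instantiate the scikit-learn estimator for a learner configuration."""
    seed = int(seed) % 2**31
    if kind == "RF":
        return RandomForestClassifier(**config, random_state=seed, n_jobs=1)
    if kind == "GB":
        return GradientBoostingClassifier(**config, random_state=seed)
    if kind == "LR":
        if config.get("solver") == "liblinear":
            # liblinear is inherently binary; one-vs-rest extends it to 3 classes
            return OneVsRestClassifier(LogisticRegression(**config, random_state=seed))
        return LogisticRegression(**config, random_state=seed)
    if kind == "SVM":
        return SVC(**config, random_state=seed)
    if kind == "KNN":
        return KNeighborsClassifier(**config)
    if kind == "ADA":
        config = dict(config)
        depth = config.pop("max_depth")
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=depth, random_state=seed),
            **config,
            random_state=seed,
        )
    raise ValidationError(f"unknown learner {kind!r}")


def train_learner(kind: str, config: dict, train: LabeledDataset, seed: int = 0):
    """Fit one learner on (already scaled) training data.

    The configuration is validated against the learner's default space; the
    fitted model records it as ``configuration_``.
    """
    space = default_space(kind)
    if not space.contains(config):
        raise ValidationError(f"configuration {config} outside the {kind} space")
    model = build_estimator(kind, config, seed)
    model.fit(train.X, train.y)
    model.configuration_ = dict(config)
    return model


def _scaled_pipeline(estimator) -> Pipeline:
    return Pipeline([("scale", MinMaxScaler()), ("model", estimator)])


@dataclasses.dataclass
class CVResult:
    """Outcome of one nested cross-validation run."""

    learner: str
    outer_fold_accuracies: list[float]
    best_hyperparameters: list[dict]
    inner_best_accuracies: list[float]
    seed: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.outer_fold_accuracies))

    @property
    def inner_outer_gap(self) -> float:
        """|mean inner selection accuracy - mean outer accuracy|: the overfitting gap."""
        return abs(float(np.mean(self.inner_best_accuracies)) - self.mean_accuracy)

    def to_dict(self) -> dict:
        return {
            "learner": self.learner,
            "outer_fold_accuracies": [float(a) for a in self.outer_fold_accuracies],
            "mean_accuracy": self.mean_accuracy,
            "inner_best_accuracies": [float(a) for a in self.inner_best_accuracies],
            "inner_outer_gap": self.inner_outer_gap,
            "best_hyperparameters": self.best_hyperparameters,
            "seed": self.seed,
        }


def _fold_seed(seed: int, fold: int) -> int:
    return (int(seed) * 7919 + fold + 1) % 2**31


def nested_cv(dataset: LabeledDataset, space: SearchSpace, seed: int = 0, k: int = 5) -> CVResult:
    """Nested stratified k-fold cross-validation with randomized search.

    For each outer fold the candidate configurations are scored by inner
    stratified k-fold accuracy on the outer-training part (scaler fit
    inside each inner training split), the best is refit on the whole
    outer-training part, and accuracy is measured on the outer-test part.
    The returned result carries the k outer accuracies, the chosen
    configuration per fold and the winning inner accuracies (their mean
    against the outer mean is the overfitting gap).
    """
    X, y = dataset.X, dataset.y
    for cls, count in zip(*np.unique(y, return_counts=True)):
        if count < k * k:
            raise StratificationError(
                f"class {cls} has {count} rows; nested {k}x{k} stratification needs >= {k * k}"
            )
    outer = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % 2**31)
    outer_acc, inner_acc, best_cfgs = [], [], []
    for fold, (tr, te) in enumerate(outer.split(X, y)):
        fold_seed = _fold_seed(seed, fold)
        configs = sample_configurations(space, fold_seed)
        inner = StratifiedKFold(n_splits=k, shuffle=True, random_state=fold_seed)
        inner_splits = list(inner.split(X[tr], y[tr]))
        best_score, best_cfg = -np.inf, None
        for config in configs:
            score = _config_cv_accuracy(
                space.learner, config, X[tr], y[tr], inner_splits, fold_seed
            )
            if score > best_score:
                best_score, best_cfg = score, config
        pipe = _scaled_pipeline(build_estimator(space.learner, best_cfg, fold_seed))
        pipe.fit(X[tr], y[tr])
        outer_acc.append(float(pipe.score(X[te], y[te])))
        inner_acc.append(best_score)
        best_cfgs.append(best_cfg)
    return CVResult(
        learner=space.learner,
        outer_fold_accuracies=outer_acc,
        best_hyperparameters=best_cfgs,
        inner_best_accuracies=inner_acc,
        seed=int(seed),
    )


def _config_cv_accuracy(learner: str, config: dict, X, y, splits, seed: int) -> float:
    """Mean k-fold accuracy of one configuration (scaler fit per training split)."""
    scores = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for tr_i, te_i in splits:
            pipe = _scaled_pipeline(build_estimator(learner, config, seed))
            pipe.fit(X[tr_i], y[tr_i])
            scores.append(pipe.score(X[te_i], y[te_i]))
    return float(np.mean(scores))


@dataclasses.dataclass
class GridSearchResult:
    """Best configuration of an exhaustive k-fold search, refit on all data."""

    learner: str
    best_params_: dict
    best_score_: float
    best_estimator_: Pipeline
    n_fits: int

    def predict(self, X):
        return self.best_estimator_.predict(X)


def grid_search(
    dataset: LabeledDataset, space: SearchSpace, seed: int = 0, k: int = 5
) -> tuple[GridSearchResult, int]:
    """Exhaustive k-fold grid search for the grid learners (LR/SVM/KNN/ADA).

    Every candidate is scored by stratified k-fold accuracy (scaler fit
    inside each training split); the winner is refit on all rows.  Returns
    the result and the number of model fits performed (candidates x folds,
    excluding the final refit).
    """
    if space.n_iterations is not None:
        raise ValidationError("grid_search expects an exhaustive (grid) space")
    X, y = dataset.X, dataset.y
    configs = sample_configurations(space, seed)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % 2**31)
    splits = list(skf.split(X, y))
    best_score, best_cfg, n_fits = -np.inf, None, 0
    for config in configs:
        score = _config_cv_accuracy(space.learner, config, X, y, splits, seed)
        n_fits += k
        if score > best_score:
            best_score, best_cfg = score, config
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        pipe = _scaled_pipeline(build_estimator(space.learner, best_cfg, seed))
        pipe.fit(X, y)
    result = GridSearchResult(
        learner=space.learner,
        best_params_=best_cfg,
        best_score_=best_score,
        best_estimator_=pipe,
        n_fits=n_fits,
    )
    return result, n_fits


def train_stacking(train: LabeledDataset, rf_config: dict, gb_config: dict, seed: int = 0):
    """Fit the RF + GB stacking classifier on (already scaled) training data.

    Base learners contribute out-of-fold class probabilities via an
    internal stratified 5-fold split; a multinomial logistic meta-learner
    combines them (6 meta-features for 3 classes x 2 base models).
    """
    for kind, config in (("RF", rf_config), ("GB", gb_config)):
        if not default_space(kind).contains(config):
            raise ValidationError(f"configuration {config} outside the {kind} space")
    seed = int(seed) % 2**31
    model = StackingClassifier(
        estimators=[
            ("rf", build_estimator("RF", rf_config, seed)),
            ("gb", build_estimator("GB", gb_config, seed)),
        ],
        final_estimator=LogisticRegression(max_iter=1000, random_state=seed),
        cv=StratifiedKFold(n_splits=5, shuffle=True, random_state=seed),
        stack_method="predict_proba",
        n_jobs=1,
    )
    model.fit(train.X, train.y)
    model.configuration_ = {"rf": dict(rf_config), "gb": dict(gb_config)}
    return model


@dataclasses.dataclass
class ModelReport:
    """Per-class precision/recall/F1/support plus accuracy and averages."""

    classes: list[int]
    precision: list[float]
    recall: list[float]
    f1: list[float]
    support: list[int]
    accuracy: float

    @property
    def macro_avg(self) -> dict[str, float]:
        return {
            "precision": float(np.mean(self.precision)),
            "recall": float(np.mean(self.recall)),
            "f1": float(np.mean(self.f1)),
        }

    @property
    def weighted_avg(self) -> dict[str, float]:
        w = np.asarray(self.support, dtype=float)
        w = w / w.sum() if w.sum() else w
        return {
            "precision": float(np.dot(w, self.precision)),
            "recall": float(np.dot(w, self.recall)),
            "f1": float(np.dot(w, self.f1)),
        }

    def to_dict(self) -> dict:
        return {
            "per_class": {
                str(c): {
                    "precision": float(p),
                    "recall": float(r),
                    "f1": float(f),
                    "support": int(s),
                }
                for c, p, r, f, s in zip(
                    self.classes, self.precision, self.recall, self.f1, self.support
                )
            },
            "accuracy": float(self.accuracy),
            "macro_avg": self.macro_avg,
            "weighted_avg": self.weighted_avg,
        }


def evaluate(model, test: LabeledDataset, classes: Sequence[int] = (0, 1, 2)) -> ModelReport:
    """Score a fitted model on a held-out set.

    Metrics with a zero denominator (a class absent from test and
    predictions) are reported as 0 with support 0.
    """
    if len(test) == 0:
        raise ValidationError("test set is empty")
    pred = model.predict(test.X)
    precision, recall, f1, support = precision_recall_fscore_support(
        test.y, pred, labels=list(classes), zero_division=0
    )
    return ModelReport(
        classes=list(classes),
        precision=precision.tolist(),
        recall=recall.tolist(),
        f1=f1.tolist(),
        support=[int(s) for s in support],
        accuracy=float(accuracy_score(test.y, pred)),
    )
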