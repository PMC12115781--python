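import dataclasses

import numpy as np
import pandas as pd
import pytest

import stresswear as sw
from stresswear.errors import StratificationError, ValidationError
from stresswear.features import FeatureTable
from stresswear.labeling import LabeledDataset
from stresswear.modeling import build_estimator


def dataset_from(X, y, columns=None):
    X = np.asarray(X, dtype=float)
    if columns is None:
        columns = ["EDA_Mean", "HR_Mean", "TEMP_Mean"][: X.shape[1]]
    frame = pd.DataFrame(X, columns=columns)
    frame.insert(0, "window_start", np.arange(len(frame)) * 5.0)
    frame.insert(0, "subject_id", "S01")
    return LabeledDataset(features=FeatureTable(frame=frame), labels=np.asarray(y))


def separable_dataset(rng, n_per_class=30, n_features=3):
    """Three well-separated Gaussian blobs."""
    X, y = [], []
    for cls in range(3):
        X.append(rng.normal(cls * 10.0, 0.5, size=(n_per_class, n_features)))
        y += [cls] * n_per_class
    return dataset_from(np.vstack(X), y)


SMALL_RF_SPACE = sw.SearchSpace(
    "RF",
    {"n_estimators": ("int", 5, 15), "max_depth": ("int", 2, 6), "bootstrap": (True, False)},
    n_iterations=5,
)


class TestStratifiedFolds:
    def test_exact_proportional_allocation(self):
        labels = np.repeat([0, 1, 2], [50, 30, 20])
        folds = sw.stratified_folds(labels, 5, seed=1)
        assert sorted(np.concatenate(folds).tolist()) == list(range(100))
        for fold in folds:
            counts = np.bincount(labels[fold], minlength=3)
            np.testing.assert_array_equal(counts, [10, 6, 4])

    def test_k1_returns_everything(self):
        folds = sw.stratified_folds([0, 1, 2, 0], 1)
        assert len(folds) == 1 and folds[0].size == 4

    def test_class_smaller_than_k_errors(self):
        with pytest.raises(StratificationError):
            sw.stratified_folds([0] * 10 + [1] * 3, 5)

    def test_within_one_of_proportional_for_uneven_counts(self, rng):
        labels = rng.integers(0, 3, size=97)
        folds = sw.stratified_folds(labels, 5, seed=0)
        for cls in range(3):
            per_fold = [int(np.sum(labels[f] == cls)) for f in folds]
            assert max(per_fold) - min(per_fold) <= 1


class TestSampleConfigurations:
    def test_rf_randomized_draws_respect_ranges(self):
        configs = sw.sample_configurations(sw.default_space("RF"), seed=7)
        assert len(configs) == 100
        assert all(50 <= c["n_estimators"] <= 300 for c in configs)
        assert all(10 <= c["max_depth"] <= 30 for c in configs)
        assert all(c["max_features"] in ("sqrt", "log2") for c in configs)

    def test_gb_learning_rate_continuous_uniform(self):
        configs = sw.sample_configurations(sw.default_space("GB"), seed=7)
        rates = [c["learning_rate"] for c in configs]
        assert all(0.01 <= r <= 0.31 for r in rates)
        assert len(set(rates)) == len(rates)  # continuous draw: no repeats

    @pytest.mark.parametrize(
        "learner, expected", [("LR", 45), ("SVM", 24), ("KNN", 16), ("ADA", 125)]
    )
    def test_grid_candidate_counts(self, learner, expected):
        assert len(sw.sample_configurations(sw.default_space(learner), seed=0)) == expected

    def test_same_seed_same_configurations(self):
        a = sw.sample_configurations(sw.default_space("GB"), seed=42)
        b = sw.sample_configurations(sw.default_space("GB"), seed=42)
        assert a == b


class TestTrainLearner:
    def test_stump_reproduces_threshold_rule(self, rng):
        X = rng.random((60, 1))
        y = (X[:, 0] > 0.5).astype(int) * 2  # classes 0 and 2
        ds = dataset_from(X, y, columns=["EDA_Mean"])
        model = build_estimator("RF", dict(n_estimators=1, max_depth=1, bootstrap=False), 0)
        model.fit(ds.X, ds.y)
        assert (model.predict(ds.X) == y).all()

    def test_knn_one_neighbor_memorizes_training_set(self, rng):
        ds = separable_dataset(rng, n_per_class=10)
        model = sw.train_learner(
            "KNN", {"metric": "euclidean", "n_neighbors": 3, "weights": "distance"}, ds
        )
        assert (model.predict(ds.X) == ds.y).all()
        assert model.configuration_["n_neighbors"] == 3

    def test_gb_zero_learning_rate_predicts_majority(self, rng):
        X = rng.random((50, 2))
        y = np.array([0] * 35 + [1] * 15)
        model = build_estimator("GB", dict(n_estimators=10, max_depth=2, learning_rate=0.0), 0)
        model.fit(X, y)
        assert (model.predict(X) == 0).all()

    def test_config_outside_space_rejected(self, rng):
        ds = separable_dataset(rng, n_per_class=5)
        with pytest.raises(ValidationError):
            sw.train_learner("RF", {"n_estimators": 999}, ds)


class TestNestedCV:
    def test_separable_data_scores_one(self, rng):
        ds = separable_dataset(rng, n_per_class=30)
        result = sw.nested_cv(ds, SMALL_RF_SPACE, seed=0)
        assert len(result.outer_fold_accuracies) == 5
        assert result.mean_accuracy == 1.0
        assert result.inner_outer_gap < 1e-9

    def test_shuffled_labels_score_near_chance(self, rng):
        # permutation null: accuracy ~ max class prior within 3 SE
        ds = separable_dataset(rng, n_per_class=25)
        y = ds.labels.copy()
        rng.shuffle(y)
        ds = LabeledDataset(features=ds.features, labels=y)
        result = sw.nested_cv(ds, SMALL_RF_SPACE, seed=1)
        prior = np.bincount(y).max() / y.size
        se = np.sqrt(prior * (1 - prior) / y.size)
        assert result.mean_accuracy < prior + 3 * se

    def test_reproducible_under_seed(self, rng):
        ds = separable_dataset(rng, n_per_class=25)
        a = sw.nested_cv(ds, SMALL_RF_SPACE, seed=9)
        b = sw.nested_cv(ds, SMALL_RF_SPACE, seed=9)
        assert a.outer_fold_accuracies == b.outer_fold_accuracies
        assert a.best_hyperparameters == b.best_hyperparameters

    def test_too_small_class_raises(self, rng):
        ds = separable_dataset(rng, n_per_class=8)  # < 25 per class
        with pytest.raises(StratificationError):
            sw.nested_cv(ds, SMALL_RF_SPACE, seed=0)


class TestStacking:
    def test_perfect_bases_give_perfect_stack(self, rng):
        ds = separable_dataset(rng, n_per_class=30)
        model = sw.train_stacking(
            ds,
            dict(n_estimators=50, max_depth=10, max_features="sqrt",
                 min_samples_split=2, min_samples_leaf=1, bootstrap=True),
            dict(n_estimators=50, max_depth=3, learning_rate=0.1),
            seed=0,
        )
        assert (model.predict(ds.X) == ds.y).all()

    def test_meta_features_are_six_for_three_classes(self, rng):
        ds = separable_dataset(rng, n_per_class=30)
        model = sw.train_stacking(
            ds,
            dict(n_estimators=50, max_depth=10, max_features="sqrt",
                 min_samples_split=2, min_samples_leaf=1, bootstrap=True),
            dict(n_estimators=50, max_depth=3, learning_rate=0.1),
            seed=0,
        )
        assert model.transform(ds.X[:3]).shape == (3, 6)

    def test_invalid_base_config_rejected(self, rng):
        ds = separable_dataset(rng)
        with pytest.raises(ValidationError):
            sw.train_stacking(ds, {"n_estimators": 10}, {"n_estimators": 10}, seed=0)


class TestEvaluate:
    def test_all_correct_gives_ones(self, rng):
        ds = separable_dataset(rng, n_per_class=10)
        model = sw.train_learner(
            "KNN", {"metric": "euclidean", "n_neighbors": 3, "weights": "distance"}, ds
        )
        report = sw.evaluate(model, ds)
        assert report.accuracy == 1.0
        assert report.precision == [1.0] * 3 and report.recall == [1.0] * 3

    def test_hand_confusion_arithmetic(self):
        # class 1: TP=8, FP=2, FN=2 -> precision = recall = F1 = 0.8
        y_true = np.array([1] * 10 + [0] * 10)
        y_pred = np.array([1] * 8 + [0] * 2 + [1] * 2 + [0] * 8)

        class Fixed:
            def predict(self, X):
                return y_pred

        ds = dataset_from(np.zeros((20, 1)), y_true, columns=["EDA_Mean"])
        report = sw.evaluate(Fixed(), ds)
        assert report.precision[1] == report.recall[1] == pytest.approx(0.8)
        assert report.f1[1] == pytest.approx(0.8)

    def test_absent_class_reports_zero_with_zero_support(self):
        y_true = np.array([0, 0, 1, 1])

        class Fixed:
            def predict(self, X):
                return y_true

        ds = dataset_from(np.zeros((4, 1)), y_true, columns=["EDA_Mean"])
        report = sw.evaluate(Fixed(), ds)
        assert report.support[2] == 0
        assert report.precision[2] == report.recall[2] == report.f1[2] == 0.0

    def test_weighted_average_recomputes_from_per_class_table(self, rng):
        ds = separable_dataset(rng, n_per_class=12)
        y_noisy = ds.labels.copy()
        flip = rng.random(y_noisy.size) < 0.2
        y_noisy[flip] = rng.integers(0, 3, size=flip.sum())

        class Fixed:
            def predict(self, X):
                return y_noisy

        report = sw.evaluate(Fixed(), ds)
        w = np.asarray(report.support) / np.sum(report.support)
        assert report.weighted_avg["f1"] == pytest.approx(float(np.dot(w, report.f1)))
        assert report.macro_avg["recall"] == pytest.approx(float(np.mean(report.recall)))
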