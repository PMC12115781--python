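"""End-to-end orchestration: simulate -> preprocess -> features -> label ->
train/evaluate -> interpret, from a single config.

Every artifact is written under one output directory together with a
manifest recording the configuration and all seeds, so a run can be
reproduced bit-for-bit from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from stresswear import sensor_io
from stresswear.errors import StresswearError
from stresswear.features import (
    FeatureConfig,
    FeatureTable,
    add_lags,
    extract_window_features,
    minmax_scale,
)
from stresswear.interpret import (
    feature_correlations,
    level_comparison_tests,
    mdi_importance,
    segment_validation,
    time_in_levels,
)
from stresswear.labeling import LabelConfig, LabeledDataset, label_dataset
from stresswear.modeling import (
    default_space,
    evaluate,
    grid_search,
    nested_cv,
    stratified_folds,
    train_learner,
    train_stacking,
)
from stresswear.preprocess import align_session
from stresswear.sensor_io import SessionRecording, StressTrace
from stresswear.synthgen import GeneratorParams, generate_cohort


@dataclasses.dataclass
class PipelineConfig:
    """Everything one run needs; loadable from a YAML key-value file."""

    out_dir: str = "results/run"
    seed: int = 0
    synthetic: bool = True
    generator: GeneratorParams = dataclasses.field(default_factory=GeneratorParams)
    features: FeatureConfig = dataclasses.field(default_factory=FeatureConfig)
    labels: LabelConfig = dataclasses.field(default_factory=LabelConfig)
    models: tuple[str, ...] = ("RF", "GB", "STACK")
    search_iterations: Optional[int] = None  # None -> each space's default (100)
    test_fraction: float = 0.2
    k_folds: int = 5
    alpha: float = 0.001
    emergency_segment: int = 4
    high_stress_fraction: float = 0.25

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "generator" in kwargs:
            kwargs["generator"] = GeneratorParams(**kwargs["generator"])
        if "features" in kwargs:
            kwargs["features"] = FeatureConfig(**kwargs["features"])
        if "labels" in kwargs:
            kwargs["labels"] = LabelConfig(**kwargs["labels"])
        if "models" in kwargs:
            kwargs["models"] = tuple(m.upper() for m in kwargs["models"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["models"] = list(self.models)
        return d


def segment_of(window_start: np.ndarray, boundaries: Sequence[float]) -> np.ndarray:
    """1-based scenario segment containing each window start."""
    b = np.asarray(boundaries, dtype=float)
    seg = np.searchsorted(b, np.asarray(window_start, dtype=float), side="right")
    return np.clip(seg, 1, b.size - 1)


def sessions_to_features(
    sessions: Sequence[SessionRecording], cfg: FeatureConfig = FeatureConfig()
) -> FeatureTable:
    """Align, window and lag-stack every session into one feature table.

    Lag features never cross subject boundaries; each subject's first
    ``max_lag`` windows are dropped.  Scenario segment ids are attached
    where sessions carry segment boundaries.
    """
    frames = []
    for session in sessions:
        aligned = align_session(session)
        table = extract_window_features(aligned, cfg)
        frame = table.frame
        if session.segment_boundaries is not None:
            frame = frame.copy()
            frame.insert(
                1, "segment_id", segment_of(table.window_start, session.segment_boundaries)
            )
        frames.append(frame)
    combined = FeatureTable(frame=pd.concat(frames, ignore_index=True))
    return add_lags(combined, cfg)


def train_test_split_stratified(
    dataset: LabeledDataset, test_fraction: float, seed: int
) -> tuple[LabeledDataset, LabeledDataset]:
    """One stratified holdout split (the 'test set' of the final report)."""
    k = max(2, int(round(1.0 / test_fraction)))
    folds = stratified_folds(dataset.labels, k, seed)
    test_idx = np.sort(folds[0])
    train_idx = np.sort(np.concatenate(folds[1:]))

    def take(idx: np.ndarray) -> LabeledDataset:
        return LabeledDataset(
            features=FeatureTable(frame=dataset.features.frame.iloc[idx].reset_index(drop=True)),
            labels=dataset.labels[idx],
        )

    return take(train_idx), take(test_idx)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis and write all artifacts.

    Returns the output directory.  Stages: simulate (optional) ->
    preprocess -> features -> label -> nested-CV model selection -> final
    refit + holdout evaluation -> interpretation reports.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        if not config.synthetic:
            raise StresswearError(
                "only synthetic runs are wired into run_pipeline; "
                "use sensor_io readers + the stage functions for recorded data"
            )
        params = dataclasses.replace(config.generator, seed=config.seed)
        cohort = generate_cohort(params)
        sessions = [s for s, _, _ in cohort]
        traces = {s.subject_id: t for s, t, _ in cohort}

        stage = "features"
        table = sessions_to_features(sessions, config.features)
        sensor_io.write_feature_table(table, out / "features.csv")

        stage = "label"
        dataset = label_dataset(
            table,
            next(iter(traces.values())),
            config.labels,
            window_duration=config.features.window_size / 4.0,
            traces_by_subject=traces,
        )

        stage = "train"
        train, test = train_test_split_stratified(dataset, config.test_fraction, config.seed)
        scaled_train, (scaled_test,), scaler = minmax_scale(train.features, [test.features])
        train_s = LabeledDataset(features=scaled_train, labels=train.labels)
        test_s = LabeledDataset(features=scaled_test, labels=test.labels)

        cv_results, reports, fitted = {}, {}, {}
        for kind in ("RF", "GB"):
            if kind not in config.models and "STACK" not in config.models:
                continue
            space = default_space(kind)
            if config.search_iterations is not None:
                space = dataclasses.replace(space, n_iterations=config.search_iterations)
            result = nested_cv(train, space, seed=config.seed, k=config.k_folds)
            cv_results[kind] = result
            best = result.best_hyperparameters[
                int(np.argmax(result.outer_fold_accuracies))
            ]
            model = train_learner(kind, best, train_s, seed=config.seed)
            fitted[kind] = model
            reports[kind] = evaluate(model, test_s)
        if "STACK" in config.models:
            stack = train_stacking(
                train_s,
                fitted["RF"].configuration_,
                fitted["GB"].configuration_,
                seed=config.seed,
            )
            fitted["STACK"] = stack
            reports["STACK"] = evaluate(stack, test_s)
        for kind in config.models:
            if kind in ("RF", "GB", "STACK"):
                continue
            search, n_fits = grid_search(train, default_space(kind), seed=config.seed)
            reports[kind] = evaluate(search, test)  # its pipeline scales internally
            sensor_io.write_report_json(
                {"n_fits": n_fits, "best_params": search.best_params_,
                 "best_cv_accuracy": float(search.best_score_)},
                out / f"search_{kind.lower()}.json",
            )
        for kind, result in cv_results.items():
            sensor_io.write_report_json(result.to_dict(), out / f"cv_{kind.lower()}.json")
        for kind, report in reports.items():
            sensor_io.write_report_json(report.to_dict(), out / f"report_{kind.lower()}.json")

        stage = "interpret"
        if "RF" in fitted:
            importance = mdi_importance(fitted["RF"], dataset.features.feature_columns)
            importance.sort_values(ascending=False).to_csv(out / "importance_rf.csv")
        feature_correlations(dataset.features).to_csv(out / "correlations.csv")
        tests = level_comparison_tests(dataset.features, dataset.labels, alpha=config.alpha)
        tests.means.to_csv(out / "level_means.csv")
        tests.tests.to_csv(out / "level_tests.csv", index=False)
        labels_by_subject = {
            s: dataset.labels[dataset.subject_id == s] for s in np.unique(dataset.subject_id)
        }
        time_in_levels(
            labels_by_subject, high_fraction=config.high_stress_fraction
        ).to_csv(out / "time_in_levels.csv", index=False)
        segment_validation(
            dataset.labels,
            dataset.features.frame["segment_id"].to_numpy(),
            dataset.subject_id,
            emergency_segment=config.emergency_segment,
        ).to_csv(out / "segment_validation.csv", index=False)

        stage = "manifest"
        config_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
        manifest = {
            "config": config.to_dict(),
            "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
            "seed": config.seed,
            "n_feature_rows": len(table),
            "scaler_columns": len(scaler),
        }
        sensor_io.write_report_json(manifest, out / "manifest.json")
    except StresswearError as exc:
        raise StresswearError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
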