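import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

sys.path.insert(0, str(Path(__file__).parent))  # for the brute-force oracle module

import stresswear as sw
from stresswear.pipeline import sessions_to_features


@pytest.fixture(scope="session")
def small_cohort():
    """Three subjects x 5 minutes, default noise/calibration, fixed seed."""
    params = sw.GeneratorParams(n_subjects=3, session_duration=300.0, seed=11)
    return sw.generate_cohort(params)


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    """Labeled feature table for the small cohort (unscaled)."""
    sessions = [s for s, _, _ in small_cohort]
    traces = {s.subject_id: t for s, t, _ in small_cohort}
    table = sessions_to_features(sessions)
    return sw.label_dataset(table, None, traces_by_subject=traces)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
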