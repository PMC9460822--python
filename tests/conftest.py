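import numpy as np
import pytest

from liftclust.cohort import ClusterArchetype, CohortConfig, generate_cohort
from liftclust.kinematics import features_table


@pytest.fixture(scope="session")
def small_cohort_config():
    """Fast cohort: default archetypes, fewer trials, short traces."""
    return CohortConfig(n_trials=120, n_participants=30, trace_duration=0.2)


@pytest.fixture(scope="session")
def small_cohort(small_cohort_config):
    return generate_cohort(small_cohort_config, seed=7)


@pytest.fixture(scope="session")
def default_cohort():
    """Default 473-trial cohort with short traces (feature values unchanged)."""
    trials = generate_cohort(CohortConfig(trace_duration=0.2), seed=0)
    feats = features_table(trials)
    X = feats[["trunk_rom", "hip_rom", "knee_rom"]].to_numpy()
    truth = np.array([t.true_cluster for t in trials])
    return trials, X, truth


@pytest.fixture
def blobs_2():
    """Two tight, far-separated 2-D blobs of 10 points each."""
    rng = np.random.default_rng(3)
    a = rng.normal([0, 0], 0.05, size=(10, 2))
    b = rng.normal([10, 10], 0.05, size=(10, 2))
    X = np.vstack([a, b])
    labels = np.repeat([1, 2], 10)
    return X, labels
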