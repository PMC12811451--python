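import numpy as np
import pytest

from fluidtraj import CohortConfig, LabelingConfig, Trajectory, simulate_cohort


def make_trajectory(tro, days=None, eye_id="eye", label=None):
    """Trajectory from a plain value list, days defaulting to 0..n-1."""
    tro = np.asarray(tro, dtype=float)
    if days is None:
        days = np.arange(tro.size)
    return Trajectory(eye_id=eye_id, days=np.asarray(days), tro=tro, label=label)


def step_series(low, high, n_low, n_high):
    return make_trajectory([low] * n_low + [high] * n_high)


@pytest.fixture
def labeling_config():
    return LabelingConfig()


@pytest.fixture(scope="session")
def default_cohort():
    """The seeded study-condition cohort used by cohort-level tests."""
    return simulate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-trajectory cohort small enough for end-to-end determinism checks."""
    return simulate_cohort(CohortConfig(n_trajectories=12, seed=7))
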