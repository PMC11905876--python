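import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from certepk.cohort import CohortConfig, simulate_cohort
from certepk.dataset import apply_m1_filter
from certepk.reference import final_model, initial_model

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# seed for the shared simulated trial; chosen once, used everywhere
COHORT_SEED = 2026


@pytest.fixture(scope="session")
def truth_model():
    return final_model()


@pytest.fixture(scope="session")
def trial_dataset(truth_model):
    """Default 31-subject cohort simulated from the published parameters."""
    ds, truth = simulate_cohort(truth_model, seed=COHORT_SEED)
    return ds, truth


@pytest.fixture(scope="session")
def analysis_dataset(trial_dataset):
    """The trial cohort after M1 exclusion of post-dose BLQ records."""
    ds, _ = trial_dataset
    filtered, _ = apply_m1_filter(ds)
    return filtered


@pytest.fixture(scope="session")
def recovery_fit(analysis_dataset):
    """FOCE-I fit of the final-model structure from displaced initials."""
    from certepk.estimation import fit

    return fit(analysis_dataset, initial_model())


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (16 subjects, 2 occasions) for optimiser-heavy tests."""
    cfg = CohortConfig(
        n_subjects=16, group_sizes=(3, 2, 6, 5), n_occasions=2
    )
    ds, truth = simulate_cohort(final_model(), cfg, seed=7)
    filtered, _ = apply_m1_filter(ds)
    return filtered, truth
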