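import numpy as np
import pytest

from permconnect import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small cohort without volumes: phenotypes + node signals only."""
    spec = CohortSpec(n_control=6, n_tia=6, n_stroke=5, n_timepoints=80,
                      generate_volumes=False, seed=42)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def volume_cohort():
    """Cohort with 4D volumes, lesion masks and component sets on a small grid."""
    spec = CohortSpec(n_control=3, n_tia=3, n_stroke=3, n_timepoints=60,
                      grid_shape=(12, 12, 8), seed=7)
    return simulate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
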