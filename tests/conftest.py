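import numpy as np
import pytest

from netphen import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """20+20 subjects, 30 nodes, planted 8-edge star with a strong effect."""
    spec = CohortSpec(
        n_case=20,
        n_control=20,
        n_nodes=30,
        n_modules=3,
        planted_edges=tuple((0, j) for j in range(1, 9)),
        effect_delta=0.1,
        edge_noise_sd=0.1,
        seed=7,
    )
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def null_cohort():
    """No group effect anywhere; useful for calibration-style checks."""
    spec = CohortSpec(n_case=15, n_control=15, n_nodes=20, n_modules=2, seed=11)
    return simulate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
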