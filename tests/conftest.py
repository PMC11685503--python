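import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def dyad_network():
    """Single layer, two disconnected unit-weight dyads {a,b} and {c,d}."""
    from oracle_utils import to_network

    A = np.zeros((4, 4))
    A[0, 1] = A[1, 0] = 1.0
    A[2, 3] = A[3, 2] = 1.0
    return to_network([A])


@pytest.fixture(scope="session")
def small_cohorts():
    """A small planted two-cohort study (shared across tests; read-only)."""
    import netlayers as nl

    spec = nl.CohortSpec(
        n_nodes=24,
        network_sizes=(8, 8, 8),
        n_layers_per_group=4,
        within_block_corr=0.6,
        between_block_corr=0.05,
        n_timepoints=150,
        seed=3,
    )
    layers_a, layers_b, truth = nl.simulate_cohorts(spec)
    return spec, layers_a, layers_b, truth
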