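import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def subcortical17():
    from covnet import load_atlas

    return load_atlas("subcortical17")


@pytest.fixture(scope="session")
def small_cohorts():
    """20+20 subcortical null-fixture cohorts (both groups, one generator)."""
    from covnet import fixture_spec, generate_cohort

    spec_a, spec_b = fixture_spec("null_17", seed=123, n_per_group=20)
    return generate_cohort(spec_a), generate_cohort(spec_b)


@pytest.fixture
def path_graph():
    return np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=np.uint8)


def complete_graph(n: int) -> np.ndarray:
    adj = np.ones((n, n), dtype=np.uint8)
    np.fill_diagonal(adj, 0)
    return adj


def ring_lattice(n: int, k: int) -> np.ndarray:
    """Ring of n nodes, each linked to its k nearest neighbours (k even)."""
    adj = np.zeros((n, n), dtype=np.uint8)
    for i in range(n):
        for step in range(1, k // 2 + 1):
            j = (i + step) % n
            adj[i, j] = adj[j, i] = 1
    return adj
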