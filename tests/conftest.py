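import numpy as np
import pytest

from fctopo import BinaryGraph, SimulationSpec, make_toy_graph, simulate_group_timeseries


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def triangle():
    return make_toy_graph("complete", 3)


@pytest.fixture
def p3():
    return make_toy_graph("path", 3)


@pytest.fixture
def star5():
    return make_toy_graph("star", 5)


@pytest.fixture(scope="session")
def random_graphs(rng):
    """30 connected-ish random graphs of varying size for property checks."""
    graphs = []
    for k in range(30):
        n = int(rng.integers(5, 25))
        p = float(rng.uniform(0.15, 0.6))
        graphs.append(make_toy_graph("erdos_renyi", n, p=p, seed=int(rng.integers(2**31))))
    return graphs


@pytest.fixture(scope="session")
def small_study():
    """Tiny null-effect two-group study shared across pipeline-level tests."""
    spec = SimulationSpec(n_per_group=(6, 6), n_regions=15, n_timepoints=80, seed=11)
    panels, covariates = simulate_group_timeseries(spec)
    return spec, panels, covariates


def random_symmetric(n: int, rng: np.random.Generator) -> np.ndarray:
    m = rng.normal(size=(n, n))
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    return m
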