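import numpy as np
import pytest

from gosmap.graph import AreaGraph, boundary_distances
from gosmap.models import AreaData, PosteriorSample
from gosmap.synthetic import make_lattice


@pytest.fixture
def path_graph():
    """A - B - C chain."""
    return AreaGraph.from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def lattice5():
    return make_lattice(5, 5)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def make_sample(s_draws, beta_draws=None, mu_draws=None, model="leroux",
                u_draws=None, rho=None):
    """Assemble a PosteriorSample from explicit draw matrices for unit tests."""
    s = np.atleast_2d(np.asarray(s_draws, dtype=float))
    m, n = s.shape
    beta = np.zeros((m, 1)) if beta_draws is None else np.atleast_2d(np.asarray(beta_draws, dtype=float))
    mu = s.copy() if mu_draws is None else np.atleast_2d(np.asarray(mu_draws, dtype=float))
    return PosteriorSample(
        model=model,
        beta=beta,
        s=s,
        mu=mu,
        sigma_s2=np.ones(m),
        u=None if u_draws is None else np.atleast_2d(np.asarray(u_draws, dtype=float)),
        sigma_u2=np.ones(m) if model == "bym" else None,
        rho=np.full(m, 0.5) if model == "leroux" else None,
    )


@pytest.fixture
def toy_data():
    """Three areas, intercept-only design."""
    return AreaData(y=[1, 1, 1], E=[1.0, 1.0, 1.0], X=np.ones((3, 1)))
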