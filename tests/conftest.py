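import numpy as np
import pytest

from spikelattice.io import EventSet
from spikelattice.models import ClusterParams, ModelSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_instance(rng, K=None, N=None, D=2, tau=None):
    """A small random event set + model for decoder tests."""
    K = K or int(rng.integers(1, 4))
    N = N or int(rng.integers(2, 7))
    z = np.sort(rng.uniform(0, 0.5, N)) + np.arange(N) * 1e-4
    X = rng.normal(0, 1, (N, D))
    priors = rng.dirichlet(np.ones(K))
    clusters = []
    for j in range(K):
        A = rng.normal(0, 1, (D, D))
        clusters.append(ClusterParams(
            mu_w=rng.normal(0, 1, D), cov_w=A @ A.T + 0.3 * np.eye(D),
            mu_isi=rng.normal(-3.5, 1), var_isi=rng.uniform(0.3, 2.5),
            beta=rng.uniform(1, 50), prior=priors[j]))
    model = ModelSet(clusters, tau_win=tau or rng.uniform(0.02, 0.6), L=K ** N)
    return EventSet(z, X), model


@pytest.fixture
def instance_factory():
    return random_instance
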