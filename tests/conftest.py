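import numpy as np
import pytest

from degroot_ga.core import Network, WeightMatrix, simulate_diffusion
from degroot_ga.ga import FixedMask


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def complete3():
    return Network.complete(3)


@pytest.fixture
def fixed3(complete3):
    return FixedMask.from_network(complete3)


@pytest.fixture
def noiseless3(complete3):
    """A 3-agent complete-network instance with a known weight matrix and
    an exact 11-step trajectory (moderately self-weighted so the weights
    are recoverable from the data)."""
    w = WeightMatrix(
        np.array([[0.7, 0.2, 0.1], [0.15, 0.75, 0.1], [0.1, 0.1, 0.8]])
    )
    traj = simulate_diffusion(w, np.array([0.1, 0.9, 0.5]), 10)
    return complete3, w, traj


def random_weight_matrix(n: int, rng: np.random.Generator,
                         network: Network | None = None) -> WeightMatrix:
    """Helper: a random row-stochastic matrix honouring a network."""
    adj = network.adjacency if network is not None else np.ones((n, n))
    w = np.zeros((n, n))
    for i in range(n):
        nb = np.flatnonzero(adj[i])
        w[i, nb] = rng.dirichlet(np.ones(nb.size))
    return WeightMatrix(w, network)
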