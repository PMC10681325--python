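import numpy as np
import pytest
import scipy.sparse as sp

from scnetpas import assembly, simulate
from scnetpas.types import GeneCellMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_counts():
    """Deterministic 60-gene x 45-cell simulated count matrix, 3 phenotypes."""
    spec = simulate.SimSpec(m=60, n=45, n_phenotypes=3, block_size=5, dropout=0.1, seed=7)
    return simulate.simulate_expression(spec)


def random_network(rng, m=8, n=6, density=0.4):
    """Random small gene-cell network with all three blocks populated."""
    def symm(k):
        a = rng.random((k, k)) * (rng.random((k, k)) < density)
        a = np.triu(a, 1)
        return a + a.T

    G = symm(m)
    C = symm(n)
    K = rng.random((m, n)) * (rng.random((m, n)) < density)
    # guarantee no fully isolated graph
    K[0, 0] = max(K[0, 0], 0.5)
    return assembly.assemble(sp.csr_matrix(G), sp.csr_matrix(C), sp.csr_matrix(K))


@pytest.fixture
def network_factory(rng):
    return lambda **kw: random_network(rng, **kw)


def dense_matrix(values, layer="counts"):
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    return GeneCellMatrix(
        sp.csr_matrix(values),
        [f"g{i}" for i in range(m)],
        [f"c{j}" for j in range(n)],
        layer,
    )
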