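import numpy as np
import pytest

from entgain import ExpressionMatrix, Network


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_ternary_matrix(rng, n_genes, t, missing_prob=0.0):
    values = rng.integers(-1, 2, size=(n_genes, t))
    if missing_prob > 0:
        mask = rng.random(size=values.shape) < missing_prob
        values[mask] = 3
    genes = [f"g{i}" for i in range(n_genes)]
    return ExpressionMatrix(genes, values, quantized=True)


def random_network(rng, n_genes, n_edges):
    genes = [f"g{i}" for i in range(n_genes)]
    edges = set()
    while len(edges) < n_edges:
        a, b = rng.choice(n_genes, size=2, replace=False)
        edges.add((genes[min(a, b)], genes[max(a, b)]))
    return Network.build(edges, genes)


@pytest.fixture
def square4():
    """4-cycle network a-b-c-d-a."""
    return Network.build([("a", "b"), ("b", "c"), ("c", "d"), ("a", "d")])
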