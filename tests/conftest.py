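import numpy as np
import pytest

from graphms.graphs import BinaryGraph
from graphms.matrices import ConnectivityMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20160478)


@pytest.fixture
def path_graph3():
    """a-b-c."""
    return BinaryGraph(3, ((0, 1), (1, 2)))


@pytest.fixture
def path_graph4():
    """a-b-c-d."""
    return BinaryGraph(4, ((0, 1), (1, 2), (2, 3)))


@pytest.fixture
def two_triangles():
    """Two disjoint K3s on 6 nodes."""
    return BinaryGraph(6, ((0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)))


def complete_graph(q: int) -> BinaryGraph:
    return BinaryGraph(q, tuple((i, j) for i in range(q) for j in range(i + 1, q)))


def random_binary_graph(q: int, p: float, rng: np.random.Generator) -> BinaryGraph:
    edges = tuple(
        (i, j) for i in range(q) for j in range(i + 1, q) if rng.random() < p
    )
    return BinaryGraph(q, edges)


def random_connectivity(q: int, rng: np.random.Generator, density: float = 0.6) -> ConnectivityMatrix:
    m = np.zeros((q, q))
    iu = np.triu_indices(q, k=1)
    w = rng.integers(0, 20, size=len(iu[0])) * (rng.random(len(iu[0])) < density)
    m[iu] = w
    return ConnectivityMatrix(m + m.T)
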