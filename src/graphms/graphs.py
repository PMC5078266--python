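"""Graph construction, proportional thresholding, and local primitives.

A subject's weighted graph G = (V, E, w) has one edge per strictly
positive off-diagonal matrix entry.  Binarization keeps a fixed fraction
tau of the strongest-weighted edges: with q nodes the retained-edge
budget is T = floor((q^2 - q) * tau / 2); the T largest-weight edges
form the unweighted graph G' on the same node set.  Ties at the cutoff
weight are broken by ascending (i, j) node index, which makes the
transform deterministic and nested in tau.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import shortest_path

from .matrices import ConnectivityMatrix


@dataclass(frozen=True)
class WeightedGraph:
    """Undirected weighted graph as an ordered edge list.

    ``edges[k] = (i, j)`` with ``i < j`` and ``weights[k] > 0``; node
    indices are 0-based.
    """

    q: int
    edges: tuple[tuple[int, int], ...]
    weights: tuple[float, ...]

    @property
    def l(self) -> int:  # noqa: E743 - the field's conventional symbol
        return len(self.edges)

    def density(self) -> float:
        """Fraction of possible node pairs carrying a connection."""
        return self.l / ((self.q * self.q - self.q) / 2)


@dataclass(frozen=True)
class BinaryGraph:
    """Unweighted graph G' produced by thresholding; same node set as G."""

    q: int
    edges: tuple[tuple[int, int], ...]
    _adj: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        a = np.zeros((self.q, self.q), dtype=bool)
        for i, j in self.edges:
            a[i, j] = a[j, i] = True
        object.__setattr__(self, "_adj", a)

    @property
    def l(self) -> int:  # noqa: E743
        return len(self.edges)

    def adjacency(self) -> np.ndarray:
        return self._adj.copy()


def graph_from_matrix(m: ConnectivityMatrix) -> WeightedGraph:
    """Build the weighted graph: one edge per positive upper-triangle entry."""
    iu, ju = np.triu_indices(m.q, k=1)
    mask = m.values[iu, ju] > 0
    edges = tuple(zip(iu[mask].tolist(), ju[mask].tolist()))
    weights = tuple(m.values[iu, ju][mask].tolist())
    return WeightedGraph(m.q, edges, weights)


def retained_edge_count(q: int, tau: float) -> int:
    """Edge budget T = floor((q^2 - q) * tau / 2) of the threshold transform."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau must lie in [0, 1], got {tau}")
    if q < 2:
        raise ValueError("need q >= 2")
    return math.floor((q * q - q) * tau / 2)


def proportional_threshold(g: WeightedGraph, tau: float) -> BinaryGraph:
    """Keep the T strongest edges of ``g``; returns the binarized graph G'.

    The node set is unchanged.  When fewer than T edges exist, all are
    kept.  Ties at the cutoff weight resolve by ascending (i, j), so the
    edge set at a smaller tau is always a subset of the set at a larger
    tau.
    """
    T = retained_edge_count(g.q, tau)
    order = sorted(
        range(g.l), key=lambda k: (-g.weights[k], g.edges[k][0], g.edges[k][1])
    )
    keep = sorted(g.edges[k] for k in order[: min(T, g.l)])
    return BinaryGraph(g.q, tuple(keep))


def degrees(g: BinaryGraph) -> np.ndarray:
    """Per-node degree k_i."""
    return g._adj.sum(axis=0).astype(int)


def shortest_path_lengths(g: BinaryGraph) -> np.ndarray:
    """All-pairs hop distances d_ij (BFS); +inf for disconnected pairs."""
    if g.l == 0:
        d = np.full((g.q, g.q), np.inf)
        np.fill_diagonal(d, 0.0)
        return d
    sp = csr_array(g._adj.astype(np.int8))
    return shortest_path(sp, method="D", unweighted=True, directed=False)


def triangle_counts(g: BinaryGraph) -> np.ndarray:
    """t_i: closed neighbor pairs around each node, via diag(A^3)/2."""
    a = g._adj.astype(np.int64)
    return (np.einsum("ij,jk,ki->i", a, a, a) // 2).astype(int)
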