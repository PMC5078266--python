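"""The six global connectome metrics.

Density is measured on the weighted graph before thresholding (fraction
of node pairs with any streamline); assortativity, transitivity, global
efficiency, modularity, and characteristic path length are measured on
the binarized graph G'.  Values that are undefined for a given graph
(assortativity on degree-regular graphs, path length on graphs with no
edges) are returned as NaN and flagged, never silently imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .graphs import (
    BinaryGraph,
    WeightedGraph,
    degrees,
    graph_from_matrix,
    proportional_threshold,
    shortest_path_lengths,
    triangle_counts,
)
from .matrices import ConnectivityMatrix, SubjectRecord

METRIC_NAMES = ("D", "r", "T", "Eg", "Q", "CPL")
#: metrics measured on the binarized graph (all but density)
BINARY_METRICS = ("r", "T", "Eg", "Q", "CPL")


@dataclass(frozen=True)
class Partition:
    """Assignment of every node to exactly one module."""

    labels: tuple[int, ...]

    @property
    def n_modules(self) -> int:
        return len(set(self.labels))

    @classmethod
    def from_communities(cls, communities: Iterable[Iterable[int]], q: int) -> "Partition":
        lab = np.full(q, -1, dtype=int)
        for m, nodes in enumerate(communities):
            for i in nodes:
                lab[i] = m
        if np.any(lab < 0):
            raise ValueError("partition does not cover all nodes")
        return cls(tuple(lab.tolist()))


@dataclass(frozen=True)
class MetricVector:
    """The six global metrics of one subject plus undefined-value flags."""

    density: float
    assortativity: float
    transitivity: float
    global_efficiency: float
    modularity: float
    char_path_length: float
    flags: tuple[str, ...] = field(default=())

    def as_dict(self) -> dict[str, float]:
        return dict(
            zip(
                METRIC_NAMES,
                (
                    self.density,
                    self.assortativity,
                    self.transitivity,
                    self.global_efficiency,
                    self.modularity,
                    self.char_path_length,
                ),
            )
        )


def density(g: WeightedGraph) -> float:
    """D = l / ((q^2 - q)/2), on the pre-threshold weighted graph."""
    return g.density()


def assortativity(g: BinaryGraph) -> float:
    """Degree correlation across edge endpoints (each edge counted once).

    Returns NaN on graphs where every edge joins equal-degree nodes
    (zero variance denominator), including all regular graphs.
    """
    if g.l == 0:
        return float("nan")
    k = degrees(g)
    ki = np.array([k[i] for i, _ in g.edges], dtype=float)
    kj = np.array([k[j] for _, j in g.edges], dtype=float)
    m_prod = np.mean(ki * kj)
    m_half_sum = np.mean((ki + kj) / 2.0)
    m_half_sq = np.mean((ki**2 + kj**2) / 2.0)
    den = m_half_sq - m_half_sum**2
    if np.isclose(den, 0.0, atol=1e-12):
        return float("nan")
    return float((m_prod - m_half_sum**2) / den)


def transitivity(g: BinaryGraph) -> float:
    """T = sum(2 t_i) / sum(k_i (k_i - 1)); 0 when no triplet exists."""
    k = degrees(g).astype(float)
    triplets = float(np.sum(k * (k - 1)))
    if triplets == 0:
        return 0.0
    return float(2.0 * np.sum(triangle_counts(g)) / triplets)


def global_efficiency(g: BinaryGraph) -> float:
    """Mean inverse shortest path; disconnected pairs contribute 0."""
    d = shortest_path_lengths(g)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[np.isinf(d)] = 0.0
    q = g.q
    return float(inv.sum() / (q * (q - 1)))


def characteristic_path_length(g: BinaryGraph) -> tuple[float, bool]:
    """CPL = mean over nodes of the mean distance to the other nodes.

    Unreachable pairs are excluded from each node's average (reachable
    nodes only); the returned flag is True when any pair was excluded or
    the graph has an isolated node.  A graph where no node can reach any
    other yields (NaN, True).
    """
    d = shortest_path_lengths(g)
    np.fill_diagonal(d, np.nan)
    finite = np.isfinite(d)
    flagged = bool(np.isinf(d).any())
    reach = finite.sum(axis=1)
    with np.errstate(invalid="ignore"):
        li = np.where(
            reach > 0, np.nansum(np.where(finite, d, 0.0), axis=1) / np.maximum(reach, 1), np.nan
        )
    if np.all(np.isnan(li)):
        return float("nan"), True
    return float(np.nanmean(li)), flagged or bool(np.isnan(li).any())


def modularity_of_partition(g: BinaryGraph, p: Partition) -> float:
    """Q = sum_u [e_uu - (sum_v e_uv)^2] over the modules of ``p``.

    e_uu is the fraction of edges inside module u; off-diagonal entries
    split each between-module edge evenly so rows sum to the fraction of
    edge ends attached to the module.
    """
    if len(p.labels) != g.q:
        raise ValueError(f"partition covers {len(p.labels)} nodes, graph has {g.q}")
    if g.l == 0:
        return float("nan")
    labels = np.asarray(p.labels)
    mods = np.unique(labels)
    idx = {m: t for t, m in enumerate(mods)}
    e = np.zeros((len(mods), len(mods)))
    for i, j in g.edges:
        u, v = idx[labels[i]], idx[labels[j]]
        if u == v:
            e[u, u] += 1.0
        else:
            e[u, v] += 0.5
            e[v, u] += 0.5
    e /= g.l
    row = e.sum(axis=1)
    return float(np.sum(np.diag(e) - row**2))


def _partitions(nodes: Sequence[int]):
    """All set partitions of ``nodes`` (restricted-growth enumeration)."""
    if not nodes:
        yield []
        return
    first, rest = nodes[0], nodes[1:]
    for part in _partitions(rest):
        for k in range(len(part)):
            yield part[:k] + [part[k] + [first]] + part[k + 1 :]
        yield part + [[first]]


def modularity(
    g: BinaryGraph,
    seed: int = 0,
    n_restarts: int = 10,
    method: str = "auto",
) -> tuple[float, Partition]:
    """Best-found modularity and its partition.

    Small graphs (q <= 8, ``method='auto'``) are solved exactly by
    enumerating all set partitions; larger graphs use seeded multi-level
    (Louvain) optimization with ``n_restarts`` restarts, keeping the
    best Q.  The trivial single-module partition (Q = 0) is always a
    candidate, so the result is never negative.
    """
    if g.l == 0:
        return float("nan"), Partition(tuple([0] * g.q))
    if method == "exact" or (method == "auto" and g.q <= 8):
        best_q, best_p = -np.inf, None
        for part in _partitions(list(range(g.q))):
            p = Partition.from_communities(part, g.q)
            val = modularity_of_partition(g, p)
            if val > best_q:
                best_q, best_p = val, p
        return float(best_q), best_p
    G = nx.Graph()
    G.add_nodes_from(range(g.q))
    G.add_edges_from(g.edges)
    best_p = Partition(tuple([0] * g.q))
    best_q = modularity_of_partition(g, best_p)  # 0 by construction
    for r in range(n_restarts):
        comms = nx.community.louvain_communities(G, seed=seed + r)
        p = Partition.from_communities(comms, g.q)
        val = modularity_of_partition(g, p)
        if val > best_q:
            best_q, best_p = val, p
    return float(best_q), best_p


def compute_all(
    m: ConnectivityMatrix,
    tau: float,
    seed: int = 0,
    n_restarts: int = 10,
) -> MetricVector:
    """All six metrics of one subject at binarization threshold ``tau``.

    Density comes from the weighted graph; the other five from the
    proportionally thresholded binary graph.
    """
    g = graph_from_matrix(m)
    gb = proportional_threshold(g, tau)
    flags = []
    r = assortativity(gb)
    if np.isnan(r):
        flags.append("assortativity_undefined")
    if gb.l == 0:
        q_val = float("nan")
        flags.append("modularity_undefined")
    else:
        q_val, _ = modularity(gb, seed=seed, n_restarts=n_restarts)
    cpl, cpl_flag = characteristic_path_length(gb)
    if cpl_flag:
        flags.append("cpl_disconnected")
    return MetricVector(
        density=density(g),
        assortativity=r,
        transitivity=transitivity(gb),
        global_efficiency=global_efficiency(gb),
        modularity=q_val,
        char_path_length=cpl,
        flags=tuple(flags),
    )


def metrics_table(
    records: Sequence[SubjectRecord],
    tau: float,
    seed: int = 0,
    n_restarts: int = 10,
) -> pd.DataFrame:
    """Tidy per-subject metric table: subject_id, group, D, r, T, Eg, Q, CPL."""
    rows = []
    for rec in records:
        v = compute_all(rec.matrix, tau, seed=seed, n_restarts=n_restarts)
        rows.append({"subject_id": rec.subject_id, "group": rec.group, **v.as_dict()})
    return pd.DataFrame(rows, columns=["subject_id", "group", *METRIC_NAMES])
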