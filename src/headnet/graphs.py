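"""Weighted graph metrics on band-averaged, thresholded connectivity matrices.

Channels are nodes and suprathreshold band-averaged connectivity values are
edge weights.  Path-based metrics map weights to lengths as 1/weight (strong
edges are short), the standard convention for functional-connectivity
networks; a ``binarize`` option supports the literal edge-count reading.

* characteristic path length — mean weighted shortest-path distance over
  ordered node pairs (disconnected pairs excluded from the mean);
* global efficiency — mean inverse shortest-path distance (disconnected
  pairs contribute 0);
* mean clustering coefficient — weighted (geometric-mean-of-triangle-weights)
  clustering with weights normalized by the maximum, averaged over nodes;
* max betweenness centrality — maximum over nodes of the fraction of
  shortest paths passing through the node (normalized by (n−1)(n−2)/2).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "GraphMetricSet",
    "weights_to_lengths",
    "characteristic_path_length",
    "global_efficiency",
    "clustering_coefficient_mean",
    "betweenness_max",
    "compute_metrics",
]


@dataclass
class GraphMetricSet:
    charpath: float
    clustering_mean: float
    betweenness_max: float
    global_efficiency: float


def _check_weights(weights: np.ndarray) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(w, w.T):
        raise ValueError("weight matrix must be symmetric")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    return w


def weights_to_lengths(weights: np.ndarray) -> np.ndarray:
    """Length = 1/weight for positive weights; absent edges are infinite."""
    w = _check_weights(weights)
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(lengths, 0.0)
    return lengths


def _distances(weights: np.ndarray, binarize: bool) -> np.ndarray:
    w = _check_weights(weights)
    if binarize:
        w = (w > 0).astype(float)
    lengths = weights_to_lengths(w)
    finite = np.where(np.isinf(lengths), 0.0, lengths)
    return shortest_path(finite, method="D", directed=False, unweighted=False)


def characteristic_path_length(weights: np.ndarray, binarize: bool = False) -> float:
    """Mean shortest-path distance over ordered pairs; disconnected pairs
    are excluded from the mean (an entirely disconnected graph raises)."""
    d = _distances(weights, binarize)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    off = ~np.eye(n, dtype=bool)
    finite = off & np.isfinite(d)
    if not finite.any():
        raise ValueError("graph has no connected node pairs")
    return float(d[finite].mean())


def global_efficiency(weights: np.ndarray, binarize: bool = False) -> float:
    """Mean inverse shortest-path distance; disconnected pairs contribute 0."""
    d = _distances(weights, binarize)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    return float(inv[off].mean())


def _to_graph(weights: np.ndarray, binarize: bool) -> nx.Graph:
    w = _check_weights(weights)
    if binarize:
        w = (w > 0).astype(float)
    g = nx.Graph()
    g.add_nodes_from(range(w.shape[0]))
    ii, jj = np.nonzero(np.triu(w, k=1))
    for i, j in zip(ii, jj):
        g.add_edge(int(i), int(j), weight=w[i, j], length=1.0 / w[i, j])
    return g


def clustering_coefficient_mean(weights: np.ndarray, binarize: bool = False) -> float:
    """Mean weighted clustering coefficient (geometric triangle means on
    max-normalized weights); nodes with degree < 2 contribute 0."""
    if weights.shape[0] < 3:
        raise ValueError("need at least 3 nodes")
    g = _to_graph(weights, binarize)
    return float(nx.average_clustering(g, weight="weight"))


def betweenness_max(weights: np.ndarray, binarize: bool = False) -> float:
    """Maximum normalized betweenness centrality over nodes (fraction of
    shortest paths through the node, counting multiplicity)."""
    if weights.shape[0] < 3:
        raise ValueError("need at least 3 nodes")
    g = _to_graph(weights, binarize)
    bc = nx.betweenness_centrality(g, weight="length", normalized=True)
    return float(max(bc.values()))


def compute_metrics(weights: np.ndarray, binarize: bool = False) -> GraphMetricSet:
    """All four network summaries for one band-averaged weight matrix."""
    return GraphMetricSet(
        charpath=characteristic_path_length(weights, binarize),
        clustering_mean=clustering_coefficient_mean(weights, binarize),
        betweenness_max=betweenness_max(weights, binarize),
        global_efficiency=global_efficiency(weights, binarize),
    )
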