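"""KNN cell graph on the feature embedding, with per-node outlier pruning.

Each cell selects its K nearest neighbours by Euclidean distance in the
embedding space (union-symmetrized into an undirected graph).  Pruning
scores each node's 1-D neighbour-distance set with the closed-form
Isolation-Forest anomaly score and drops the selections flagged as
outliers; an edge survives as long as either endpoint still retains it, and
a node's single nearest neighbour is never pruned, so no node becomes
isolated by pruning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "CellGraph",
    "default_k",
    "build_knn_graph",
    "prune_graph",
    "adjacency_views",
    "isolation_scores_1d",
]


def _avg_path_length(n: int) -> float:
    """c(n): average unsuccessful-search path length in a BST of n points."""
    if n <= 1:
        return 0.0
    h = np.log(n - 1) + np.euler_gamma  # harmonic number H_{n-1}
    return 2.0 * h - 2.0 * (n - 1) / n


def _expected_depths(xs: np.ndarray) -> np.ndarray:
    """Expected isolation depth of each of the sorted points ``xs``.

    An isolation tree splits the current value range at a uniform random
    point; this computes the exact expectation of each point's path length
    over all such trees (the infinite-ensemble limit of an Isolation
    Forest).  Runs of identical values can never be separated and receive
    the unsplittable-leaf correction c(run length).
    """
    m = len(xs)
    cache: dict[tuple[int, int], np.ndarray] = {}

    def solve(i: int, j: int) -> np.ndarray:
        if (i, j) in cache:
            return cache[(i, j)]
        size = j - i + 1
        if size == 1:
            out = np.zeros(1)
        elif xs[j] - xs[i] <= 0.0:
            out = np.full(size, _avg_path_length(size))
        else:
            total = xs[j] - xs[i]
            out = np.zeros(size)
            for g in range(i, j):  # split falls in gap (x_g, x_{g+1})
                w = xs[g + 1] - xs[g]
                if w <= 0.0:
                    continue
                p = w / total
                out[: g - i + 1] += p * solve(i, g)
                out[g - i + 1 :] += p * solve(g + 1, j)
            out += 1.0
        cache[(i, j)] = out
        return out

    return solve(0, m - 1)


def isolation_scores_1d(values: np.ndarray) -> np.ndarray:
    """Isolation-Forest anomaly scores for a 1-D sample, in closed form.

    Returns the standard score s = 2^{-E[depth]/c(m)} per point (higher =
    more anomalous), computed from the exact expected isolation depth
    instead of a finite tree ensemble.
    """
    values = np.asarray(values, dtype=float).ravel()
    order = np.argsort(values, kind="stable")
    depths_sorted = _expected_depths(values[order])
    depths = np.empty_like(depths_sorted)
    depths[order] = depths_sorted
    c = _avg_path_length(len(values))
    if c <= 0:
        return np.full(len(values), 0.5)
    return np.power(2.0, -depths / c)


@dataclass
class CellGraph:
    """Undirected cell graph with per-node neighbour selections.

    ``neighbor_idx[i]`` / ``neighbor_dist[i]`` record which neighbours node i
    itself selected (the directed KNN relation) — pruning operates on these.
    ``edges`` is the union-symmetrized undirected edge set with Euclidean
    weights.
    """

    n_nodes: int
    neighbor_idx: list[np.ndarray]
    neighbor_dist: list[np.ndarray]
    edges: dict[tuple[int, int], float]
    pruned: bool = False

    def __post_init__(self) -> None:
        for (i, j), w in self.edges.items():
            if i == j:
                raise ValueError("self-loops are not allowed")
            if i > j:
                raise ValueError("edges must be stored as (min, max) pairs")
            if w < 0:
                raise ValueError("edge weights must be non-negative")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def to_edge_list(self) -> list[tuple[int, int, float]]:
        return [(i, j, w) for (i, j), w in sorted(self.edges.items())]


def default_k(n_cells: int) -> int:
    """K = max(5, round(N/100)), capped at 20."""
    return min(max(5, round(n_cells / 100)), 20)


def build_knn_graph(emb, k: int) -> CellGraph:
    """Exact K-nearest-neighbour graph on the embedding.

    Distance ties break toward the smaller cell index (stable sort).  The
    undirected edge set is the union of all directed selections.
    """
    vectors = emb.vectors if hasattr(emb, "vectors") else np.asarray(emb, dtype=float)
    n = vectors.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"need N > k >= 1, got N={n}, k={k}")
    neighbor_idx: list[np.ndarray] = []
    neighbor_dist: list[np.ndarray] = []
    edges: dict[tuple[int, int], float] = {}
    block = 512
    for start in range(0, n, block):
        rows = vectors[start : start + block]
        d = cdist(rows, vectors)
        for r in range(d.shape[0]):
            i = start + r
            di = d[r].copy()
            di[i] = np.inf  # exclude self
            order = np.argsort(di, kind="stable")[:k]
            neighbor_idx.append(order)
            neighbor_dist.append(di[order])
            for j, w in zip(order, di[order]):
                key = (min(i, int(j)), max(i, int(j)))
                edges[key] = float(w)
    return CellGraph(n, neighbor_idx, neighbor_dist, edges, pruned=False)


def prune_graph(
    g: CellGraph,
    contamination: float = 0.1,
    seed: int | None = 0,
    n_estimators: int | None = None,
) -> CellGraph:
    """Isolation-Forest pruning of each node's neighbour selections.

    Each node's 1-D distances to its selected neighbours are scored with the
    closed-form Isolation-Forest anomaly score (``isolation_scores_1d``);
    following the usual contamination rule, selections scoring strictly
    above the (1 - contamination) quantile are dropped — so a node whose
    neighbour distances are all equal loses nothing — except the nearest
    neighbour, which is always kept.  An undirected edge survives if either
    endpoint retains it.  The result is deterministic; ``seed`` and
    ``n_estimators`` are accepted for API stability but unused.
    """
    if g.pruned:
        raise ValueError("graph is already pruned")
    kept_idx: list[np.ndarray] = []
    kept_dist: list[np.ndarray] = []
    for i in range(g.n_nodes):
        idx, dist = g.neighbor_idx[i], g.neighbor_dist[i]
        if len(idx) < 2 or np.ptp(dist) < 1e-12:
            kept_idx.append(idx.copy())
            kept_dist.append(dist.copy())
            continue
        scores = isolation_scores_1d(dist)
        threshold = np.quantile(scores, 1.0 - contamination)
        keep = scores <= threshold
        keep[int(np.argmin(dist))] = True  # never prune the nearest neighbour
        kept_idx.append(idx[keep])
        kept_dist.append(dist[keep])
    edges: dict[tuple[int, int], float] = {}
    for i in range(g.n_nodes):
        for j, w in zip(kept_idx[i], kept_dist[i]):
            key = (min(i, int(j)), max(i, int(j)))
            edges[key] = float(w)
    return CellGraph(g.n_nodes, kept_idx, kept_dist, edges, pruned=True)


def adjacency_views(g: CellGraph, self_loops: bool = False):
    """Binary adjacency A, degree matrix D, and D^{-1/2} A D^{-1/2}.

    Degree-0 nodes get zero rows in the normalized view (no division by
    zero).  ``self_loops=True`` normalizes A + I instead.
    """
    n = g.n_nodes
    a = np.zeros((n, n))
    for i, j in g.edges:
        a[i, j] = 1.0
        a[j, i] = 1.0
    if self_loops:
        a = a + np.eye(n)
    deg = a.sum(axis=1)
    d = np.diag(deg)
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-300)), 0.0)
    a_norm = a * inv_sqrt[:, None] * inv_sqrt[None, :]
    return a, d, a_norm
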