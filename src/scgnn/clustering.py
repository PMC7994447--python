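"""Cell clustering: Louvain fixes the cluster count, k-means assigns cells.

Louvain modularity optimization runs on the (unweighted) pruned cell graph
and its community count k is handed to k-means on the 16-d graph embedding.
An optional affinity weighting 1/(1+d) is available for Louvain, and the
Louvain partition itself can serve as the assignment when the graph
autoencoder is ablated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.cluster import KMeans

__all__ = [
    "ClusterAssignment",
    "louvain_cluster_count",
    "louvain_communities",
    "kmeans_on_embedding",
]


@dataclass
class ClusterAssignment:
    """Per-cell integer labels, 0-based and contiguous."""

    labels: np.ndarray
    n_clusters: int
    method_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(self.n_clusters)):
            raise ValueError("labels must take exactly the values 0..n_clusters-1")

    @property
    def n_cells(self) -> int:
        return len(self.labels)


def _canonicalize(labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Relabel clusters by first occurrence so labels are 0..k-1."""
    mapping: dict[int, int] = {}
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out, len(mapping)


def _nx_graph(g, weighted: bool) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(range(g.n_nodes))
    for (i, j), w in g.edges.items():
        G.add_edge(i, j, weight=(1.0 / (1.0 + w)) if weighted else 1.0)
    return G


def louvain_communities(g, resolution: float = 1.0, seed: int | None = 0,
                        weighted: bool = False) -> ClusterAssignment:
    """Louvain partition of the pruned cell graph as a cluster assignment."""
    if g.n_edges == 0:
        raise ValueError("graph has no edges; increase the KNN parameter K")
    G = _nx_graph(g, weighted)
    comms = nx.algorithms.community.louvain_communities(
        G, weight="weight", resolution=resolution, seed=seed
    )
    labels = np.empty(g.n_nodes, dtype=int)
    for c, members in enumerate(comms):
        labels[list(members)] = c
    labels, k = _canonicalize(labels)
    return ClusterAssignment(labels, k, {"method": "louvain", "resolution": resolution, "seed": seed})


def louvain_cluster_count(g, resolution: float = 1.0, seed: int | None = 0,
                          weighted: bool = False, consensus_runs: int = 1) -> int:
    """Number of Louvain communities on the pruned cell graph.

    With ``consensus_runs`` > 1 the count is the mode over that many seeded
    Louvain runs (ties toward the smaller count): the community count on KNN
    graphs is noisy across Louvain seeds, and the mode is a steadier
    estimate than a single draw.
    """
    if consensus_runs <= 1:
        return louvain_communities(g, resolution, seed, weighted).n_clusters
    base = 0 if seed is None else int(seed)
    counts = [
        louvain_communities(g, resolution, (base + i) % (2**31 - 1), weighted).n_clusters
        for i in range(consensus_runs)
    ]
    vals, freq = np.unique(counts, return_counts=True)
    return int(vals[np.argmax(freq)])


def kmeans_on_embedding(z, k: int, seed: int | None = 0,
                        n_init: int = 10, max_iter: int = 300, tol: float = 1e-4) -> ClusterAssignment:
    """k-means (k-means++ init, best of ``n_init`` restarts) on the embedding."""
    vectors = z.vectors if hasattr(z, "vectors") else np.asarray(z, dtype=float)
    n = vectors.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of cells {n}")
    km = KMeans(n_clusters=k, n_init=n_init, max_iter=max_iter, tol=tol,
                random_state=None if seed is None else int(seed))
    raw = km.fit_predict(vectors)
    labels, k_eff = _canonicalize(raw)
    return ClusterAssignment(
        labels, k_eff,
        {"method": "kmeans", "inertia": float(km.inertia_), "seed": seed, "requested_k": k},
    )
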