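"""ZINB synthetic scRNA-Seq count matrices with planted cluster structure.

Counts follow a negative binomial parameterized by (mean, dispersion) with
variance mean + mean^2/dispersion; each cluster elevates its own marker
genes by a fold change, and excess (dropout) zeros are added per entry with
probability sigmoid(intercept + slope * log(mean + 1)) — slope negative, so
lowly expressed genes drop out more, as in real data.  Optional gene pairs
with a planted latent correlation are generated through a Gaussian copula
over the NB marginals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .clustering import ClusterAssignment
from .io_preprocess import ExpressionMatrix

__all__ = ["SyntheticSpec", "generate_zinb", "generate_correlated_pairs"]


@dataclass
class SyntheticSpec:
    """Generating parameters for the planted-cluster ZINB matrix.

    Defaults give 3 clusters x 200 cells, 300 genes with 30 markers per
    cluster at 4x fold change, dispersion 2, and dropout tuned so the final
    matrix is roughly 70% zeros.
    """

    cells_per_cluster: tuple[int, ...] = (200, 200, 200)
    n_genes: int = 300
    n_marker_genes: int = 30
    base_mean: float = 2.0
    marker_fold_change: float = 4.0
    dispersion: float = 2.0
    dropout_logit: tuple[float, float] = (1.5, -1.0)  # (intercept, slope vs log-mean)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.cells_per_cluster) or self.n_genes < 1:
            raise ValueError("counts must be >= 1")
        if self.dispersion <= 0 or self.base_mean <= 0 or self.marker_fold_change <= 0:
            raise ValueError("base_mean, fold change and dispersion must be positive")
        total_markers = self.n_marker_genes * len(self.cells_per_cluster)
        if total_markers > self.n_genes:
            raise ValueError("more marker genes than genes")

    @property
    def n_cells(self) -> int:
        return sum(self.cells_per_cluster)

    @property
    def n_clusters(self) -> int:
        return len(self.cells_per_cluster)


def _mean_matrix(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-cluster x per-gene NB means and the marker-block assignment."""
    k = spec.n_clusters
    means = np.full((k, spec.n_genes), spec.base_mean)
    marker_of = np.full(spec.n_genes, -1, dtype=int)
    for c in range(k):
        block = np.arange(c * spec.n_marker_genes, (c + 1) * spec.n_marker_genes)
        means[c, block] = spec.base_mean * spec.marker_fold_change
        marker_of[block] = c
    return means, marker_of


def _nb_p(mean: np.ndarray, dispersion: float) -> np.ndarray:
    # numpy/scipy NB parameterization: n = dispersion, p = n / (n + mean)
    return dispersion / (dispersion + mean)


def _dropout_prob(mean: np.ndarray, logit: tuple[float, float]) -> np.ndarray:
    intercept, slope = logit
    z = intercept + slope * np.log1p(mean)
    return 1.0 / (1.0 + np.exp(-z))


def generate_zinb(spec: SyntheticSpec):
    """Sample the planted-cluster ZINB matrix.

    Returns ``(counts, true_labels, truth_meta)``; ``truth_meta`` records
    the generating means, marker assignment and per-entry dropout
    probabilities so tests can verify recovery against the ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    means, marker_of = _mean_matrix(spec)
    labels = np.repeat(np.arange(spec.n_clusters), spec.cells_per_cluster)
    cell_means = means[labels]  # N x M
    counts = rng.negative_binomial(spec.dispersion, _nb_p(cell_means, spec.dispersion)).astype(float)
    p_drop = _dropout_prob(cell_means, spec.dropout_logit)
    dropped = rng.random(cell_means.shape) < p_drop
    counts[dropped] = 0.0
    x = ExpressionMatrix(
        counts,
        [f"cell{i:04d}" for i in range(spec.n_cells)],
        [f"gene{g:04d}" for g in range(spec.n_genes)],
        layer_tag="raw",
    )
    assignment = ClusterAssignment(labels, spec.n_clusters, {"method": "planted", "seed": spec.seed})
    truth = {
        "cluster_means": means,
        "marker_of": marker_of,
        "dropout_prob": p_drop,
        "dropped": dropped,
        "spec": spec,
    }
    return x, assignment, truth


def generate_correlated_pairs(
    spec: SyntheticSpec,
    pair_defs: list[tuple[int, int, float]],
    apply_dropout: bool = True,
):
    """ZINB matrix with planted latent gene-gene correlations.

    Each (gene_a, gene_b, rho) pair is generated from a bivariate Gaussian
    copula with latent correlation rho, pushed through the genes' NB
    marginal quantile functions; remaining genes are sampled independently.
    Returns ``(counts, true_labels, truth_meta)``.
    """
    for a, b, r in pair_defs:
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"correlation {r} outside [-1, 1]")
        if a == b:
            raise ValueError("a pair must name two distinct genes")
    rng = np.random.default_rng(spec.seed)
    means, marker_of = _mean_matrix(spec)
    labels = np.repeat(np.arange(spec.n_clusters), spec.cells_per_cluster)
    cell_means = means[labels]
    counts = rng.negative_binomial(spec.dispersion, _nb_p(cell_means, spec.dispersion)).astype(float)
    paired_genes: set[int] = set()
    for a, b, rho in pair_defs:
        if a in paired_genes or b in paired_genes:
            raise ValueError("genes may appear in at most one pair")
        paired_genes.update((a, b))
        cov = np.array([[1.0, rho], [rho, 1.0]])
        latent = rng.multivariate_normal(np.zeros(2), cov, size=spec.n_cells,
                                         method="cholesky")
        u = np.clip(stats.norm.cdf(latent), 1e-12, 1 - 1e-12)
        for col, gene in enumerate((a, b)):
            p = _nb_p(cell_means[:, gene], spec.dispersion)
            counts[:, gene] = stats.nbinom.ppf(u[:, col], spec.dispersion, p)
    if apply_dropout:
        p_drop = _dropout_prob(cell_means, spec.dropout_logit)
        dropped = rng.random(cell_means.shape) < p_drop
        counts[dropped] = 0.0
    else:
        p_drop = np.zeros_like(cell_means)
        dropped = np.zeros(cell_means.shape, dtype=bool)
    x = ExpressionMatrix(
        counts,
        [f"cell{i:04d}" for i in range(spec.n_cells)],
        [f"gene{g:04d}" for g in range(spec.n_genes)],
        layer_tag="raw",
    )
    assignment = ClusterAssignment(labels, spec.n_clusters, {"method": "planted", "seed": spec.seed})
    truth = {
        "cluster_means": means,
        "marker_of": marker_of,
        "pairs": list(pair_defs),
        "dropout_prob": p_drop,
        "dropped": dropped,
        "spec": spec,
    }
    return x, assignment, truth
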