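"""Benchmark harness: synthetic dropout corruption and evaluation metrics.

Imputation is scored on deliberately zeroed ("flipped") non-zero entries by
median L1 distance, cosine similarity and RMSE between original and imputed
values; clustering by the adjusted Rand index against reference labels and
by the mean silhouette coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score, silhouette_samples

from .io_preprocess import ExpressionMatrix

__all__ = [
    "DropoutMask",
    "synthetic_dropout",
    "median_l1",
    "cosine_sim",
    "rmse",
    "adjusted_rand_index",
    "silhouette_mean",
    "masked_metrics",
    "baseline_imputations",
]


@dataclass
class DropoutMask:
    """Positions flipped to zero, with the original values for scoring."""

    entries: np.ndarray  # (n_masked, 2) array of (cell, gene) indices
    rate: float
    seed: int | None
    original_values: np.ndarray

    @property
    def n_masked(self) -> int:
        return len(self.entries)


def synthetic_dropout(
    x: ExpressionMatrix, rate: float, seed: int | None = 0
) -> tuple[ExpressionMatrix, DropoutMask]:
    """Flip ``round(rate * nnz)`` uniformly chosen non-zero entries to zero."""
    if not 0.0 < rate < 1.0:
        raise ValueError(f"dropout rate must lie in (0, 1), got {rate}")
    rows, cols = np.nonzero(x.values)
    nnz = len(rows)
    n_mask = int(round(rate * nnz))
    if n_mask == 0:
        raise ValueError(f"rate {rate} rounds to zero masked entries ({nnz} non-zeros)")
    rng = np.random.default_rng(seed)
    pick = rng.choice(nnz, size=n_mask, replace=False)
    entries = np.stack([rows[pick], cols[pick]], axis=1)
    values = x.values.copy()
    original = values[entries[:, 0], entries[:, 1]].copy()
    values[entries[:, 0], entries[:, 1]] = 0.0
    return x.with_values(values), DropoutMask(entries, rate, seed, original)


def median_l1(original: np.ndarray, imputed: np.ndarray) -> float:
    """Median absolute deviation over the masked entries."""
    original, imputed = np.asarray(original, float), np.asarray(imputed, float)
    if original.shape != imputed.shape:
        raise ValueError("vector lengths differ")
    return float(np.median(np.abs(original - imputed)))


def cosine_sim(x: np.ndarray, y: np.ndarray) -> float:
    """x.y / (||x|| ||y||); defined as 0 when either norm vanishes."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx_, ny_ = np.linalg.norm(x), np.linalg.norm(y)
    if nx_ == 0 or ny_ == 0:
        return 0.0
    return float(x @ y / (nx_ * ny_))


def rmse(x: np.ndarray, y: np.ndarray) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    return float(np.sqrt(np.mean((x - y) ** 2)))


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Permutation-model ARI (contingency-table closed form)."""
    labels_a, labels_b = np.asarray(labels_a), np.asarray(labels_b)
    if len(labels_a) != len(labels_b):
        raise ValueError("label vectors differ in length")
    if len(labels_a) < 2:
        raise ValueError("ARI needs at least two samples")
    return float(adjusted_rand_score(labels_a, labels_b))


def silhouette_mean(points: np.ndarray, labels) -> float:
    """Mean per-cell silhouette (b - a)/max(a, b), Euclidean distance.

    Singleton clusters score 0 by convention; if every cluster is a
    singleton the mean is 0.
    """
    points = np.asarray(points, float)
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("silhouette needs at least two clusters")
    if len(uniq) == len(labels):
        return 0.0
    return float(np.mean(silhouette_samples(points, labels)))


def _rowwise(original_m: ExpressionMatrix, imputed_m: ExpressionMatrix, mask: DropoutMask):
    """Per-cell metric vectors over cells holding >= 1 masked entry."""
    cells = np.unique(mask.entries[:, 0])
    l1s, coss, rmses = [], [], []
    for c in cells:
        sel = mask.entries[:, 0] == c
        genes = mask.entries[sel, 1]
        orig = mask.original_values[sel]
        imp = imputed_m.values[c, genes]
        l1s.append(float(np.abs(orig - imp).sum()))
        coss.append(cosine_sim(orig, imp))
        rmses.append(rmse(orig, imp))
    return np.array(l1s), np.array(coss), np.array(rmses)


def masked_metrics(
    original_m: ExpressionMatrix,
    imputed_m: ExpressionMatrix,
    mask: DropoutMask,
    mode: str = "rowwise",
) -> dict[str, float]:
    """Score recovered values at the masked positions.

    ``rowwise`` (default) computes L1 / cosine / RMSE per cell row restricted
    to that cell's masked entries, then takes the median (L1) or mean
    (cosine, RMSE) across cells; ``pooled`` treats all masked entries as one
    pair of vectors.
    """
    imp = imputed_m.values[mask.entries[:, 0], mask.entries[:, 1]]
    if mode == "pooled":
        return {
            "median_l1": median_l1(mask.original_values, imp),
            "cosine": cosine_sim(mask.original_values, imp),
            "rmse": rmse(mask.original_values, imp),
        }
    if mode != "rowwise":
        raise ValueError(f"unknown mode {mode!r}")
    l1s, coss, rmses = _rowwise(original_m, imputed_m, mask)
    return {
        "median_l1": float(np.median(l1s)),
        "cosine": float(np.mean(coss)),
        "rmse": float(np.mean(rmses)),
    }


def baseline_imputations(corrupted: ExpressionMatrix) -> dict[str, ExpressionMatrix]:
    """Reference imputations: leave zeros as-is, or fill masked-looking zeros
    with the gene's mean over the corrupted matrix."""
    zeros = corrupted.with_values(corrupted.values.copy())
    gm = corrupted.values.copy()
    gene_means = corrupted.values.mean(axis=0)
    zero_pos = gm == 0
    gm[zero_pos] = np.broadcast_to(gene_means, gm.shape)[zero_pos]
    return {"zeros": zeros, "gene_mean": corrupted.with_values(gm)}
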