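"""Dense autoencoders: one architecture, three loss variants.

* feature autoencoder — reconstruction loss weighted element-wise by the
  TRS regulatory-signal matrix (strength ``alpha``); its bottleneck is the
  embedding the cell graph is built on.
* cluster autoencoder — same architecture, plain sum-of-squares loss, one
  independent model per inferred cell cluster.
* imputation autoencoder — feature loss plus an L1 weight penalty and two
  cell-pair regularizers driven by the pruned cell graph (``gamma1``) and
  the co-cluster matrix (``gamma2``); its reconstruction is the imputed
  expression matrix.

The encoder layers use ReLU and the decoder layers sigmoid, so inputs are
min-max scaled per gene to [0, 1] before training and inverse-scaled after.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import Adam, glorot, relu, sigmoid, seeded_rng
from .io_preprocess import ExpressionMatrix

__all__ = [
    "DenseAEConfig",
    "ImputationRegularizerConfig",
    "Embedding",
    "feature_ae_loss",
    "imputation_ae_loss",
    "train_feature_ae",
    "train_cluster_ae",
    "train_imputation_ae",
]


@dataclass
class DenseAEConfig:
    """Architecture and training hyperparameters shared by all dense AEs.

    Encoder layer widths default to 512 and 128 (so the embedding is 128-d);
    the decoder mirrors them.  Training is full-batch Adam unless the matrix
    has more than 5000 cells, in which case minibatches of ``batch_size``
    (default 128) are used.
    """

    encoder_dims: tuple[int, ...] = (512, 128)
    learning_rate: float = 1e-3
    epochs: int = 500
    batch_size: int | None = None
    seed: int = 0

    @property
    def embedding_dim(self) -> int:
        return self.encoder_dims[-1]


@dataclass
class ImputationRegularizerConfig:
    """Intensities of the four imputation-loss regularizers, each in [0, 1]."""

    alpha: float = 0.5    # TRS element-wise weighting
    beta: float = 0.5     # L1 on autoencoder weights
    gamma1: float = 0.01  # pruned-graph cell-pair term
    gamma2: float = 0.01  # co-cluster cell-pair term

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma1", "gamma2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class Embedding:
    """Per-cell bottleneck vectors aligned with the source matrix's cells."""

    vectors: np.ndarray
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding contains NaN/Inf")
        if self.vectors.shape[0] != len(self.cell_ids):
            raise ValueError("embedding rows and cell ids disagree")


class _GeneScaler:
    """Per-gene min-max scaling to [0, 1] with inverse transform.

    Constant genes (zero range) map to 0 under ``transform`` and are restored
    exactly to their constant under ``inverse`` whatever the network emitted,
    so a gene that never varies cannot acquire reconstruction noise.
    """

    def __init__(self, values: np.ndarray):
        self.lo = values.min(axis=0)
        span = values.max(axis=0) - self.lo
        degenerate = span <= 1e-12
        self.span_div = np.where(degenerate, 1.0, span)
        self.span_mul = np.where(degenerate, 0.0, span)

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (values - self.lo) / self.span_div

    def inverse(self, values: np.ndarray) -> np.ndarray:
        return values * self.span_mul + self.lo


class DenseAutoencoder:
    """Symmetric dense AE: ReLU encoder stack, sigmoid decoder stack."""

    def __init__(self, n_features: int, cfg: DenseAEConfig):
        self.cfg = cfg
        dims = [n_features, *cfg.encoder_dims]
        dec_dims = [*cfg.encoder_dims[::-1][1:], n_features]
        self.n_encoder = len(cfg.encoder_dims)
        self.acts = ["relu"] * self.n_encoder + ["sigmoid"] * len(dec_dims)
        all_dims = dims + dec_dims
        rng = seeded_rng(cfg.seed)
        # float32 throughout: halves memory traffic of the matmul-bound
        # training loop; parameters and losses stay deterministic per seed
        self.W = [glorot(rng, all_dims[i], all_dims[i + 1]).astype(np.float32)
                  for i in range(len(all_dims) - 1)]
        self.b = [np.zeros(all_dims[i + 1], dtype=np.float32) for i in range(len(all_dims) - 1)]
        self._rng = rng

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray):
        pre, act = [], []
        h = np.asarray(x, dtype=np.float32)
        for W, b, a in zip(self.W, self.b, self.acts):
            z = h @ W + b
            h = relu(z) if a == "relu" else sigmoid(z)
            pre.append(z)
            act.append(h)
        return pre, act

    def embed(self, x: np.ndarray) -> np.ndarray:
        _, act = self.forward(x)
        return act[self.n_encoder - 1]

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        _, act = self.forward(x)
        return act[-1]

    def _grads(self, x: np.ndarray, entry_w: np.ndarray, l1: float):
        pre, act = self.forward(x)
        x_hat = act[-1]
        resid = x - x_hat
        loss = float(np.sum(entry_w * resid**2))
        d = -2.0 * entry_w * resid
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        for i in range(len(self.W) - 1, -1, -1):
            a = act[i]
            if self.acts[i] == "sigmoid":
                dz = d * a * (1.0 - a)
            else:
                dz = d * (pre[i] > 0)
            upstream = act[i - 1] if i > 0 else x
            gW[i] = upstream.T @ dz
            gb[i] = dz.sum(axis=0)
            if i > 0:
                d = dz @ self.W[i].T
        if l1 > 0:
            loss += l1 * sum(float(np.abs(W).sum()) for W in self.W)
            for i, W in enumerate(self.W):
                gW[i] = gW[i] + l1 * np.sign(W)
        return loss, gW, gb

    def fit(self, x: np.ndarray, entry_w: np.ndarray | None = None, l1: float = 0.0):
        """Train with Adam on the entry-weighted SSE (+ optional L1); returns
        the per-epoch loss trace.  Aborts on NaN with diagnostics."""
        cfg = self.cfg
        x = np.asarray(x, dtype=np.float32)
        n = x.shape[0]
        entry_w = np.ones_like(x) if entry_w is None else np.asarray(entry_w, dtype=np.float32)
        opt = Adam(self.W + self.b, lr=cfg.learning_rate)
        batch = cfg.batch_size if cfg.batch_size else (None if n <= 5000 else 128)
        losses = []
        for epoch in range(cfg.epochs):
            if batch is None:
                loss, gW, gb = self._grads(x, entry_w, l1)
                opt.step(gW + gb)
            else:
                order = self._rng.permutation(n)
                loss = 0.0
                for start in range(0, n, batch):
                    idx = order[start : start + batch]
                    li, gW, gb = self._grads(x[idx], entry_w[idx], l1)
                    opt.step(gW + gb)
                    loss += li
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"NaN/Inf loss at epoch {epoch} (lr={cfg.learning_rate}); "
                    "lower the learning rate"
                )
            losses.append(loss)
        return losses


# -- loss functions (also usable standalone, e.g. for verification) ---------

def feature_ae_loss(
    x: np.ndarray, x_hat: np.ndarray, trs_weights: np.ndarray, alpha: float
) -> float:
    """(1-alpha) * sum((x - x_hat)^2) + alpha * sum((x - x_hat)^2 o TRS)."""
    x, x_hat, trs_weights = map(np.asarray, (x, x_hat, trs_weights))
    if not (x.shape == x_hat.shape == trs_weights.shape):
        raise ValueError("x, x_hat and TRS weights must share a shape")
    sq = (x - x_hat) ** 2
    return float((1.0 - alpha) * sq.sum() + alpha * (sq * trs_weights).sum())


def _pair_terms(resid_sq_per_cell: np.ndarray, mat: np.ndarray, mode: str, resid: np.ndarray):
    if mode == "literal":
        # sum_ij M_ij * ||r_j||^2  (matrix product of M with the per-cell
        # squared-residual vector, then summed)
        return float(mat.sum(axis=0) @ resid_sq_per_cell)
    if mode == "coupled":
        return float(np.sum(mat * (resid @ resid.T)))
    raise ValueError(f"unknown pair-term mode {mode!r}")


def imputation_ae_loss(
    x: np.ndarray,
    x_hat: np.ndarray,
    trs_weights: np.ndarray,
    adjacency: np.ndarray,
    co_cluster: np.ndarray,
    weights: list[np.ndarray],
    reg: ImputationRegularizerConfig,
    pair_mode: str = "literal",
) -> float:
    """Five-term imputation loss.

    Feature loss (TRS-weighted SSE) + beta * sum|w| over the model weights +
    gamma1 * graph pair term + gamma2 * co-cluster pair term.  ``pair_mode``
    selects how the cell-pair matrices couple with residuals: ``literal``
    penalizes each cell's squared residual by its (co-)neighbour count,
    ``coupled`` uses the cross-cell residual inner products.
    """
    x, x_hat = np.asarray(x, float), np.asarray(x_hat, float)
    n = x.shape[0]
    if adjacency.shape != (n, n) or co_cluster.shape != (n, n):
        raise ValueError("pair matrices must be N x N")
    loss = feature_ae_loss(x, x_hat, trs_weights, reg.alpha)
    loss += reg.beta * sum(float(np.abs(w).sum()) for w in weights)
    resid = x - x_hat
    s = (resid**2).sum(axis=1)
    loss += reg.gamma1 * _pair_terms(s, adjacency, pair_mode, resid)
    loss += reg.gamma2 * _pair_terms(s, co_cluster, pair_mode, resid)
    return float(loss)


# -- training entry points ---------------------------------------------------

def train_feature_ae(
    x: ExpressionMatrix,
    trs_weights: np.ndarray,
    cfg: DenseAEConfig,
    alpha: float = 0.5,
    model: DenseAutoencoder | None = None,
):
    """Train the TRS-regularized feature autoencoder.

    Returns ``(embedding, reconstruction, loss_trace, model)``; the
    reconstruction is inverse-scaled back to the input's per-gene range.
    Passing ``model`` continues training an existing autoencoder (warm
    start) instead of re-initializing — the iterative driver uses this so
    the embedding stays in the same basin across iterations.
    """
    scaler = _GeneScaler(x.values)
    xs = scaler.transform(x.values)
    entry_w = (1.0 - alpha) + alpha * np.asarray(trs_weights, dtype=float)
    if model is not None:
        ae = model
        ae.cfg = cfg  # training budget/lr of this phase, not of the old one
    else:
        ae = DenseAutoencoder(x.n_genes, cfg)
    losses = ae.fit(xs, entry_w)
    emb = Embedding(ae.embed(xs), list(x.cell_ids))
    recon = x.with_values(scaler.inverse(ae.reconstruct(xs)), layer_tag="reconstructed")
    return emb, recon, losses, ae


def train_cluster_ae(
    x_reconstructed: ExpressionMatrix,
    clusters,
    cfg: DenseAEConfig,
    min_cells: int = 10,
):
    """Train one plain autoencoder per cluster and concatenate the outputs.

    Cells of clusters smaller than ``min_cells`` pass through unchanged.
    Output rows stay in the original cell order.
    """
    labels = np.asarray(clusters.labels if hasattr(clusters, "labels") else clusters)
    out = x_reconstructed.values.copy()
    traces: dict[int, list[float]] = {}
    for c in np.unique(labels):
        idx = np.where(labels == c)[0]
        if len(idx) < min_cells:
            continue
        sub = x_reconstructed.values[idx]
        scaler = _GeneScaler(sub)
        xs = scaler.transform(sub)
        sub_cfg = DenseAEConfig(
            encoder_dims=cfg.encoder_dims,
            learning_rate=cfg.learning_rate,
            epochs=cfg.epochs,
            batch_size=cfg.batch_size,
            seed=(cfg.seed + 7919 * (int(c) + 1)) % (2**31 - 1),
        )
        ae = DenseAutoencoder(x_reconstructed.n_genes, sub_cfg)
        traces[int(c)] = ae.fit(xs)
        out[idx] = scaler.inverse(ae.reconstruct(xs))
    return x_reconstructed.with_values(out, layer_tag="reconstructed"), traces


def train_imputation_ae(
    x_pre: ExpressionMatrix,
    trs_weights: np.ndarray,
    adjacency: np.ndarray,
    clusters,
    cfg: DenseAEConfig,
    reg: ImputationRegularizerConfig,
    model: DenseAutoencoder | None = None,
    pair_norm: bool = True,
):
    """Train the imputation autoencoder on the pre-processed matrix.

    The graph and co-cluster pair terms (literal reading) fold into a
    per-cell weight on the squared residual: cell j's entries carry weight
    ``(1-alpha) + alpha*TRS + gamma1*colsum(A)_j + gamma2*colsum(B)_j``;
    the L1 term applies to all layer weight matrices.  ``model`` warm-starts
    from an already-trained autoencoder (the driver passes the final feature
    autoencoder, which already encodes the denoised cluster structure).
    Returns the imputed matrix (tag ``imputed``) and the loss trace.
    """
    labels = np.asarray(clusters.labels if hasattr(clusters, "labels") else clusters)
    n = x_pre.n_cells
    adjacency = np.asarray(adjacency, dtype=float)
    if adjacency.shape != (n, n):
        raise ValueError("adjacency must be N x N")
    co_cluster = (labels[:, None] == labels[None, :]).astype(float)
    if pair_norm:
        # row-normalize the pair matrices before folding them into the
        # per-cell weights: binary co-cluster column sums equal the cluster
        # size (~hundreds), which would drown the TRS contrast that keeps
        # censored zeros down-weighted
        a_n = adjacency / np.maximum(adjacency.sum(axis=1, keepdims=True), 1.0)
        b_n = co_cluster / np.maximum(co_cluster.sum(axis=1, keepdims=True), 1.0)
        cell_w = reg.gamma1 * a_n.sum(axis=0) + reg.gamma2 * b_n.sum(axis=0)
    else:
        cell_w = reg.gamma1 * adjacency.sum(axis=0) + reg.gamma2 * co_cluster.sum(axis=0)
    entry_w = (1.0 - reg.alpha) + reg.alpha * np.asarray(trs_weights, dtype=float)
    entry_w = entry_w + cell_w[:, None]
    scaler = _GeneScaler(x_pre.values)
    xs = scaler.transform(x_pre.values)
    if model is not None:
        ae = model
        ae.cfg = cfg
    else:
        ae = DenseAutoencoder(x_pre.n_genes, cfg)
    losses = ae.fit(xs, entry_w, l1=reg.beta)
    imputed = x_pre.with_values(
        np.maximum(scaler.inverse(ae.reconstruct(xs)), 0.0), layer_tag="imputed"
    )
    return imputed, losses
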