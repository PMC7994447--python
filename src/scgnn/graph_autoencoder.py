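"""Graph autoencoder: two-layer GCN encoder + inner-product decoder.

The encoder is Z = ReLU(A_norm ReLU(A_norm X' W1) W2) with the symmetrically
normalized adjacency A_norm = D^{-1/2} A D^{-1/2}; the decoder reconstructs
edge probabilities as sigmoid(Z Z^T) and training minimizes the mean
element-wise cross-entropy against the binary adjacency.  The 16-d graph
embedding Z is the substrate for cell clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import Adam, glorot, relu, sigmoid, seeded_rng
from .autoencoders import Embedding

__all__ = ["GAEConfig", "GraphEmbedding", "gcn_forward", "gae_decode", "gae_loss", "train_gae"]

_EPS = 1e-7


@dataclass
class GAEConfig:
    layer_dims: tuple[int, int] = (32, 16)
    learning_rate: float = 1e-3
    epochs: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.layer_dims) or self.layer_dims[0] <= self.layer_dims[1]:
            raise ValueError("layer dims must be positive and decreasing")


@dataclass
class GraphEmbedding:
    vectors: np.ndarray  # N x layer_dims[-1], non-negative (outer ReLU)
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("graph embedding contains NaN/Inf")


def gcn_forward(a_norm: np.ndarray, x: np.ndarray, w1: np.ndarray, w2: np.ndarray) -> np.ndarray:
    """Z = ReLU(A_norm @ ReLU(A_norm @ X @ W1) @ W2)."""
    n = a_norm.shape[0]
    if a_norm.shape != (n, n) or x.shape[0] != n or x.shape[1] != w1.shape[0]:
        raise ValueError("dimension mismatch in GCN forward pass")
    return relu(a_norm @ relu(a_norm @ x @ w1) @ w2)


def gae_decode(z: np.ndarray) -> np.ndarray:
    """Edge probabilities sigmoid(Z Z^T); symmetric, entries in (0, 1)."""
    z = np.asarray(z, dtype=float)
    return sigmoid(z @ z.T)


def gae_loss(a: np.ndarray, a_hat: np.ndarray, pos_weight: float | None = None) -> float:
    """Mean element-wise cross-entropy over all N x N adjacency entries.

    ``pos_weight`` optionally reweights the positive (edge) class, e.g. by
    (#zeros / #ones) for sparse graphs; default is the unweighted mean.
    """
    a = np.asarray(a, dtype=float)
    a_hat = np.clip(np.asarray(a_hat, dtype=float), _EPS, 1.0 - _EPS)
    if a.shape != a_hat.shape:
        raise ValueError("adjacency shapes differ")
    w_pos = 1.0 if pos_weight is None else pos_weight
    ce = -(w_pos * a * np.log(a_hat) + (1.0 - a) * np.log(1.0 - a_hat))
    return float(ce.mean())


def train_gae(
    graph,
    emb: Embedding,
    cfg: GAEConfig = GAEConfig(),
    propagation: np.ndarray | None = None,
    pos_weight: bool = False,
    normalize_features: bool = True,
    init_weights: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[GraphEmbedding, list[float], tuple[np.ndarray, np.ndarray]]:
    """Full-batch Adam training of W1, W2 against the binary adjacency.

    ``propagation`` overrides the matrix used inside the GCN layers (the
    iterative driver passes the mixed adjacency here); the reconstruction
    target stays the binary pruned adjacency.  Node feature rows are scaled
    to unit L2 norm by default — unnormalized feature magnitudes saturate
    the inner-product decoder and leave most ReLU units dead.
    """
    from .cell_graph import adjacency_views

    a, _, a_norm = adjacency_views(graph)
    prop = a_norm if propagation is None else np.asarray(propagation, dtype=float)
    x = emb.vectors
    if normalize_features:
        x = x / np.maximum(np.linalg.norm(x, axis=1, keepdims=True), 1e-12)
    n = x.shape[0]
    rng = seeded_rng(cfg.seed)
    if init_weights is not None:
        w1, w2 = (np.asarray(w, dtype=np.float32).copy() for w in init_weights)
    else:
        w1 = glorot(rng, x.shape[1], cfg.layer_dims[0]).astype(np.float32)
        w2 = glorot(rng, cfg.layer_dims[0], cfg.layer_dims[1]).astype(np.float32)
    opt = Adam([w1, w2], lr=cfg.learning_rate)
    wp = np.float32((a.size - a.sum()) / max(a.sum(), 1.0) if pos_weight else 1.0)
    x = x.astype(np.float32)
    a = a.astype(np.float32)
    prop = prop.astype(np.float32)
    px = prop @ x  # constant across epochs
    losses = []
    for epoch in range(cfg.epochs):
        p1 = px @ w1
        h1 = relu(p1)
        ph1 = prop @ h1
        p2 = ph1 @ w2
        z = relu(p2)
        s = z @ z.T
        a_hat = np.clip(sigmoid(s), _EPS, 1.0 - _EPS)
        ce = -(wp * a * np.log(a_hat) + (1.0 - a) * np.log(1.0 - a_hat))
        loss = float(ce.mean())
        if not np.isfinite(loss):
            raise FloatingPointError(f"NaN/Inf GAE loss at epoch {epoch}")
        losses.append(loss)
        # d(mean CE)/dS with S = Z Z^T; sigmoid folds into (a_hat - a)
        ds = (wp * a * (a_hat - 1.0) + (1.0 - a) * a_hat) / (n * n)
        dz = (ds + ds.T) @ z
        dp2 = dz * (p2 > 0)
        gw2 = ph1.T @ dp2
        dh1 = (prop.T @ (dp2 @ w2.T)) * (p1 > 0)
        gw1 = px.T @ dh1
        opt.step([gw1, gw2])
    z = gcn_forward(prop, x, w1, w2)
    return GraphEmbedding(z, list(emb.cell_ids)), losses, (w1, w2)
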