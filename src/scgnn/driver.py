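"""The iterative training loop and the end-to-end entry point.

Per iteration: feature autoencoder -> KNN graph + pruning -> graph
autoencoder (on the mixed adjacency) -> Louvain cluster count + k-means ->
per-cluster autoencoders, whose concatenated reconstruction feeds the next
iteration.  The loop stops when the mixed adjacency or the clustering
stabilizes, then a final imputation autoencoder is trained on the original
pre-processed matrix using the last graph and clustering as regularizers.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .autoencoders import (
    DenseAEConfig,
    Embedding,
    ImputationRegularizerConfig,
    train_cluster_ae,
    train_feature_ae,
    train_imputation_ae,
)
from .cell_graph import CellGraph, adjacency_views, build_knn_graph, default_k, prune_graph
from .clustering import ClusterAssignment, kmeans_on_embedding, louvain_cluster_count, louvain_communities
from .evaluation import adjusted_rand_index, baseline_imputations, masked_metrics, synthetic_dropout
from .graph_autoencoder import GAEConfig, GraphEmbedding, train_gae
from .io_preprocess import ExpressionMatrix, preprocess
from .ltmg import build_trs_matrix

__all__ = [
    "IterationConfig",
    "ScgnnConfig",
    "ScgnnResult",
    "mix_adjacency",
    "check_convergence",
    "run_scgnn",
    "impute_benchmark",
]


@dataclass
class IterationConfig:
    """Adjacency mixing and stopping rules for the iterative loop.

    ``conv_adj_threshold``/``conv_ari_threshold`` (both 0.99) are the
    convergence thresholds: the loop stops when the entry-wise L1 change of
    the mixed adjacency falls below (1 - 0.99) of the initial adjacency's L1
    norm, or when consecutive clusterings agree with ARI > 0.99.
    ``literal_convergence`` instead applies the inequalities exactly as
    printed (element-wise difference < 0.99 * initial; ARI < 0.99).
    """

    mixing_lambda: float = 0.5
    conv_adj_threshold: float = 0.99
    conv_ari_threshold: float = 0.99
    max_iterations: int = 10
    literal_convergence: bool = False
    # ablations
    skip_graph_ae: bool = False
    skip_cluster_ae: bool = False
    use_all_genes: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.mixing_lambda <= 1.0:
            raise ValueError("mixing_lambda must lie in [0, 1]")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class ScgnnConfig:
    """Bundle of every stage's configuration."""

    # preprocessing
    do_preprocess: bool = True
    gene_min_cell_frac: float = 0.01
    cell_min_gene_frac: float = 0.01
    n_top_genes: int = 2000
    # LTMG
    max_components: int = 5
    truncation_point: float = 0.0
    ltmg_restarts: int = 5
    trs_weight_mode: str = "minmax"
    # the imputation stage uses the binary reading: a censored zero is a
    # candidate dropout and should not anchor the fit, while every expressed
    # regulatory state is equally trustworthy signal
    imputation_trs_weight_mode: str = "expressed"
    refit_ltmg: bool = False
    # dense autoencoders
    encoder_dims: tuple[int, ...] = (512, 128)
    learning_rate: float = 1e-3
    feature_epochs: int = 500
    # continued (warm-start) training per iteration after the first uses a
    # shorter budget, as is conventional for EM-style refinement loops
    em_epochs: int = 200
    cluster_epochs: int = 500
    imputation_epochs: int = 500
    batch_size: int | None = None
    alpha: float = 0.5
    min_cluster_cells: int = 10
    regularizers: ImputationRegularizerConfig = field(default_factory=ImputationRegularizerConfig)
    # cell graph
    knn_k: int | None = None
    contamination: float = 0.1
    self_loops: bool = False
    # graph autoencoder
    gae_dims: tuple[int, int] = (32, 16)
    gae_epochs: int = 200
    gae_learning_rate: float = 1e-3
    # positive-class reweighting is on by default in the pipeline: on sparse
    # cell graphs the unweighted cross-entropy has a degenerate optimum at
    # Z = 0 (all probabilities 0.5) because the ReLU embedding is non-negative
    gae_pos_weight: bool = True
    # the imputation autoencoder trains from scratch by default; continuing
    # from the smoothed feature autoencoder reproduces its reconstruction
    # instead of learning the crisper non-zero structure of the raw matrix
    imputation_warm_start: bool = False
    # clustering
    resolution: float = 1.0
    louvain_weighted: bool = False
    # cluster count = mode over several seeded Louvain runs (less noisy than
    # a single modularity optimisation on a sparse KNN graph)
    louvain_consensus_runs: int = 5
    # loop
    iteration: IterationConfig = field(default_factory=IterationConfig)

    @classmethod
    def desk_scale(cls, **overrides) -> "ScgnnConfig":
        """Profile for desk-scale matrices (hundreds of cells).

        Shorter training budgets than the full-scale defaults: on small,
        over-parameterized matrices long full-batch training memorizes noise
        (see the methods note), and the benchmark suite must run on one CPU.
        """
        cfg = dict(
            feature_epochs=150,
            em_epochs=50,
            cluster_epochs=150,
            imputation_epochs=500,
            gae_epochs=150,
            ltmg_restarts=2,
        )
        cfg.update(overrides)
        return cls(**cfg)


@dataclass
class ScgnnResult:
    imputed: ExpressionMatrix
    clusters: ClusterAssignment
    embedding: Embedding
    graph_embedding: GraphEmbedding | None
    graph: CellGraph
    preprocessed: ExpressionMatrix
    report: dict


def stage_seed(master: int, stage: str, iteration: int = 0) -> int:
    """Deterministic per-stage seed: crc32 of 'stage:iteration' mixed with
    the master seed, reduced below 2^31."""
    h = zlib.crc32(f"{stage}:{iteration}".encode())
    return (int(master) * 1_000_003 + h) % (2**31 - 1)


def mix_adjacency(l0: np.ndarray, a_t: np.ndarray, mixing_lambda: float) -> np.ndarray:
    """lambda * L0 + (1 - lambda) * rowNormalize(A_t); zero rows stay zero."""
    l0 = np.asarray(l0, float)
    a_t = np.asarray(a_t, float)
    if l0.shape != a_t.shape:
        raise ValueError("adjacency shapes differ")
    row_sums = a_t.sum(axis=1, keepdims=True)
    row_norm = np.divide(a_t, row_sums, out=np.zeros_like(a_t), where=row_sums > 0)
    return mixing_lambda * l0 + (1.0 - mixing_lambda) * row_norm


def check_convergence(
    a_prev: np.ndarray,
    a_curr: np.ndarray,
    a_init: np.ndarray,
    labels_prev,
    labels_curr,
    cfg: IterationConfig,
) -> tuple[bool, str]:
    """Stop when the adjacency change is small or clusterings agree."""
    g1, g2 = cfg.conv_adj_threshold, cfg.conv_ari_threshold
    ari = adjusted_rand_index(labels_prev, labels_curr)
    if cfg.literal_convergence:
        adj_ok = bool(np.all(a_curr - a_prev < g1 * a_init))
        ari_ok = ari < g2
    else:
        diff = np.abs(a_curr - a_prev).sum()
        adj_ok = diff < (1.0 - g1) * np.abs(a_init).sum()
        ari_ok = ari > g2
    if adj_ok:
        return True, "adjacency_converged"
    if ari_ok:
        return True, "clustering_converged"
    return False, f"continue (ARI={ari:.3f})"


def _dense_cfg(cfg: ScgnnConfig, epochs: int, seed: int) -> DenseAEConfig:
    return DenseAEConfig(
        encoder_dims=cfg.encoder_dims,
        learning_rate=cfg.learning_rate,
        epochs=epochs,
        batch_size=cfg.batch_size,
        seed=seed,
    )


def run_scgnn(
    x_raw: ExpressionMatrix,
    config: ScgnnConfig | None = None,
    seed: int = 0,
) -> ScgnnResult:
    """Execute the full pipeline on a raw (or pre-processed) matrix.

    All stage seeds derive deterministically from ``seed``.  The per-iteration
    losses, cluster counts and the stop reason are collected in
    ``result.report``.
    """
    cfg = config or ScgnnConfig()
    it_cfg = cfg.iteration
    if cfg.do_preprocess:
        n_top = x_raw.n_genes if it_cfg.use_all_genes else cfg.n_top_genes
        x_pre = preprocess(
            x_raw,
            gene_min_cell_frac=cfg.gene_min_cell_frac,
            cell_min_gene_frac=cfg.cell_min_gene_frac,
            n_top=n_top,
        )
    else:
        x_pre = x_raw if x_raw.layer_tag == "preprocessed" else x_raw.with_values(
            x_raw.values, layer_tag="preprocessed"
        )

    trs = build_trs_matrix(
        x_pre,
        max_components=cfg.max_components,
        truncation_point=cfg.truncation_point,
        seed=stage_seed(seed, "ltmg", 0),
        n_restarts=cfg.ltmg_restarts,
    )
    trs_w = trs.to_weights(cfg.trs_weight_mode)

    current = x_pre
    n = x_pre.n_cells
    k_knn = cfg.knn_k or default_k(n)
    report: dict = {"iterations": [], "stop_reason": None, "seed": seed}

    l0 = None
    prev_tilde = None
    prev_labels = None
    graph = None
    clusters = None
    emb = None
    z_emb = None
    feature_model = None
    gae_weights = None
    stop_reason = "max_iterations"

    for t in range(1, it_cfg.max_iterations + 1):
        if cfg.refit_ltmg and t > 1:
            trs = build_trs_matrix(
                current,
                max_components=cfg.max_components,
                truncation_point=cfg.truncation_point,
                seed=stage_seed(seed, "ltmg", t),
                n_restarts=cfg.ltmg_restarts,
            )
            trs_w = trs.to_weights(cfg.trs_weight_mode)

        # warm start: later iterations continue training the same model so
        # the embedding stays in one basin and the loop can converge
        fe = cfg.feature_epochs if feature_model is None else cfg.em_epochs
        emb, recon, f_losses, feature_model = train_feature_ae(
            current, trs_w, _dense_cfg(cfg, fe, stage_seed(seed, "feature", 1)),
            alpha=cfg.alpha, model=feature_model,
        )
        graph = prune_graph(
            build_knn_graph(emb, k_knn), contamination=cfg.contamination
        )
        a_bin, _, a_norm = adjacency_views(graph, self_loops=cfg.self_loops)
        if l0 is None:
            l0 = a_norm
            tilde = a_norm
        else:
            tilde = mix_adjacency(l0, a_bin, it_cfg.mixing_lambda)

        if it_cfg.skip_graph_ae:
            z_emb = None
            clusters = louvain_communities(
                graph, resolution=cfg.resolution, seed=stage_seed(seed, "louvain", t),
                weighted=cfg.louvain_weighted,
            )
            gae_final = None
        else:
            z_emb, gae_losses, gae_weights = train_gae(
                graph,
                emb,
                GAEConfig(
                    layer_dims=cfg.gae_dims,
                    learning_rate=cfg.gae_learning_rate,
                    epochs=cfg.gae_epochs if gae_weights is None else cfg.em_epochs,
                    seed=stage_seed(seed, "gae", 1),
                ),
                propagation=tilde,
                pos_weight=cfg.gae_pos_weight,
                init_weights=gae_weights,
            )
            k_louvain = louvain_cluster_count(
                graph, resolution=cfg.resolution, seed=stage_seed(seed, "louvain", t),
                weighted=cfg.louvain_weighted, consensus_runs=cfg.louvain_consensus_runs,
            )
            # cluster on unit-norm rows: the inner-product decoder makes the
            # embedding's geometry angular, and norm variation only encodes
            # degree, which k-means would otherwise split on
            zv = z_emb.vectors
            zn = zv / np.maximum(np.linalg.norm(zv, axis=1, keepdims=True), 1e-12)
            clusters = kmeans_on_embedding(zn, k_louvain, seed=stage_seed(seed, "kmeans", t))
            gae_final = gae_losses[-1]

        report["iterations"].append(
            {
                "iteration": t,
                "feature_loss_final": f_losses[-1],
                "gae_loss_final": gae_final,
                "n_clusters": clusters.n_clusters,
                "n_edges": graph.n_edges,
            }
        )

        if it_cfg.skip_graph_ae and it_cfg.skip_cluster_ae:
            # with both ablations nothing feeds back: a single pass of
            # feature AE + Louvain is the whole pipeline
            stop_reason = "ablation_single_pass"
            break
        if prev_labels is not None:
            stop, reason = check_convergence(
                prev_tilde, tilde, l0, prev_labels, clusters.labels, it_cfg
            )
            report["iterations"][-1]["convergence"] = reason
            if stop:
                stop_reason = reason
                break
        if t == it_cfg.max_iterations:
            break

        if it_cfg.skip_cluster_ae:
            current = recon
        else:
            current, _ = train_cluster_ae(
                recon,
                clusters,
                _dense_cfg(cfg, cfg.cluster_epochs, stage_seed(seed, "cluster", t)),
                min_cells=cfg.min_cluster_cells,
            )
        prev_tilde = tilde
        prev_labels = clusters.labels

    report["stop_reason"] = stop_reason
    report["n_iterations"] = len(report["iterations"])

    a_bin, _, _ = adjacency_views(graph, self_loops=False)
    imputed, imp_losses = train_imputation_ae(
        x_pre,
        trs.to_weights(cfg.imputation_trs_weight_mode),
        a_bin,
        clusters,
        _dense_cfg(cfg, cfg.imputation_epochs, stage_seed(seed, "imputation", 0)),
        cfg.regularizers,
        model=feature_model if cfg.imputation_warm_start else None,
    )
    report["imputation_loss_final"] = imp_losses[-1]
    return ScgnnResult(
        imputed=imputed,
        clusters=clusters,
        embedding=emb,
        graph_embedding=z_emb,
        graph=graph,
        preprocessed=x_pre,
        report=report,
    )


def impute_benchmark(
    x_raw: ExpressionMatrix,
    rate: float = 0.1,
    repeats: int = 3,
    seed: int = 0,
    config: ScgnnConfig | None = None,
    mode: str = "rowwise",
) -> dict:
    """Synthetic-dropout imputation benchmark with baseline comparisons.

    Preprocesses the matrix once, then for each repeat flips ``rate`` of the
    non-zero entries to zero, runs the full pipeline on the corrupted matrix,
    and scores masked-entry recovery for the pipeline and for the zeros /
    gene-mean baselines.  Returns per-repeat metrics plus mean and SD.
    """
    cfg = config or ScgnnConfig()
    if cfg.do_preprocess:
        n_top = x_raw.n_genes if cfg.iteration.use_all_genes else cfg.n_top_genes
        x_pre = preprocess(x_raw, cfg.gene_min_cell_frac, cfg.cell_min_gene_frac, n_top=n_top)
    else:
        x_pre = x_raw
    run_cfg = replace(cfg, do_preprocess=False)
    repeats_out = []
    for r in range(repeats):
        rep_seed = stage_seed(seed, "dropout", r)
        corrupted, mask = synthetic_dropout(x_pre, rate, seed=rep_seed)
        result = run_scgnn(corrupted, run_cfg, seed=rep_seed)
        scores = {"scgnn": masked_metrics(x_pre, result.imputed, mask, mode=mode)}
        for name, baseline in baseline_imputations(corrupted).items():
            scores[name] = masked_metrics(x_pre, baseline, mask, mode=mode)
        repeats_out.append({"seed": rep_seed, "scores": scores, "report": result.report})
    summary: dict = {"rate": rate, "repeats": repeats_out, "mode": mode}
    for method in ("scgnn", "zeros", "gene_mean"):
        for metric in ("median_l1", "cosine", "rmse"):
            vals = [r["scores"][method][metric] for r in repeats_out]
            summary[f"{method}_{metric}_mean"] = float(np.mean(vals))
            summary[f"{method}_{metric}_sd"] = float(np.std(vals))
    return summary
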