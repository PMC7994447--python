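"""Reading scRNA-Seq expression matrices and the standard preprocessing pipeline.

The pipeline mirrors common single-cell quality control: drop genes expressed
in too few cells and cells expressing too few genes, log-transform, and keep
the most variable genes.  All downstream stages operate on the dense
cells x genes :class:`ExpressionMatrix`.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "ExpressionMatrix",
    "read_matrix",
    "filter_cells_genes",
    "log_transform",
    "select_variable_genes",
    "preprocess",
]

LAYER_TAGS = ("raw", "preprocessed", "reconstructed", "imputed")


class DegenerateInputError(ValueError):
    """Raised when filtering empties an axis; relax the thresholds."""


@dataclass
class ExpressionMatrix:
    """Dense non-negative cells x genes expression matrix with identifiers.

    ``values`` is always oriented cells (rows) x genes (columns), whatever the
    on-disk orientation was.  ``layer_tag`` records which stage of the pipeline
    produced the matrix (raw counts, preprocessed, autoencoder reconstruction,
    or final imputation).
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    layer_tag: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = list(map(str, self.cell_ids))
        self.gene_ids = list(map(str, self.gene_ids))
        self.validate()

    def validate(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, m = self.values.shape
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} rows")
        if len(self.gene_ids) != m:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {m} columns")
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell ids are not unique")
        if len(set(self.gene_ids)) != m:
            raise ValueError("gene ids are not unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain NaN/Inf")
        if np.any(self.values < 0):
            raise ValueError("values contain negative entries")
        if self.layer_tag not in LAYER_TAGS:
            raise ValueError(f"unknown layer_tag {self.layer_tag!r}")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, layer_tag: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=values,
            cell_ids=list(self.cell_ids),
            gene_ids=list(self.gene_ids),
            layer_tag=layer_tag or self.layer_tag,
        )

    def subset(
        self,
        cell_idx: np.ndarray | None = None,
        gene_idx: np.ndarray | None = None,
        layer_tag: str | None = None,
    ) -> "ExpressionMatrix":
        values = self.values
        cell_ids = self.cell_ids
        gene_ids = self.gene_ids
        if gene_idx is not None:
            values = values[:, gene_idx]
            gene_ids = [gene_ids[i] for i in np.atleast_1d(gene_idx)]
        if cell_idx is not None:
            values = values[cell_idx, :]
            cell_ids = [cell_ids[i] for i in np.atleast_1d(cell_idx)]
        return ExpressionMatrix(values, cell_ids, gene_ids, layer_tag or self.layer_tag)

    def to_csv(self, path: str | pathlib.Path) -> None:
        pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids).to_csv(path)


def _read_sidecar(path: pathlib.Path) -> list[str]:
    ids = pd.read_csv(path, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
    return ids


def read_matrix(
    path: str | pathlib.Path,
    fmt: str = "csv",
    orientation: str = "cells_by_genes",
    barcodes: str | pathlib.Path | None = None,
    features: str | pathlib.Path | None = None,
) -> ExpressionMatrix:
    """Read a CSV/TSV or Matrix-Market expression matrix as cells x genes.

    CSV convention: first row holds gene ids, first column cell ids (swapped
    when ``orientation='genes_by_cells'``).  MTX follows the 10x convention of
    genes x cells on disk with ``features``/``barcodes`` sidecar files; when
    not given they are looked up next to the matrix file.
    """
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "csv":
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except pd.errors.ParserError as exc:
            raise ValueError(f"malformed CSV {path}: {exc}") from exc
        values = df.to_numpy(dtype=float)
        row_ids = df.index.astype(str).tolist()
        col_ids = df.columns.astype(str).tolist()
        if orientation == "cells_by_genes":
            return ExpressionMatrix(values, row_ids, col_ids, "raw")
        return ExpressionMatrix(values.T, col_ids, row_ids, "raw")
    if fmt == "mtx":
        try:
            mat = scipy.io.mmread(path)
        except ValueError as exc:
            raise ValueError(f"malformed MTX {path}: {exc}") from exc
        mat = scipy.sparse.coo_matrix(mat).toarray().astype(float)
        bpath = pathlib.Path(barcodes) if barcodes else path.parent / "barcodes.tsv"
        fpath = pathlib.Path(features) if features else path.parent / "features.tsv"
        if not fpath.exists():
            alt = path.parent / "genes.tsv"
            fpath = alt if alt.exists() else fpath
        # 10x stores genes x cells on disk; orientation declares the disk layout
        values = mat.T if orientation == "genes_by_cells" else mat
        cell_ids = _read_sidecar(bpath) if bpath.exists() else [f"cell{i}" for i in range(values.shape[0])]
        gene_ids = _read_sidecar(fpath) if fpath.exists() else [f"gene{i}" for i in range(values.shape[1])]
        if len(cell_ids) != values.shape[0] or len(gene_ids) != values.shape[1]:
            raise ValueError(
                f"sidecar dimensions ({len(cell_ids)} barcodes, {len(gene_ids)} features) "
                f"do not match matrix shape {values.shape}"
            )
        return ExpressionMatrix(values, cell_ids, gene_ids, "raw")
    raise ValueError(f"unknown format {fmt!r}")


def filter_cells_genes(
    x: ExpressionMatrix,
    gene_min_cell_frac: float = 0.01,
    cell_min_gene_frac: float = 0.01,
    order: str = "genes_first",
) -> ExpressionMatrix:
    """Keep genes non-zero in strictly more than ``gene_min_cell_frac`` of
    cells and cells non-zero in strictly more than ``cell_min_gene_frac`` of
    genes.  Applied one pass per axis, genes first by default."""
    values = x.values
    cell_idx = np.arange(x.n_cells)
    gene_idx = np.arange(x.n_genes)

    def _gene_pass(v, ci, gi):
        frac = (v != 0).mean(axis=0)
        keep = frac > gene_min_cell_frac
        return v[:, keep], ci, gi[keep]

    def _cell_pass(v, ci, gi):
        frac = (v != 0).mean(axis=1)
        keep = frac > cell_min_gene_frac
        return v[keep, :], ci[keep], gi

    passes = (_gene_pass, _cell_pass) if order == "genes_first" else (_cell_pass, _gene_pass)
    for p in passes:
        values, cell_idx, gene_idx = p(values, cell_idx, gene_idx)
        if values.shape[0] == 0 or values.shape[1] == 0:
            raise DegenerateInputError(
                "filtering removed every cell or gene; relax gene_min_cell_frac/"
                "cell_min_gene_frac"
            )
    return x.subset(cell_idx=cell_idx, gene_idx=gene_idx)


def log_transform(x: ExpressionMatrix) -> ExpressionMatrix:
    """Entry-wise log(1 + value); zeros map to zeros."""
    return x.with_values(np.log1p(x.values), layer_tag="preprocessed")


def select_variable_genes(x: ExpressionMatrix, n_top: int = 2000) -> ExpressionMatrix:
    """Restrict to the ``n_top`` genes with the largest standard deviation.

    Output genes are ordered by descending SD with lexicographic gene-id
    tie-break, so the selection is deterministic.
    """
    if x.n_genes < 1:
        raise ValueError("matrix has no genes")
    sds = x.values.std(axis=0)
    order = sorted(range(x.n_genes), key=lambda i: (-sds[i], x.gene_ids[i]))
    keep = np.array(order[: min(n_top, x.n_genes)], dtype=int)
    return x.subset(gene_idx=keep)


def preprocess(
    x: ExpressionMatrix,
    gene_min_cell_frac: float = 0.01,
    cell_min_gene_frac: float = 0.01,
    n_top: int = 2000,
    filter_order: str = "genes_first",
    rank_on: str = "log",
    median_scale: bool = False,
) -> ExpressionMatrix:
    """Full preprocessing: filter -> (optional library scaling) -> log ->
    top-variable-gene selection.

    ``rank_on='raw'`` ranks gene variability on the pre-log values instead.
    ``median_scale`` rescales each cell's counts to the median library size
    before the log transform (off by default).
    """
    x = filter_cells_genes(x, gene_min_cell_frac, cell_min_gene_frac, order=filter_order)
    if median_scale:
        libsize = x.values.sum(axis=1)
        libsize[libsize == 0] = 1.0
        scale = np.median(libsize) / libsize
        x = x.with_values(x.values * scale[:, None])
    if rank_on == "raw":
        selected = select_variable_genes(x, n_top)
        return log_transform(selected)
    return select_variable_genes(log_transform(x), n_top)
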