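"""Pre-clustering stack: QC, filtering, normalization, HVGs, PCA, BBKNN.

Cells are retained when they detect between ``min_genes_per_cell`` and
``max_genes_per_cell`` genes (inclusive) and their mitochondrial count
fraction is strictly below ``max_pct_mito``; genes expressed in at most
``min_cells_per_gene_exclusive`` of the remaining cells are removed.
Normalization is global scaling: counts divided by the cell total,
multiplied by a scale factor, then ``log(1 + x)``.

Dimension reduction follows the classic recipe: per-gene dispersion
(variance/mean of normalized expression) standardized within
equal-frequency mean bins to pick highly variable genes, per-gene
z-scoring (clipped) and exact PCA with a deterministic sign convention,
then a batch-balanced k-nearest-neighbour graph in PC space in which
every cell takes its k nearest neighbours *within each batch*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.neighbors import NearestNeighbors

from .errors import EmptyResultError, ValidationError
from .io_formats import CountMatrix
from .params import PipelineParams

__all__ = [
    "ExpressionMatrix",
    "QCMetrics",
    "EmbeddingSpace",
    "NeighborGraph",
    "compute_qc",
    "filter_cells_genes",
    "normalize_log1p",
    "select_hvg",
    "scale_and_pca",
    "build_batch_balanced_graph",
    "HVGSelector",
    "ScaledPCA",
    "BatchBalancedNeighbors",
]


@dataclass
class ExpressionMatrix:
    """Real-valued genes x cells expression with the same annotation."""

    values: sp.csr_matrix
    gene_symbols: list
    barcodes: list
    cell_meta: pd.DataFrame

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_row(self, symbol: str) -> np.ndarray:
        idx = self.gene_symbols.index(symbol)
        return np.asarray(self.values[idx].todense()).ravel()

    def subset_cells(self, cell_mask) -> "ExpressionMatrix":
        cm = np.asarray(cell_mask)
        if cm.dtype != bool:
            tmp = np.zeros(self.n_cells, bool)
            tmp[cm] = True
            cm = tmp
        return ExpressionMatrix(
            values=self.values[:, cm].tocsr(),
            gene_symbols=list(self.gene_symbols),
            barcodes=[b for b, k in zip(self.barcodes, cm) if k],
            cell_meta=self.cell_meta.loc[cm].copy(),
        )


@dataclass
class QCMetrics:
    """Per-cell QC table: n_genes_detected, total_counts, pct_mito."""

    table: pd.DataFrame  # index barcode

    def __getitem__(self, col: str) -> pd.Series:
        return self.table[col]


@dataclass
class EmbeddingSpace:
    """PCA embedding: cell scores, gene loadings, explained variance."""

    scores: np.ndarray  # cells x n_pcs
    loadings: np.ndarray  # hvg genes x n_pcs
    explained_variance: np.ndarray
    hvg_list: list
    barcodes: list


@dataclass
class NeighborGraph:
    """Directed within-batch kNN edge list over cells."""

    n_cells: int
    src: np.ndarray
    dst: np.ndarray
    dist: np.ndarray
    batch_labels: np.ndarray
    k_within_batch: int

    def to_igraph(self):
        """Symmetrized undirected simple graph for community detection."""
        import igraph

        edges = {tuple(sorted((int(a), int(b)))) for a, b in zip(self.src, self.dst)}
        g = igraph.Graph(n=self.n_cells, edges=sorted(edges), directed=False)
        return g


# ---------------------------------------------------------------------------
# QC and filtering
# ---------------------------------------------------------------------------

def compute_qc(m: CountMatrix, params: PipelineParams) -> QCMetrics:
    """Detected genes, total counts and mitochondrial fraction per cell.

    ``pct_mito`` is the fraction of counts on genes whose symbol starts
    with ``params.mito_prefix`` (0 for empty cells).
    """
    csc = m.values.tocsc()
    n_genes_detected = np.asarray((csc > 0).sum(axis=0)).ravel()
    total = np.asarray(csc.sum(axis=0)).ravel()
    mito_mask = np.array(
        [s.upper().startswith(params.mito_prefix.upper()) for s in m.gene_symbols]
    )
    mito = np.asarray(csc[mito_mask].sum(axis=0)).ravel() if mito_mask.any() else np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    table = pd.DataFrame(
        {
            "n_genes_detected": n_genes_detected.astype(int),
            "total_counts": total.astype(int),
            "pct_mito": pct,
        },
        index=pd.Index(m.barcodes, name="barcode"),
    )
    return QCMetrics(table)


def filter_cells_genes(
    m: CountMatrix, qc: QCMetrics, params: PipelineParams
) -> tuple:
    """Apply the cell filter, then the gene filter; report removals.

    Cells kept iff ``min <= n_genes_detected <= max`` (inclusive) and
    ``pct_mito < max_pct_mito`` (cells at exactly the cutoff are
    excluded). Genes kept iff expressed (count > 0) in strictly more
    than ``min_cells_per_gene_exclusive`` of the *remaining* cells.
    """
    t = qc.table
    low = t["n_genes_detected"] < params.min_genes_per_cell
    high = t["n_genes_detected"] > params.max_genes_per_cell
    mito = t["pct_mito"] >= params.max_pct_mito
    cell_keep = ~(low | high | mito)
    kept = m.subset(cell_mask=cell_keep.to_numpy())
    if kept.n_cells == 0:
        raise EmptyResultError("empty after filtering: no cells pass QC")
    cells_per_gene = np.asarray((kept.values > 0).sum(axis=1)).ravel()
    gene_keep = cells_per_gene > params.min_cells_per_gene_exclusive
    out = kept.subset(gene_mask=gene_keep)
    if out.n_genes == 0:
        raise EmptyResultError("empty after filtering: no genes pass the cell-count rule")
    report = {
        "input_cells": int(m.n_cells),
        "input_genes": int(m.n_genes),
        "cells_removed_low_genes": int(low.sum()),
        "cells_removed_high_genes": int((high & ~low).sum()),
        "cells_removed_mito": int((mito & ~low & ~high).sum()),
        "cells_removed_total": int((~cell_keep).sum()),
        "cells_kept": int(out.n_cells),
        "genes_removed_low_cells": int((~gene_keep).sum()),
        "genes_kept": int(out.n_genes),
        "filter_order": "cells_then_genes",
    }
    return out, report


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_log1p(m: CountMatrix, params: PipelineParams) -> ExpressionMatrix:
    """Library-size normalize and log-transform the counts.

    ``value(g, c) = ln(1 + scale_factor * count(g, c) / total(c))``;
    zeros stay exactly zero, so sparsity is preserved.
    """
    totals = np.asarray(m.values.sum(axis=0)).ravel().astype(float)
    if (totals == 0).any():
        raise ValidationError(
            "cells with zero total counts present: run filter_cells_genes first"
        )
    csc = m.values.tocsc().astype(float)
    # scale each column by scale_factor / total, then log1p the data
    scale = params.scale_factor / totals
    csc = csc.multiply(scale[None, :]).tocsc()
    csc.data = np.log1p(csc.data)
    return ExpressionMatrix(
        values=csc.tocsr(),
        gene_symbols=list(m.gene_symbols),
        barcodes=list(m.barcodes),
        cell_meta=m.cell_meta.copy(),
    )


# ---------------------------------------------------------------------------
# HVG selection
# ---------------------------------------------------------------------------

class HVGSelector(BaseEstimator):
    """Rank genes by binned, standardized dispersion of expression.

    Dispersion is variance/mean of normalized expression per gene,
    z-scored within ``n_bins`` equal-frequency mean bins so that genes
    are compared against others of similar abundance. Ties are broken
    by feature-name order for determinism.

    Follows the scikit-learn estimator protocol; ``X`` is cells x genes.
    """

    def __init__(self, n_top: int = 2000, n_bins: int = 20):
        self.n_top = n_top
        self.n_bins = n_bins

    def fit(self, X, y=None, feature_names=None):
        X = sp.csc_matrix(X) if sp.issparse(X) else np.asarray(X)
        n_cells, n_genes = X.shape
        if feature_names is None:
            feature_names = [f"g{i}" for i in range(n_genes)]
        feature_names = list(feature_names)
        if sp.issparse(X):
            mean = np.asarray(X.mean(axis=0)).ravel()
            sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
        else:
            mean = X.mean(axis=0)
            sq = (X ** 2).mean(axis=0)
        var = np.maximum(sq - mean ** 2, 0.0) * (n_cells / max(n_cells - 1, 1))
        if np.allclose(var, 0.0):
            raise ValidationError("constant expression matrix: no variability to rank")
        with np.errstate(invalid="ignore", divide="ignore"):
            disp = np.where(mean > 0, var / np.maximum(mean, 1e-300), 0.0)

        # equal-frequency mean bins; z-score dispersion within each bin
        n_bins = min(self.n_bins, n_genes)
        order = np.lexsort((np.array(feature_names), mean))
        bins = np.empty(n_genes, int)
        bins[order] = np.minimum((np.arange(n_genes) * n_bins) // n_genes, n_bins - 1)
        z = np.zeros(n_genes)
        for b in range(n_bins):
            idx = bins == b
            if not idx.any():
                continue
            d = disp[idx]
            sd = d.std(ddof=1) if idx.sum() > 1 else 0.0
            z[idx] = (d - d.mean()) / sd if sd > 0 else 0.0
        z[var == 0] = -np.inf  # flat genes always rank below variable ones

        rank_order = np.lexsort((np.array(feature_names), -z))
        self.n_features_in_ = n_genes
        self.feature_names_ = feature_names
        self.dispersions_ = disp
        self.dispersions_norm_ = z
        self.ranking_ = rank_order
        n_top = min(self.n_top, n_genes)
        if n_top < self.n_top:
            warnings.warn(
                f"only {n_genes} genes available; returning all (requested {self.n_top})"
            )
        support = np.zeros(n_genes, bool)
        support[rank_order[:n_top]] = True
        self.support_ = support
        self.selected_ = [feature_names[i] for i in rank_order[:n_top]]
        return self

    def transform(self, X):
        X = sp.csc_matrix(X) if sp.issparse(X) else np.asarray(X)
        return X[:, self.support_]


def select_hvg(norm: ExpressionMatrix, params: PipelineParams) -> list:
    """Top ``n_hvg`` genes by binned-dispersion ranking (ordered)."""
    sel = HVGSelector(n_top=params.n_hvg, n_bins=params.hvg_bins)
    sel.fit(norm.values.T, feature_names=norm.gene_symbols)
    return sel.selected_


# ---------------------------------------------------------------------------
# Scaling and PCA
# ---------------------------------------------------------------------------

class ScaledPCA(BaseEstimator, TransformerMixin):
    """Per-gene z-scoring (clipped) followed by exact PCA.

    Gene standard deviations are clamped below by ``sd_floor`` and
    z-scores clipped at ``+-clip`` to bound outlier leverage. PCA is an
    exact eigendecomposition of the feature covariance; each component's
    sign is fixed so its largest-magnitude loading is positive, making
    downstream trajectories reproducible. ``X`` is cells x genes.
    """

    def __init__(self, n_components: int = 7, clip: float = 10.0, sd_floor: float = 1e-8):
        self.n_components = n_components
        self.clip = clip
        self.sd_floor = sd_floor

    def _zscore(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.mean_) / self.scale_
        np.clip(Z, -self.clip, self.clip, out=Z)
        return Z

    def fit(self, X, y=None):
        X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)
        n_cells, n_genes = X.shape
        if n_cells < self.n_components:
            raise ValidationError(
                f"fewer cells ({n_cells}) than requested components ({self.n_components})"
            )
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1) if n_cells > 1 else np.zeros(n_genes)
        self.scale_ = np.maximum(sd, self.sd_floor)
        Z = self._zscore(X)
        Zc = Z - Z.mean(axis=0)  # clipping can shift the mean slightly
        cov = (Zc.T @ Zc) / max(n_cells - 1, 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1][: self.n_components]
        comps = evecs[:, order].T  # n_components x genes
        evals = np.maximum(evals[order], 0.0)
        for i in range(comps.shape[0]):
            j = np.argmax(np.abs(comps[i]))
            if comps[i, j] < 0:
                comps[i] = -comps[i]
        self.components_ = comps
        self.explained_variance_ = evals
        self._train_scores_ = Zc @ comps.T
        self._zc_mean_ = Z.mean(axis=0)
        return self

    def transform(self, X):
        X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)
        Z = self._zscore(X) - self._zc_mean_
        return Z @ self.components_.T

    def fit_transform(self, X, y=None):
        self.fit(X)
        return self._train_scores_


def scale_and_pca(
    norm: ExpressionMatrix, hvg: list, params: PipelineParams
) -> EmbeddingSpace:
    """Z-score the HVG submatrix and embed cells into ``n_pcs`` PCs."""
    lookup = {g: i for i, g in enumerate(norm.gene_symbols)}
    missing = [g for g in hvg if g not in lookup]
    if missing:
        raise ValidationError(f"HVGs not present in matrix: {missing[:5]}...")
    idx = [lookup[g] for g in hvg]
    X = np.asarray(norm.values[idx].todense()).T  # cells x hvg
    est = ScaledPCA(n_components=params.n_pcs, clip=params.zscore_clip)
    scores = est.fit_transform(X)
    return EmbeddingSpace(
        scores=scores,
        loadings=est.components_.T,
        explained_variance=est.explained_variance_,
        hvg_list=list(hvg),
        barcodes=list(norm.barcodes),
    )


# ---------------------------------------------------------------------------
# Batch-balanced kNN graph
# ---------------------------------------------------------------------------

class BatchBalancedNeighbors(BaseEstimator):
    """Within-batch kNN: each cell takes k nearest cells in every batch.

    The union over batches gives the directed edge list; symmetrization
    happens when the graph is handed to community detection. A batch
    with a single cell contributes no edges (with a warning).
    """

    def __init__(self, k_within_batch: int = 3):
        self.k_within_batch = k_within_batch

    def fit(self, X, y=None, batch=None):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if batch is None:
            batch = np.zeros(n, int)
        batch = np.asarray(batch)
        if len(batch) != n:
            raise ValidationError("batch label length does not match cell count")
        src_all: list = []
        dst_all: list = []
        dist_all: list = []
        for b in pd.unique(batch):
            members = np.flatnonzero(batch == b)
            if len(members) < 2:
                warnings.warn(f"batch {b!r} has {len(members)} cell(s); contributes no edges")
                continue
            k = min(self.k_within_batch, len(members) - 1)
            nn = NearestNeighbors(n_neighbors=min(k + 1, len(members))).fit(X[members])
            dist, idx = nn.kneighbors(X)
            neigh = members[idx]  # n x (k+1) global indices
            not_self = neigh != np.arange(n)[:, None]
            # stable-sort moves non-self neighbours first, preserving order
            sel = np.argsort(~not_self, axis=1, kind="stable")[:, :k]
            rows = np.arange(n)[:, None]
            neigh_k = neigh[rows, sel]
            dist_k = dist[rows, sel]
            src_all.append(np.repeat(np.arange(n), k))
            dst_all.append(neigh_k.ravel())
            dist_all.append(dist_k.ravel())
        if not src_all:
            raise ValidationError("no batch produced edges")
        self.n_cells_ = n
        self.src_ = np.concatenate(src_all)
        self.dst_ = np.concatenate(dst_all)
        self.dist_ = np.concatenate(dist_all)
        self.batch_ = batch
        return self


def build_batch_balanced_graph(
    emb: EmbeddingSpace, batch_labels, params: PipelineParams
) -> NeighborGraph:
    """Batch-balanced neighbor graph over the PCA scores."""
    est = BatchBalancedNeighbors(k_within_batch=params.neighbors_within_batch)
    est.fit(emb.scores, batch=np.asarray(batch_labels))
    return NeighborGraph(
        n_cells=est.n_cells_,
        src=est.src_,
        dst=est.dst_,
        dist=est.dist_,
        batch_labels=est.batch_,
        k_within_batch=params.neighbors_within_batch,
    )
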