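"""Clustering, doublet detection, markers, consensus annotation.

Clustering is Leiden community detection on the symmetrized
batch-balanced kNN graph. Doublets are scored by the
artificial-nearest-neighbour approach: synthetic doublets (averaged
normalized profiles of random cell pairs) are co-embedded with the real
cells, each real cell's pANN is the fraction of artificial cells among
its nearest neighbours, and the neighbourhood size pK is chosen by
maximizing the mean-variance-normalized bimodality coefficient of the
pANN distribution. Cluster annotation runs three independent methods —
marker-evidence ranking, hypergeometric overlap with a marker-reference
database, and Spearman correlation against reference expression
profiles — and takes the label consistent in at least two of them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

from .errors import ValidationError
from .io_formats import MarkerReference
from .params import PipelineParams
from .preprocess import ExpressionMatrix, HVGSelector, NeighborGraph, ScaledPCA

__all__ = [
    "Clustering",
    "DoubletScores",
    "AnnotationResult",
    "cluster_graph",
    "score_doublets",
    "doublet_removal_mask",
    "find_markers",
    "annotate_consensus",
    "LeidenClustering",
    "DoubletDetector",
    "cluster_mean_profiles",
]

UNASSIGNED = "unassigned"
AMBIGUOUS = "ambiguous"


@dataclass
class Clustering:
    labels: np.ndarray  # contiguous ints from 0
    resolution: float
    seed: int
    modularity: float

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0


@dataclass
class DoubletScores:
    pann: np.ndarray  # per real cell, in [0, 1]
    pk: float
    n_expected: int
    call: np.ndarray  # bool per real cell
    bcmvn: pd.DataFrame  # pK grid with BC_mvn values


@dataclass
class AnnotationResult:
    table: pd.DataFrame  # per cluster: three labels, consensus, votes

    def consensus_for(self, cluster: int) -> str:
        return self.table.loc[cluster, "consensus"]

    def label_map(self) -> dict:
        return self.table["consensus"].to_dict()


# ---------------------------------------------------------------------------
# Leiden clustering
# ---------------------------------------------------------------------------

class LeidenClustering(BaseEstimator):
    """Leiden modularity clustering over a neighbor graph.

    ``fit`` accepts a :class:`NeighborGraph` (or an igraph Graph);
    labels are relabelled contiguously by first appearance so the
    result is deterministic under a fixed seed.
    """

    def __init__(self, resolution: float = 1.0, seed: int = 0):
        self.resolution = resolution
        self.seed = seed

    def fit(self, graph, y=None):
        import igraph
        import leidenalg

        if isinstance(graph, NeighborGraph):
            g = graph.to_igraph()
        elif isinstance(graph, igraph.Graph):
            g = graph
        else:
            raise ValidationError(f"unsupported graph type: {type(graph)!r}")
        if g.vcount() == 0:
            raise ValidationError("empty graph")
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=self.resolution,
            seed=self.seed,
            n_iterations=-1,
        )
        raw = np.asarray(part.membership)
        # contiguous relabel by first appearance
        remap: dict = {}
        labels = np.empty_like(raw)
        for i, lab in enumerate(raw):
            if lab not in remap:
                remap[lab] = len(remap)
            labels[i] = remap[lab]
        self.labels_ = labels
        self.modularity_ = float(g.modularity(labels))
        return self

    def fit_predict(self, graph, y=None):
        return self.fit(graph).labels_


def cluster_graph(g: NeighborGraph, params: PipelineParams) -> Clustering:
    """Partition the neighbor graph by Leiden community detection."""
    est = LeidenClustering(resolution=params.clustering_resolution, seed=params.random_seed)
    est.fit(g)
    return Clustering(
        labels=est.labels_,
        resolution=params.clustering_resolution,
        seed=params.random_seed,
        modularity=est.modularity_,
    )


# ---------------------------------------------------------------------------
# Doublet detection
# ---------------------------------------------------------------------------

def _bimodality_coefficient(x: np.ndarray) -> float:
    skew = scipy.stats.skew(x)
    kurt = scipy.stats.kurtosis(x, fisher=False)
    if kurt == 0:
        return np.nan
    return (skew ** 2 + 1.0) / kurt


class DoubletDetector(BaseEstimator):
    """pANN doublet scoring with BC_mvn neighbourhood-size selection.

    ``X`` is real cells x genes normalized expression. Artificial
    doublets (``artificial_frac`` of the real cell count) are the
    averaged profiles of random cell pairs; real and artificial cells
    are re-embedded with the same HVG/PCA settings as the main
    pipeline, and pANN(cell) is the fraction of artificial doublets
    among its ``ceil(pK * n_merged)`` nearest neighbours. ``pK`` is
    chosen on the grid {0.005, 0.010, ..., 0.3} by maximizing
    ``BC_mvn = mean(pANN) * BC / var(pANN)`` with
    ``BC = (skewness^2 + 1) / kurtosis``. The top ``rate * n`` cells by
    pANN are called doublets.
    """

    PK_GRID = np.round(np.arange(0.005, 0.3001, 0.005), 3)

    def __init__(
        self,
        expected_rate: float = 0.075,
        artificial_frac: float = 0.25,
        n_hvg: int = 2000,
        n_pcs: int = 7,
        n_bins: int = 20,
        clip: float = 10.0,
        seed: int = 0,
        pk_override: float | None = None,
    ):
        self.expected_rate = expected_rate
        self.artificial_frac = artificial_frac
        self.n_hvg = n_hvg
        self.n_pcs = n_pcs
        self.n_bins = n_bins
        self.clip = clip
        self.seed = seed
        self.pk_override = pk_override

    def fit(self, X, y=None, totals=None):
        X = sp.csr_matrix(X) if sp.issparse(X) else np.asarray(X, dtype=float)
        n = X.shape[0]
        if n < 50:
            raise ValidationError(f"doublet scoring needs >= 50 cells, got {n}")
        rng = np.random.default_rng(self.seed)
        n_art = max(int(round(self.artificial_frac * n)), 1)
        # pairs are drawn in a content-based canonical order so that the
        # scoring is label-free: permuting the input cells permutes the
        # scores identically
        Xc = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, float)
        canon = np.lexsort(Xc.T)
        ii_c = rng.integers(0, n, n_art)
        jj_c = rng.integers(0, n - 1, n_art)
        jj_c[jj_c >= ii_c] += 1  # distinct partner
        ii = canon[ii_c]
        jj = canon[jj_c]
        # mix the pair on the de-logged (library-normalized) scale: a
        # physical doublet pools its parents' transcripts, so parent
        # contributions are proportional to parent library sizes (equal
        # mixing when sizes are unknown), not averaged in log space.
        # When library sizes are available, the mixture is re-sampled at
        # an empirical sequencing depth so artificial doublets match the
        # detection-rate distribution of real libraries.
        Xd = Xc
        lin = np.expm1(Xd)
        if totals is not None:
            totals = np.asarray(totals, float)
            w = totals[ii] / (totals[ii] + totals[jj])
            mix = w[:, None] * lin[ii] + (1.0 - w[:, None]) * lin[jj]
            scale_sum = mix.sum(axis=1, keepdims=True)  # ~ the scale factor
            conc = mix / np.maximum(scale_sum, 1e-300)
            depth = totals[canon[rng.integers(0, n, n_art)]]
            counts = rng.poisson(depth[:, None] * conc)
            art = np.log1p(counts / depth[:, None] * scale_sum)
        else:
            art = np.log1p(0.5 * (lin[ii] + lin[jj]))
        dense = np.vstack([Xd, art])
        n_merged = n + n_art

        sel = HVGSelector(n_top=self.n_hvg, n_bins=self.n_bins)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel.fit(dense)
        sub = dense[:, sel.support_]
        pca = ScaledPCA(n_components=min(self.n_pcs, sub.shape[1]), clip=self.clip)
        scores = pca.fit_transform(sub)

        # neighbour lists queried once, generously, so that smaller
        # artificial subsets (the pN sweep) can be emulated by masking
        k_max = int(min(np.ceil(self.PK_GRID.max() * n_merged), n_merged - 1))
        k_query = int(min(k_max + n_art, n_merged - 1))
        nn = NearestNeighbors(n_neighbors=k_query + 1).fit(scores)
        _, idx = nn.kneighbors(scores[:n])
        idx = idx[:, 1:]  # drop self

        if self.pk_override is not None:
            pk_opt = float(self.PK_GRID[int(np.argmin(np.abs(self.PK_GRID - self.pk_override)))])
            bcmvn_tab = pd.DataFrame({"pK": [pk_opt], "BC_mean": [np.nan],
                                      "BC_var": [np.nan], "BC_mvn": [np.nan]})
        else:
            # pK selection: BC of the pANN distribution per (pN, pK), then
            # mean/variance normalization across the pN sweep per pK
            pn_grid = [f for f in (0.05, 0.10, 0.15, 0.20, 0.25, 0.30)
                       if f <= self.artificial_frac + 1e-9]
            bc_mat = np.full((len(pn_grid), len(self.PK_GRID)), np.nan)
            for a, pn in enumerate(pn_grid):
                n_sub = int(round(pn * n))
                valid = idx < n + n_sub  # real cells or artificial within subset
                order = np.argsort(~valid, axis=1, kind="stable")
                idx_v = np.take_along_axis(idx, order, axis=1)
                cum = np.cumsum((idx_v >= n).astype(float), axis=1)
                nm = n + n_sub
                for b, pk in enumerate(self.PK_GRID):
                    k = int(min(np.ceil(pk * nm), cum.shape[1]))
                    bc_mat[a, b] = _bimodality_coefficient(cum[:, k - 1] / k)
            # the variance term is stabilized with an absolute floor: across
            # a short pN sweep the sample variance of BC is dominated by
            # estimation noise, and an unfloored ratio would pick pK at
            # whichever grid point that noise happens to vanish
            with np.errstate(invalid="ignore", divide="ignore"):
                bcmvn = np.nanmean(bc_mat, axis=0) / (np.nanvar(bc_mat, axis=0) + 1e-3)
            bcmvn_tab = pd.DataFrame(
                {"pK": self.PK_GRID, "BC_mean": np.nanmean(bc_mat, axis=0),
                 "BC_var": np.nanvar(bc_mat, axis=0), "BC_mvn": bcmvn}
            )
            if np.isfinite(bcmvn).any():
                pk_opt = float(self.PK_GRID[int(np.nanargmax(bcmvn))])
            else:
                warnings.warn("degenerate pANN distribution; falling back to smallest pK")
                pk_opt = float(self.PK_GRID[0])

        # final pANN at the chosen pK with the full artificial set
        cum_full = np.cumsum((idx >= n).astype(float), axis=1)
        k = int(min(np.ceil(pk_opt * n_merged), cum_full.shape[1]))
        pann = cum_full[:, k - 1] / k
        # ties at small k are broken by the fraction over the widest
        # neighbourhood, keeping the call set deterministic but informed
        pann_fine = cum_full[:, k_max - 1] / k_max

        n_call = int(np.floor(self.expected_rate * n))
        call = np.zeros(n, bool)
        if n_call > 0:
            order = np.lexsort((np.arange(n), -pann_fine, -pann))
            call[order[:n_call]] = True
        self.pann_ = pann
        self.pk_ = pk_opt
        self.n_expected_ = n_call
        self.call_ = call
        self.bcmvn_ = bcmvn_tab
        return self


def score_doublets(
    norm, params: PipelineParams, dd_rate: float | None = None,
    seed: int | None = None, totals=None, pk_override: float | None = None,
) -> DoubletScores:
    """Score doublets on a normalized matrix (genes x cells).

    ``totals`` (per-cell library sizes, optional) let artificial
    doublets mix parents proportionally to their library sizes.
    """
    if isinstance(norm, ExpressionMatrix):
        X = norm.values.T.tocsr()
    else:
        X = sp.csr_matrix(norm).T.tocsr() if sp.issparse(norm) else np.asarray(norm).T
    det = DoubletDetector(
        expected_rate=params.doublet_rate if dd_rate is None else dd_rate,
        artificial_frac=params.artificial_doublet_frac,
        n_hvg=params.n_hvg,
        n_pcs=params.n_pcs,
        n_bins=params.hvg_bins,
        clip=params.zscore_clip,
        seed=params.random_seed if seed is None else seed,
        pk_override=pk_override,
    )
    det.fit(X, totals=totals)
    return DoubletScores(
        pann=det.pann_,
        pk=det.pk_,
        n_expected=det.n_expected_,
        call=det.call_,
        bcmvn=det.bcmvn_,
    )


def doublet_removal_mask(
    labels: np.ndarray, call: np.ndarray, cluster_frac: float = 0.60
) -> np.ndarray:
    """Cells to drop: called doublets plus whole infiltrated clusters.

    A cluster whose called-doublet fraction exceeds ``cluster_frac`` is
    removed entirely (its remaining singlets included).
    """
    labels = np.asarray(labels)
    call = np.asarray(call, bool)
    drop = call.copy()
    for lab in np.unique(labels):
        members = labels == lab
        if call[members].mean() > cluster_frac:
            drop |= members
    return drop


# ---------------------------------------------------------------------------
# Marker detection
# ---------------------------------------------------------------------------

def find_markers(
    norm: ExpressionMatrix, clustering: Clustering, params: PipelineParams
) -> pd.DataFrame:
    """Per-cluster marker table via rank-sum tests against the rest.

    A gene is a marker of a cluster when its BH-adjusted two-sided
    rank-sum p is below ``fdr_level``, its log2 fold change (de-logged
    means with a 1e-9 pseudocount) is positive, and it is detected in at
    least ``marker_min_pct`` of the cluster's cells. Clusters with
    fewer than 3 cells are skipped with a warning.
    """
    from .differential import bh_adjust, ranksum_p_vs_rest, _tie_term
    import scipy.stats as st

    labels = np.asarray(clustering.labels)
    dense = np.asarray(norm.values.todense())  # genes x cells
    expm1 = np.expm1(dense)
    genes = norm.gene_symbols
    ranks = st.rankdata(dense, axis=1)
    ties = _tie_term(dense)
    out = []
    for lab in np.unique(labels):
        members = labels == lab
        if members.sum() < 3:
            warnings.warn(f"cluster {lab} has {int(members.sum())} cells; skipped")
            continue
        x = dense[:, members]
        y = dense[:, ~members]
        p = ranksum_p_vs_rest(dense, members, ranks=ranks, tie_term=ties)
        fdr = bh_adjust(p)
        pct_in = (x > 0).mean(axis=1)
        pct_out = (y > 0).mean(axis=1)
        mean_in = expm1[:, members].mean(axis=1)
        mean_out = expm1[:, ~members].mean(axis=1)
        log2fc = np.log2((mean_in + 1e-9) / (mean_out + 1e-9))
        is_marker = (fdr < params.fdr_level) & (log2fc > 0) & (pct_in >= params.marker_min_pct)
        out.append(
            pd.DataFrame(
                {
                    "cluster": lab,
                    "gene": genes,
                    "log2fc": log2fc,
                    "pct_in": pct_in,
                    "pct_out": pct_out,
                    "p": p,
                    "fdr": fdr,
                    "is_marker": is_marker,
                }
            )
        )
    if not out:
        raise ValidationError("no cluster had >= 3 cells")
    return pd.concat(out, ignore_index=True)


def cluster_mean_profiles(norm: ExpressionMatrix, clustering: Clustering) -> pd.DataFrame:
    """Mean normalized expression per gene within each cluster."""
    labels = np.asarray(clustering.labels)
    cols = {}
    for lab in np.unique(labels):
        members = labels == lab
        cols[int(lab)] = np.asarray(norm.values[:, members].mean(axis=1)).ravel()
    return pd.DataFrame(cols, index=pd.Index(norm.gene_symbols, name="gene"))


# ---------------------------------------------------------------------------
# Consensus annotation
# ---------------------------------------------------------------------------

def _method_marker_rank(cluster_markers: pd.DataFrame, ref: MarkerReference):
    """Evidence score per type: sum of -log10(fdr) over shared markers."""
    scores = {}
    marker_fdr = dict(zip(cluster_markers["gene"].str.upper(), cluster_markers["fdr"]))
    for ctype, ref_genes in ref.entries.items():
        shared = set(marker_fdr) & ref_genes
        scores[ctype] = float(sum(-np.log10(max(marker_fdr[g], 1e-300)) for g in shared))
    best = max(scores, key=lambda t: (scores[t], t))
    if scores[best] <= 0:
        return UNASSIGNED, scores
    return best, scores


def _method_overlap_test(cluster_markers: pd.DataFrame, ref: MarkerReference, universe: set):
    """Hypergeometric overlap of the cluster's marker set with each type."""
    from scipy.stats import hypergeom

    query = set(cluster_markers["gene"].str.upper()) & universe
    pvals = {}
    for ctype, ref_genes in ref.entries.items():
        K = len(ref_genes & universe)
        k = len(ref_genes & query)
        N, n_draw = len(universe), len(query)
        if K == 0 or n_draw == 0:
            pvals[ctype] = 1.0
        else:
            pvals[ctype] = float(hypergeom.sf(k - 1, N, K, n_draw))
    best = min(pvals, key=lambda t: (pvals[t], t))
    if pvals[best] >= 0.05:
        return UNASSIGNED, pvals
    return best, pvals


def _method_profile_corr(cluster_profile: pd.Series, ref_profiles: pd.DataFrame):
    """Spearman correlation of the cluster profile vs each type profile."""
    shared = cluster_profile.index.intersection(ref_profiles.index)
    rhos = {}
    for ctype in ref_profiles.columns:
        if len(shared) < 3:
            rhos[ctype] = np.nan
            continue
        rho = scipy.stats.spearmanr(
            cluster_profile.loc[shared], ref_profiles.loc[shared, ctype]
        ).statistic
        rhos[ctype] = float(rho) if np.isfinite(rho) else np.nan
    finite = {t: r for t, r in rhos.items() if np.isfinite(r)}
    if not finite:
        return UNASSIGNED, rhos
    best = max(finite, key=lambda t: (finite[t], t))
    if finite[best] <= 0:
        return UNASSIGNED, rhos
    return best, rhos


def annotate_consensus(
    markers: pd.DataFrame,
    mean_profiles: pd.DataFrame,
    ref: MarkerReference,
    ref_profiles: pd.DataFrame | None = None,
    params: PipelineParams | None = None,
) -> AnnotationResult:
    """Three-method cluster annotation with a >= 2-vote consensus.

    Methods: (1) marker-evidence ranking, (2) hypergeometric overlap of
    cluster markers with the reference sets (universe = all tested
    genes), (3) Spearman correlation against reference mean profiles
    (skipped when ``ref_profiles`` is None, in which case methods 1 and
    2 must agree). A method abstains when it has no positive evidence;
    a cluster without two agreeing votes is labelled ``ambiguous``.
    """
    params = params or PipelineParams()
    universe = set(markers["gene"].str.upper())
    if not universe & ref.all_genes():
        raise ValidationError("no overlap between data genes and reference genes")
    mean_profiles = mean_profiles.copy()
    mean_profiles.index = mean_profiles.index.str.upper()
    if ref_profiles is not None:
        ref_profiles = ref_profiles.copy()
        ref_profiles.index = ref_profiles.index.str.upper()

    rows = []
    for lab in sorted(markers["cluster"].unique()):
        sub = markers[(markers["cluster"] == lab) & markers["is_marker"]]
        lab1, scores1 = _method_marker_rank(sub, ref)
        lab2, scores2 = _method_overlap_test(sub, ref, universe)
        if ref_profiles is not None:
            lab3, scores3 = _method_profile_corr(mean_profiles[lab], ref_profiles)
        else:
            lab3, scores3 = None, {}
        votes_cast = [l for l in (lab1, lab2, lab3) if l not in (None, UNASSIGNED)]
        counts = pd.Series(votes_cast).value_counts() if votes_cast else pd.Series(dtype=int)
        if not counts.empty and counts.iloc[0] >= 2:
            consensus = counts.index[0]
            votes = int(counts.iloc[0])
        else:
            consensus = AMBIGUOUS
            votes = int(counts.iloc[0]) if not counts.empty else 0
        rows.append(
            {
                "cluster": lab,
                "label_marker_rank": lab1,
                "label_overlap_test": lab2,
                "label_profile_corr": lab3 if lab3 is not None else "skipped",
                "consensus": consensus,
                "votes": votes,
                "score_marker_rank": scores1,
                "score_overlap_test": scores2,
                "score_profile_corr": scores3,
            }
        )
    return AnnotationResult(table=pd.DataFrame(rows).set_index("cluster"))
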