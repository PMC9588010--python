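"""Statistical layer: rank-sum tests, BH, exercise DE, composition, ORA.

All group comparisons use the unpaired two-sample Wilcoxon rank-sum
(Mann-Whitney) test: exact enumeration when the pooled sample is small
and tie-free, otherwise the tie-corrected normal approximation with
continuity correction. Cells are treated as replicates within a cell
type, mirroring the original analysis; composition shifts are tested
one-sided on per-sample proportions, where exact enumeration at n=3 vs
3 with complete separation gives p = 1/20 = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io_formats import GeneSetCollection
from .params import PipelineParams
from .preprocess import ExpressionMatrix

__all__ = [
    "TestResult",
    "rank_sum_test",
    "bh_adjust",
    "exercise_de",
    "composition_table",
    "composition_shift_test",
    "hypergeom_ora",
    "bulk_sc_overlap",
]

_SIDES = {"two": "two-sided", "greater": "greater", "less": "less"}


@dataclass
class TestResult:
    """Outcome of a two-sample rank-sum test.

    ``sidedness`` states the alternative for the first sample relative
    to the second (scipy convention): ``greater`` tests x > y.
    """

    statistic: float
    p: float
    method: str  # "exact" | "normal_approx"
    sidedness: str


def rank_sum_test(x, y, sidedness: str = "two") -> TestResult:
    """Unpaired two-sample Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null enumeration is used when ``len(x) + len(y) <= 20`` and
    there are no ties across the pooled sample; otherwise mid-ranks with
    the tie-corrected normal approximation and continuity correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both groups must be nonempty")
    if sidedness not in _SIDES:
        raise ValidationError(f"sidedness must be one of {sorted(_SIDES)}, got {sidedness!r}")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = (len(x) + len(y) <= 20) and not has_ties
    res = scipy.stats.mannwhitneyu(
        x,
        y,
        alternative=_SIDES[sidedness],
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    p = float(np.clip(res.pvalue, np.finfo(float).tiny, 1.0))
    return TestResult(
        statistic=float(res.statistic),
        p=p,
        method="exact" if exact else "normal_approx",
        sidedness=sidedness,
    )


def ranksum_p_vs_rest(dense: np.ndarray, members: np.ndarray,
                      ranks: np.ndarray | None = None,
                      tie_term: np.ndarray | None = None) -> np.ndarray:
    """Two-sided tie-corrected rank-sum p for each row, group vs rest.

    Uses the shared-ranking identity: mid-ranks over all columns are
    computed once, the group's U statistic follows from its rank sum,
    and the normal approximation uses the tie-corrected variance with
    continuity correction — equivalent to the per-row asymptotic
    Mann-Whitney test but linear instead of quadratic in group count.
    """
    n = dense.shape[1]
    if ranks is None:
        ranks = scipy.stats.rankdata(dense, axis=1)
    if tie_term is None:
        tie_term = _tie_term(dense)
    n1 = int(members.sum())
    n2 = n - n1
    r1 = ranks[:, members].sum(axis=1)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    var = np.maximum(var, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (np.abs(u1 - mu) - 0.5) / np.sqrt(var)
    z = np.where(var > 0, np.maximum(z, 0.0), 0.0)
    p = 2.0 * scipy.stats.norm.sf(z)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def _tie_term(dense: np.ndarray) -> np.ndarray:
    """Per-row sum of t^3 - t over tied groups (for rank-sum variance)."""
    out = np.empty(dense.shape[0])
    for i in range(dense.shape[0]):
        _, counts = np.unique(dense[i], return_counts=True)
        out[i] = float((counts.astype(float) ** 3 - counts).sum())
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Exercise differential expression
# ---------------------------------------------------------------------------

def exercise_de(
    norm: ExpressionMatrix,
    cell_types,
    params: PipelineParams,
    aggregate_by_subject: bool = False,
    global_adjust: bool = False,
) -> pd.DataFrame:
    """Pre- vs post-exercise DE within each cell type.

    Only genes detected in strictly more than ``de_min_pct`` of the
    type's cells at *both* timepoints are tested (two-sided rank-sum,
    cells as replicates), with BH adjustment within the cell type
    (``global_adjust=True`` adjusts across all types instead).
    ``aggregate_by_subject=True`` averages cells per (subject,
    timepoint) first and tests subjects as replicates, avoiding
    pseudoreplication at the cost of power. Types with fewer than 3
    replicates at either timepoint are skipped.
    """
    cell_types = np.asarray(cell_types)
    tp = norm.cell_meta["timepoint"].to_numpy()
    dense = np.asarray(norm.values.todense())
    if aggregate_by_subject:
        subj = norm.cell_meta["subject_id"].to_numpy()
        rows = []
        for ctype in pd.unique(cell_types):
            sel = cell_types == ctype
            cols, tps = [], []
            for s in pd.unique(subj):
                for t in ("pre", "post"):
                    members = sel & (subj == s) & (tp == t)
                    if members.any():
                        cols.append(dense[:, members].mean(axis=1))
                        tps.append(t)
            if not cols:
                continue
            rows.append((ctype, np.column_stack(cols), np.array(tps)))
        return _exercise_de_blocks(rows, np.asarray(norm.gene_symbols), params,
                                   global_adjust)
    blocks = [
        (ctype, dense[:, cell_types == ctype], tp[cell_types == ctype])
        for ctype in pd.unique(cell_types)
    ]
    return _exercise_de_blocks(blocks, np.asarray(norm.gene_symbols), params,
                               global_adjust)


_DE_COLUMNS = ["cell_type", "gene", "log2fc_post_vs_pre",
               "pct_pre", "pct_post", "p", "fdr"]


def _exercise_de_blocks(blocks, genes, params, global_adjust):
    """Shared DE core: blocks of (cell_type, genes x replicates, tp)."""
    rows = []
    for ctype, sub, tps in blocks:
        pre = tps == "pre"
        post = tps == "post"
        if pre.sum() < 3 or post.sum() < 3:
            warnings.warn(
                f"cell type {ctype!r} has <3 replicates at a timepoint; skipped"
            )
            continue
        pct_pre = (sub[:, pre] > 0).mean(axis=1)
        pct_post = (sub[:, post] > 0).mean(axis=1)
        tested = (pct_pre > params.de_min_pct) & (pct_post > params.de_min_pct)
        if not tested.any():
            continue
        p = ranksum_p_vs_rest(sub[tested], post)
        expm1 = np.expm1(sub[tested])
        mean_pre = expm1[:, pre].mean(axis=1)
        mean_post = expm1[:, post].mean(axis=1)
        log2fc = np.log2((mean_post + 1e-9) / (mean_pre + 1e-9))
        rows.append(
            pd.DataFrame(
                {
                    "cell_type": ctype,
                    "gene": genes[tested],
                    "log2fc_post_vs_pre": log2fc,
                    "pct_pre": pct_pre[tested],
                    "pct_post": pct_post[tested],
                    "p": p,
                    "fdr": np.nan,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=_DE_COLUMNS)
    out = pd.concat(rows, ignore_index=True)
    if global_adjust:
        out["fdr"] = bh_adjust(out["p"].to_numpy())
    else:
        out["fdr"] = out.groupby("cell_type")["p"].transform(
            lambda s: bh_adjust(s.to_numpy())
        )
    return out


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def composition_table(cell_types, cell_meta: pd.DataFrame) -> pd.DataFrame:
    """Per-sample cell-type counts and proportions.

    Every (sample, cell type) combination is present, with zero counts
    where a type was not observed, so per-type sample vectors have equal
    length across timepoints.
    """
    df = pd.DataFrame(
        {
            "sample_id": cell_meta["sample_id"].to_numpy(),
            "timepoint": cell_meta["timepoint"].to_numpy(),
            "cell_type": np.asarray(cell_types),
        }
    )
    all_types = sorted(df["cell_type"].unique())
    rows = []
    for (sample, tp), sub in df.groupby(["sample_id", "timepoint"], sort=True):
        counts = sub["cell_type"].value_counts()
        total = len(sub)
        for ctype in all_types:
            n = int(counts.get(ctype, 0))
            rows.append((sample, tp, ctype, n, n / total))
    return pd.DataFrame(
        rows, columns=["sample_id", "timepoint", "cell_type", "n_cells", "proportion"]
    )


def composition_shift_test(comp: pd.DataFrame, direction: str = "increase") -> pd.DataFrame:
    """One-sided rank-sum on per-sample proportions, post vs pre.

    ``direction='increase'`` tests whether post-exercise proportions
    exceed pre-exercise ones. Exact enumeration applies automatically at
    typical sample sizes. Requires >= 2 samples per timepoint.
    """
    if direction not in ("increase", "decrease"):
        raise ValidationError("direction must be 'increase' or 'decrease'")
    rows = []
    for ctype, sub in comp.groupby("cell_type", sort=True):
        pre = sub.loc[sub["timepoint"] == "pre", "proportion"].to_numpy()
        post = sub.loc[sub["timepoint"] == "post", "proportion"].to_numpy()
        if len(pre) < 2 or len(post) < 2:
            raise ValidationError(
                f"cell type {ctype!r}: need >= 2 samples per timepoint "
                f"(got {len(pre)} pre, {len(post)} post)"
            )
        res = rank_sum_test(post, pre, "greater" if direction == "increase" else "less")
        rows.append((ctype, res.statistic, res.p, res.method))
    return pd.DataFrame(rows, columns=["cell_type", "statistic", "p", "method"]).set_index(
        "cell_type"
    )


# ---------------------------------------------------------------------------
# Over-representation analysis
# ---------------------------------------------------------------------------

def hypergeom_ora(query, sets: GeneSetCollection, background) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation against a background.

    For each set: ``K = |set & background|``, ``k = |set & query|``,
    ``p = P(X >= k | N=|background|, K, n=|query|)``; BH across sets.
    The query must be a subset of the background.
    """
    background = {str(g).upper() for g in background}
    query = {str(g).upper() for g in query}
    if not background:
        raise ValidationError("empty background")
    if not query <= background:
        raise ValidationError("query genes must be a subset of the background")
    N, n_draw = len(background), len(query)
    rows = []
    for name in sets.sets:
        genes = sets.genes(name)
        K = len(genes & background)
        k = len(genes & query)
        p = float(scipy.stats.hypergeom.sf(k - 1, N, K, n_draw)) if K else 1.0
        rows.append((name, k, K, N, n_draw, p))
    df = pd.DataFrame(
        rows, columns=["set_name", "overlap_k", "set_size_K", "background_N", "drawn_n", "p"]
    )
    df["fdr"] = bh_adjust(df["p"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# Bulk vs single-cell detection overlap
# ---------------------------------------------------------------------------

def bulk_sc_overlap(
    bulk: pd.Series,
    norm: ExpressionMatrix,
    cell_types,
    params: PipelineParams,
) -> tuple:
    """Partition genes into bulk-only / shared / single-cell-only.

    Bulk detection requires logCPM strictly above
    ``params.bulk_detect_logcpm``; single-cell detection requires some
    cell type where the gene is expressed in at least 50% of cells with
    a positive mean normalized value.
    """
    bulk_genes = {str(g).upper() for g in bulk.index}
    sc_genes = {g.upper() for g in norm.gene_symbols}
    if not bulk_genes & sc_genes:
        raise ValidationError("bulk and single-cell gene universes are disjoint")
    bulk_idx = pd.Index([str(g).upper() for g in bulk.index])
    bulk_detected = set(bulk_idx[np.asarray(bulk, float) > params.bulk_detect_logcpm])

    cell_types = np.asarray(cell_types)
    dense = np.asarray(norm.values.todense())
    detected = np.zeros(norm.n_genes, bool)
    for ctype in pd.unique(cell_types):
        members = cell_types == ctype
        if not members.any():
            continue
        sub = dense[:, members]
        pct = (sub > 0).mean(axis=1)
        mean = sub.mean(axis=1)
        detected |= (pct >= 0.5) & (mean > 0)
    sc_detected = {norm.gene_symbols[i].upper() for i in np.flatnonzero(detected)}

    shared = bulk_detected & sc_detected
    bulk_only = bulk_detected - sc_detected
    sc_only = sc_detected - bulk_detected
    return bulk_only, shared, sc_only
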