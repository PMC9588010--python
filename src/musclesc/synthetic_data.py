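"""Synthetic multi-subject pre/post-exercise muscle atlas with ground truth.

The generator emulates the statistical structure of a skeletal-muscle
single-cell experiment sampled before and three hours after a single
bout of exercise:

* six cell types with distinct marker programs (endothelial,
  mesenchymal, myogenic, pericyte, lymphocyte, monocyte), with an
  immune-fraction increase post-exercise and a compensatory decrease of
  resident types;
* negative-binomial counts with a shared dispersion, per-cell lognormal
  library-size factors, and per-cell Beta-distributed mitochondrial
  content (with a small outlier fraction above the QC cutoff);
* a myogenic compartment lying on a latent differentiation continuum
  ``tau`` in [0, 1]; designated trend genes have mean multipliers
  ``exp(beta * tau)`` so log-scale trends are linear in tau; a known
  shift ``delta`` is added to tau post-exercise (clipped to [0, 1]);
* 7.5%-rate doublets formed by summing two parent cells and rescaling
  to a single-cell library size.

Every generated quantity is recorded in :class:`GroundTruth`, so each
downstream stage can be tested as a parameter-recovery problem.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import EmptyResultError, ValidationError
from .io_formats import CountMatrix, MarkerReference

__all__ = [
    "SimDesign",
    "GroundTruth",
    "default_design",
    "simulate_atlas",
    "inject_doublets",
    "simulate_bulk_profile",
    "marker_reference_from_design",
    "expected_type_profiles",
]

MITO_GENES = (
    "MT-CO1", "MT-CO2", "MT-CO3", "MT-ND1", "MT-ND2",
    "MT-ND3", "MT-ND4", "MT-ATP6", "MT-ATP8", "MT-CYB",
)

# Baseline and post-exercise compositions: circulating immune cells
# roughly double three hours after exercise while resident endothelial
# and pericyte fractions fall; the myogenic fraction is unchanged.
DEFAULT_CELL_TYPES = (
    ("Endothelial", 0.44, 0.37),
    ("Mesenchymal", 0.26, 0.27),
    ("Myogenic", 0.18, 0.18),
    ("Pericyte", 0.06, 0.05),
    ("Lymphocyte", 0.04, 0.09),
    ("Monocyte", 0.02, 0.04),
)

DEFAULT_MARKERS: dict = {
    "Endothelial": [
        ("VWF", 8.0), ("PECAM1", 8.0), ("ESAM", 6.0), ("CDH5", 8.0),
        ("CLDN5", 6.0), ("EGFL7", 8.0), ("FLT1", 6.0), ("CD34", 4.0),
    ],
    "Mesenchymal": [
        ("PDGFRA", 8.0), ("COL1A1", 8.0), ("COL1A2", 8.0), ("DCN", 8.0),
        ("GSN", 6.0), ("LUM", 6.0), ("FBLN1", 6.0), ("MGP", 4.0),
    ],
    "Myogenic": [
        ("DES", 8.0), ("CKM", 8.0), ("ACTC1", 6.0), ("MYBPH", 6.0),
        ("SGCA", 6.0), ("CHRNA1", 6.0), ("CAV3", 4.0), ("MYOZ1", 4.0),
        # continuum genes: myogenic-restricted, modulated by exp(beta*tau)
        ("PAX7", 6.0), ("MYF5", 6.0), ("NCAM1", 4.0), ("APOE", 4.0),
        ("MYOD1", 4.0), ("MYF6", 4.0),
        ("TNNI1", 2.0), ("TNNC1", 2.0), ("MYL2", 2.0),
        ("TNNI2", 2.0), ("TNNC2", 2.0), ("ENO3", 2.0), ("TNNT1", 2.0),
    ],
    "Pericyte": [
        ("RGS5", 8.0), ("PDGFRB", 8.0), ("NOTCH3", 6.0), ("ACTA2", 8.0),
        ("MYH11", 6.0), ("KCNJ8", 6.0), ("HIGD1B", 4.0), ("CSPG4", 4.0),
    ],
    "Lymphocyte": [
        ("CD3E", 8.0), ("CD3D", 8.0), ("IL7R", 6.0), ("CCL5", 8.0),
        ("NKG7", 6.0), ("CD2", 6.0), ("GZMA", 6.0), ("TRAC", 4.0),
    ],
    "Monocyte": [
        ("CD14", 8.0), ("LYZ", 8.0), ("TYROBP", 8.0), ("CXCL8", 6.0),
        ("S100A8", 6.0), ("S100A9", 6.0), ("FCN1", 6.0), ("AIF1", 4.0),
    ],
}

# Beyond canonical markers, each type carries a broader expression
# program (modest fold changes over many genes), as real cell types do;
# synthetic program genes are named <TYPE-PREFIX>.Pnn.
for _t in list(DEFAULT_MARKERS):
    _prefix = _t[:3].upper()
    DEFAULT_MARKERS[_t] = list(DEFAULT_MARKERS[_t]) + [
        (f"{_prefix}.P{_i:02d}", 3.0) for _i in range(30)
    ]

# Differentiation-trend slopes on the log scale: satellite/progenitor
# markers (PAX7, MYF5, ...) fall with tau, maturation markers
# (troponins, ENO3, MYL2) rise.
DEFAULT_TREND_GENES: dict = {
    "PAX7": -2.5, "MYF5": -2.0, "NCAM1": -1.5, "APOE": -1.5,
    "MYOD1": -1.0, "MYF6": -1.0,
    "TNNI1": 2.0, "TNNC1": 2.0, "MYL2": 1.5,
    "TNNI2": 2.0, "TNNC2": 2.0, "ENO3": 1.5, "TNNT1": 1.5,
}
# Differentiation is a broad transcriptional program, not a handful of
# genes: add synthetic trend genes (MYO.Tnn) with strong slopes in both
# directions so the continuum dominates within-myogenic variance, as it
# does in tissue where progenitor and mature myogenic cells form
# distinct clusters.
DEFAULT_TREND_GENES.update(
    {f"MYO.T{_i:02d}": (2.0 if _i % 2 == 0 else -2.0) for _i in range(100)}
)
# Trend genes are part of the myogenic program and highly expressed, as
# contractile-apparatus transcripts are in maturing myogenic cells.
DEFAULT_MARKERS["Myogenic"] = list(DEFAULT_MARKERS["Myogenic"]) + [
    (f"MYO.T{_i:02d}", 10.0) for _i in range(100)
]


@dataclass
class SimDesign:
    """Full specification of a synthetic atlas.

    ``cell_types`` rows are ``(name, proportion_pre, proportion_post)``;
    each proportion vector must sum to 1. ``marker_table`` maps cell
    type to ``(gene_symbol, fold_change >= 1)`` pairs; a marker may not
    belong to two types. ``continuum`` settings define the latent
    myogenic differentiation time ``tau ~ Beta(tau_alpha, tau_beta)``
    pre-exercise, with ``shift_delta`` added post-exercise (clipped).
    """

    n_subjects: int = 4
    cells_per_sample: int = 1000
    cell_types: Sequence = DEFAULT_CELL_TYPES
    marker_table: Mapping = field(default_factory=lambda: dict(DEFAULT_MARKERS))
    n_background_genes: int = 3000
    nb_dispersion: float = 10.0
    libsize_meanlog: float = 0.0
    libsize_sdlog: float = 0.2
    mito_beta_a: float = 3.0
    mito_beta_b: float = 57.0
    pct_mito_outliers: float = 0.02
    doublet_rate: float = 0.075
    tau_alpha: float = 1.0
    tau_beta: float = 1.0
    shift_delta: float = 0.08
    trend_genes: Mapping = field(default_factory=lambda: dict(DEFAULT_TREND_GENES))
    myogenic_type: str = "Myogenic"
    marker_base_mean: float = 0.5
    background_meanlog: float = float(np.log(0.3))
    background_sdlog: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        pre = sum(p for _, p, _ in self.cell_types)
        post = sum(q for _, _, q in self.cell_types)
        if abs(pre - 1.0) > 1e-9 or abs(post - 1.0) > 1e-9:
            raise ValidationError(
                f"cell-type proportions must sum to 1 (got pre={pre}, post={post})"
            )
        seen: dict = {}
        for ctype, markers in self.marker_table.items():
            for gene, fold in markers:
                if fold < 1:
                    raise ValidationError(f"marker fold changes must be >= 1 ({gene}: {fold})")
                if gene in seen and seen[gene] != ctype:
                    raise ValidationError(
                        f"marker {gene!r} assigned to both {seen[gene]!r} and {ctype!r}"
                    )
                seen[gene] = ctype
        if not (0.0 <= self.shift_delta <= 1.0):
            raise ValidationError(f"shift_delta must be in [0, 1], got {self.shift_delta}")
        if not (0.0 <= self.doublet_rate < 0.5):
            raise ValidationError(f"doublet_rate must be in [0, 0.5), got {self.doublet_rate}")
        names = [n for n, _, _ in self.cell_types]
        if len(set(names)) != len(names):
            raise ValidationError("cell type names must be unique")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cell_types"] = [list(row) for row in self.cell_types]
        d["marker_table"] = {k: [list(x) for x in v] for k, v in self.marker_table.items()}
        return d


@dataclass
class GroundTruth:
    """Per-cell truth (type, doublet flag, tau) plus run-level truth."""

    cells: pd.DataFrame  # index barcode: true_type, is_doublet, tau, sample_id, ...
    shift_delta: float
    composition_pre: pd.Series
    composition_post: pd.Series

    def subset(self, barcodes: Sequence) -> "GroundTruth":
        return GroundTruth(
            cells=self.cells.loc[list(barcodes)].copy(),
            shift_delta=self.shift_delta,
            composition_pre=self.composition_pre,
            composition_post=self.composition_post,
        )


def default_design(**overrides) -> SimDesign:
    """The default study-condition design (override fields by keyword)."""
    return SimDesign(**overrides)


def _gene_universe(design: SimDesign) -> tuple:
    """Deterministic gene ordering: structured genes, background, mito."""
    structured: list = []
    for ctype in design.marker_table:
        for gene, _ in design.marker_table[ctype]:
            if gene not in structured:
                structured.append(gene)
    for gene in design.trend_genes:
        if gene not in structured:
            structured.append(gene)
    background = [f"BG{i:05d}" for i in range(design.n_background_genes)]
    genes = structured + background + list(MITO_GENES)
    return genes, structured, background


def _base_means(design: SimDesign, genes: list, structured: list, rng) -> np.ndarray:
    base = np.empty(len(genes))
    n_struct = len(structured)
    n_bg = design.n_background_genes
    base[:n_struct] = design.marker_base_mean
    base[n_struct:n_struct + n_bg] = rng.lognormal(
        design.background_meanlog, design.background_sdlog, size=n_bg
    )
    base[n_struct + n_bg:] = 1.0  # mito genes rescaled per cell below
    return base


def simulate_atlas(design: SimDesign) -> tuple:
    """Draw a full atlas (without doublets) and its ground truth.

    Counts are negative binomial with mean
    ``base_mean * marker_fold * exp(beta * tau) * libsize_factor``,
    with mitochondrial genes rescaled per cell so the expected
    mitochondrial fraction follows the designed Beta distribution.
    Deterministic given ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    genes, structured, background = _gene_universe(design)
    gene_index = {g: i for i, g in enumerate(genes)}
    base = _base_means(design, genes, structured, rng)
    n_mito = len(MITO_GENES)
    mito_slice = slice(len(genes) - n_mito, len(genes))
    nonmito_slice = slice(0, len(genes) - n_mito)

    # per-(type, gene) fold-change matrix
    type_names = [n for n, _, _ in design.cell_types]
    folds = {t: np.ones(len(genes)) for t in type_names}
    for ctype, markers in design.marker_table.items():
        for gene, fold in markers:
            folds[ctype][gene_index[gene]] = fold
    trend_idx = np.array([gene_index[g] for g in design.trend_genes], dtype=int)
    trend_beta = np.array(list(design.trend_genes.values()))

    r = design.nb_dispersion
    blocks: list = []
    meta_rows: list = []
    truth_rows: list = []
    barcodes: list = []

    for subj in range(design.n_subjects):
        for tp, props in (
            ("pre", [p for _, p, _ in design.cell_types]),
            ("post", [q for _, _, q in design.cell_types]),
        ):
            sample_id = f"S{subj + 1}{tp}"
            n_cells = design.cells_per_sample
            if n_cells == 0:
                continue
            type_counts = rng.multinomial(n_cells, props)
            cell_types_vec = np.repeat(np.arange(len(type_names)), type_counts)
            libsize = rng.lognormal(design.libsize_meanlog, design.libsize_sdlog, n_cells)
            mito_frac = rng.beta(design.mito_beta_a, design.mito_beta_b, n_cells)
            outlier = rng.random(n_cells) < design.pct_mito_outliers
            mito_frac[outlier] = rng.uniform(0.20, 0.50, int(outlier.sum()))

            fold_matrix = np.column_stack([folds[t] for t in type_names])
            mu = base[:, None] * fold_matrix[:, cell_types_vec]
            tau = np.full(n_cells, np.nan)
            myo = np.flatnonzero(
                cell_types_vec == type_names.index(design.myogenic_type)
            ) if design.myogenic_type in type_names else np.array([], int)
            if len(myo):
                tau_m = rng.beta(design.tau_alpha, design.tau_beta, len(myo))
                if tp == "post":
                    tau_m = np.minimum(tau_m + design.shift_delta, 1.0)
                tau[myo] = tau_m
                mu[np.ix_(trend_idx, myo)] *= np.exp(np.outer(trend_beta, tau_m))
            # expression programs are compositional: every cell's mean
            # vector is normalized to a common expected depth so that
            # sequencing depth is driven only by the lognormal factor
            t0 = base[nonmito_slice].sum()
            mu *= (t0 / mu[nonmito_slice].sum(axis=0))[None, :]
            mu *= libsize[None, :]
            nonmito_total = mu[nonmito_slice].sum(axis=0)
            mu[mito_slice] = (
                mito_frac / (1.0 - mito_frac) * nonmito_total / n_mito
            )[None, :]
            counts = rng.negative_binomial(r, r / (r + mu))
            blocks.append(sp.csr_matrix(counts))

            for ci in range(n_cells):
                bc = f"{sample_id}-{ci:05d}"
                barcodes.append(bc)
                meta_rows.append((bc, sample_id, f"subj{subj + 1}", tp))
                truth_rows.append(
                    (bc, type_names[cell_types_vec[ci]], False, tau[ci], sample_id, tp)
                )

    comp_pre = pd.Series({n: p for n, p, _ in design.cell_types}, name="proportion")
    comp_post = pd.Series({n: q for n, _, q in design.cell_types}, name="proportion")

    if not blocks:
        values = sp.csr_matrix((len(genes), 0), dtype=np.int64)
    else:
        values = sp.hstack(blocks).tocsr().astype(np.int64)
    meta = pd.DataFrame(
        meta_rows, columns=["barcode", "sample_id", "subject_id", "timepoint"]
    ).set_index("barcode")
    truth = pd.DataFrame(
        truth_rows,
        columns=["barcode", "true_type", "is_doublet", "tau", "sample_id", "timepoint"],
    ).set_index("barcode")

    m = CountMatrix(
        values=values,
        gene_ids=[f"SIM{i:05d}" for i in range(len(genes))],
        gene_symbols=genes,
        barcodes=barcodes,
        cell_meta=meta,
    )
    gt = GroundTruth(
        cells=truth,
        shift_delta=design.shift_delta,
        composition_pre=comp_pre,
        composition_post=comp_post,
    )
    return m, gt


def inject_doublets(
    m: CountMatrix, t: GroundTruth, rate: float, seed: int
) -> tuple:
    """Append ``floor(rate * n)`` synthetic doublets to the matrix.

    Each doublet is the entrywise sum of two distinct cells drawn from
    the same sample, rescaled to a single-cell library size drawn from
    the empirical library-size distribution, and flagged in the truth
    table with both parent types.
    """
    if not (0.0 <= rate < 0.5):
        raise ValidationError(f"doublet rate must be in [0, 0.5), got {rate}")
    n = m.n_cells
    if n < 2 and rate > 0:
        raise ValidationError("need at least 2 cells to form doublets")
    n_doub = int(np.floor(rate * n))
    if n_doub == 0:
        return m, t
    rng = np.random.default_rng(seed)
    totals = np.asarray(m.values.sum(axis=0)).ravel().astype(float)
    sample_ids = m.cell_meta["sample_id"].to_numpy()
    samples, sample_counts = np.unique(sample_ids, return_counts=True)
    eligible = samples[sample_counts >= 2]
    if len(eligible) == 0:
        raise ValidationError("no sample has >= 2 cells; cannot form doublets")
    weights = sample_counts[sample_counts >= 2].astype(float)
    weights /= weights.sum()

    cols: list = []
    bcs: list = []
    meta_rows: list = []
    truth_rows: list = []
    csc = m.values.tocsc()
    by_sample = {s: np.flatnonzero(sample_ids == s) for s in eligible}
    for d in range(n_doub):
        s = rng.choice(eligible, p=weights)
        i, j = rng.choice(by_sample[s], size=2, replace=False)
        summed = np.asarray((csc[:, i] + csc[:, j]).todense()).ravel().astype(np.int64)
        target = totals[rng.integers(0, n)]
        scale = target / summed.sum()
        if scale <= 1.0:
            # binomial thinning: the library is a random subsample of the
            # pooled transcripts, not a deterministic rounding
            scaled = rng.binomial(summed, scale)
        else:
            scaled = summed + rng.poisson(summed * (scale - 1.0))
        cols.append(sp.csr_matrix(scaled[:, None]))
        bc = f"DBL-{d:05d}"
        bcs.append(bc)
        row = m.cell_meta.iloc[i]
        meta_rows.append((bc, row["sample_id"], row["subject_id"], row["timepoint"]))
        ti, tj = t.cells["true_type"].iloc[i], t.cells["true_type"].iloc[j]
        truth_rows.append((bc, f"{ti}+{tj}", True, np.nan, row["sample_id"], row["timepoint"]))

    new_vals = sp.hstack([m.values] + cols).tocsr()
    new_meta = pd.concat(
        [
            m.cell_meta,
            pd.DataFrame(
                meta_rows, columns=["barcode", "sample_id", "subject_id", "timepoint"]
            ).set_index("barcode"),
        ]
    )
    new_truth = pd.concat(
        [
            t.cells,
            pd.DataFrame(
                truth_rows,
                columns=["barcode", "true_type", "is_doublet", "tau", "sample_id", "timepoint"],
            ).set_index("barcode"),
        ]
    )
    m2 = CountMatrix(
        values=new_vals,
        gene_ids=list(m.gene_ids),
        gene_symbols=list(m.gene_symbols),
        barcodes=list(m.barcodes) + bcs,
        cell_meta=new_meta,
    )
    t2 = GroundTruth(
        cells=new_truth,
        shift_delta=t.shift_delta,
        composition_pre=t.composition_pre,
        composition_post=t.composition_post,
    )
    return m2, t2


def simulate_bulk_profile(m: CountMatrix, noise_sdlog: float, seed: int) -> pd.Series:
    """Pseudobulk the matrix to a gene -> logCPM table (log2(CPM + 1)).

    Per-gene count sums are converted to counts per million with
    optional multiplicative lognormal noise on the CPM scale.
    Zero-count genes map to exactly 0 at zero noise.
    """
    sums = np.asarray(m.values.sum(axis=1)).ravel().astype(float)
    total = sums.sum()
    if total == 0:
        raise EmptyResultError("all-zero matrix: cannot form a bulk profile")
    cpm = sums / total * 1e6
    if noise_sdlog > 0:
        rng = np.random.default_rng(seed)
        cpm = cpm * rng.lognormal(0.0, noise_sdlog, size=len(cpm))
    logcpm = np.log2(1.0 + cpm)
    return pd.Series(logcpm, index=pd.Index(m.gene_symbols, name="gene"), name="logCPM")


def marker_reference_from_design(design: SimDesign) -> MarkerReference:
    """The design's own marker table as an annotation reference."""
    return MarkerReference(
        entries={t: {g for g, _ in markers} for t, markers in design.marker_table.items()}
    )


def expected_type_profiles(design: SimDesign, n_grid: int = 201) -> pd.DataFrame:
    """Expected mean expression per (gene, cell type) under the design.

    For the myogenic type, trend-gene means are averaged over the
    pre-exercise Beta distribution of tau (numerical quadrature on a
    grid). Returned on the raw mean-count scale (genes x types); only
    the ranks matter for Spearman-based profile annotation.
    """
    from scipy.stats import beta as beta_dist

    rng = np.random.default_rng(design.seed)
    genes, structured, background = _gene_universe(design)
    gene_index = {g: i for i, g in enumerate(genes)}
    base = _base_means(design, genes, structured, rng)
    grid = np.linspace(0.0, 1.0, n_grid)
    w = beta_dist.pdf(grid, design.tau_alpha, design.tau_beta)
    w = w / w.sum()

    profiles = {}
    for ctype, _, _ in design.cell_types:
        mu = base.copy()
        for gene, fold in design.marker_table.get(ctype, ()):
            mu[gene_index[gene]] *= fold
        if ctype == design.myogenic_type:
            for gene, b in design.trend_genes.items():
                mu[gene_index[gene]] *= float(np.sum(w * np.exp(b * grid)))
        profiles[ctype] = mu
    return pd.DataFrame(profiles, index=pd.Index(genes, name="gene"))
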