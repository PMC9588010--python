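"""Standard formats: 10x-style MTX triplets, marker references, GMT.

The central container is :class:`CountMatrix`: a sparse non-negative
integer genes x cells matrix with gene identifiers/symbols, unique cell
barcodes, and per-cell sample/subject/timepoint metadata. Orientation is
fixed as genes on rows and cells on columns everywhere in the package.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError, IntegrityError, ValidationError

__all__ = [
    "CountMatrix",
    "MarkerReference",
    "GeneSetCollection",
    "read_10x_mtx",
    "write_10x_mtx",
    "read_marker_reference",
    "read_gmt",
    "concat_cells",
]

logger = logging.getLogger(__name__)

TIMEPOINTS = ("pre", "post")

META_COLUMNS = ("sample_id", "subject_id", "timepoint")


@dataclass
class CountMatrix:
    """Sparse genes x cells integer count matrix with cell metadata.

    Attributes
    ----------
    values : scipy.sparse.csr_matrix
        Non-negative integer counts, genes on rows, cells on columns.
    gene_ids, gene_symbols : list of str
        Per-row identifiers; ``gene_ids`` are unique and kept for
        provenance, all biology-facing logic operates on symbols.
    barcodes : list of str
        Unique per-column cell barcodes.
    cell_meta : pandas.DataFrame
        Indexed by barcode, columns ``sample_id``, ``subject_id``,
        ``timepoint`` (levels ``pre``/``post``).
    """

    values: sp.csr_matrix
    gene_ids: list
    gene_symbols: list
    barcodes: list
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.validate()

    # -- invariants -------------------------------------------------
    def validate(self) -> None:
        g, c = self.values.shape
        if len(self.gene_ids) != g or len(self.gene_symbols) != g:
            raise IntegrityError(
                f"gene annotation length {len(self.gene_ids)} != matrix rows {g}"
            )
        if len(self.barcodes) != c:
            raise IntegrityError(f"barcode count {len(self.barcodes)} != matrix cols {c}")
        if len(set(self.gene_ids)) != g:
            raise IntegrityError("gene_ids are not unique")
        if len(set(self.barcodes)) != c:
            raise IntegrityError("barcodes are not unique")
        if self.values.nnz and self.values.data.min() < 0:
            raise IntegrityError("negative counts present")
        if self.values.nnz and not np.allclose(self.values.data, np.round(self.values.data)):
            raise IntegrityError("non-integer counts present")
        missing = [c_ for c_ in META_COLUMNS if c_ not in self.cell_meta.columns]
        if missing:
            raise IntegrityError(f"cell_meta missing columns: {missing}")
        if list(self.cell_meta.index) != list(self.barcodes):
            raise IntegrityError("cell_meta index does not match barcodes")
        bad_tp = set(self.cell_meta["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise IntegrityError(f"timepoint values outside {TIMEPOINTS}: {sorted(bad_tp)}")

    # -- basic views ------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset(self, gene_mask=None, cell_mask=None) -> "CountMatrix":
        """Return a new CountMatrix restricted to masked genes/cells."""
        gm = np.ones(self.n_genes, bool) if gene_mask is None else np.asarray(gene_mask)
        cm = np.ones(self.n_cells, bool) if cell_mask is None else np.asarray(cell_mask)
        if gm.dtype != bool:
            tmp = np.zeros(self.n_genes, bool)
            tmp[gm] = True
            gm = tmp
        if cm.dtype != bool:
            tmp = np.zeros(self.n_cells, bool)
            tmp[cm] = True
            cm = tmp
        vals = self.values[gm][:, cm]
        return CountMatrix(
            values=vals.tocsr(),
            gene_ids=[g for g, k in zip(self.gene_ids, gm) if k],
            gene_symbols=[g for g, k in zip(self.gene_symbols, gm) if k],
            barcodes=[b for b, k in zip(self.barcodes, cm) if k],
            cell_meta=self.cell_meta.loc[cm].copy(),
        )

    def to_anndata(self):
        """Interop: cells x genes AnnData view of the same counts."""
        import anndata

        var = pd.DataFrame({"gene_ids": self.gene_ids}, index=self.gene_symbols)
        return anndata.AnnData(
            X=self.values.T.tocsr(), obs=self.cell_meta.copy(), var=var
        )


def concat_cells(mats: Sequence[CountMatrix]) -> CountMatrix:
    """Concatenate matrices over cells; gene annotation must agree."""
    if not mats:
        raise ValidationError("nothing to concatenate")
    first = mats[0]
    for m in mats[1:]:
        if m.gene_symbols != first.gene_symbols or m.gene_ids != first.gene_ids:
            raise IntegrityError("gene annotation differs between matrices")
    barcodes = [b for m in mats for b in m.barcodes]
    metas = [m.cell_meta for m in mats]
    if len(set(barcodes)) != len(barcodes):
        # same barcode sequenced in two samples: disambiguate by sample
        barcodes = [
            f"{m.cell_meta['sample_id'].iloc[i]}:{b}"
            for m in mats
            for i, b in enumerate(m.barcodes)
        ]
        metas = [m.cell_meta.set_axis(
            [f"{m.cell_meta['sample_id'].iloc[i]}:{b}" for i, b in enumerate(m.barcodes)]
        ) for m in mats]
    meta = pd.concat(metas)
    meta.index.name = "barcode"
    return CountMatrix(
        values=sp.hstack([m.values for m in mats]).tocsr(),
        gene_ids=list(first.gene_ids),
        gene_symbols=list(first.gene_symbols),
        barcodes=barcodes,
        cell_meta=meta,
    )


@dataclass
class MarkerReference:
    """Cell type -> set of uppercase marker gene symbols."""

    entries: dict
    tissue: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.entries.items():
            if not genes:
                raise ValidationError(f"marker set for {name!r} is empty")
        self.entries = {
            name: {str(g).upper() for g in genes} for name, genes in self.entries.items()
        }

    @property
    def cell_types(self) -> list:
        return list(self.entries)

    def all_genes(self) -> set:
        return set().union(*self.entries.values())


@dataclass
class GeneSetCollection:
    """Named gene sets: set name -> (description, set of symbols)."""

    sets: dict

    def __post_init__(self) -> None:
        for name, (_, genes) in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def genes(self, name: str) -> set:
        return self.sets[name][1]


# ---------------------------------------------------------------------------
# MTX triplet reading/writing
# ---------------------------------------------------------------------------

def _find_component(dir_path: Path, stem: str) -> Path:
    for suffix in ("", ".gz"):
        cand = dir_path / f"{stem}{suffix}"
        if cand.exists():
            return cand
    raise FormatError(f"missing {stem}[.gz] in {dir_path}")


def _open_maybe_gz(path: Path, mode: str = "rt") -> IO:
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _read_tsv_lines(path: Path) -> list:
    with _open_maybe_gz(path) as fh:
        return [line.rstrip("\n").split("\t") for line in fh if line.strip()]


def dedupe_symbols(
    values: sp.spmatrix, gene_ids: list, gene_symbols: list
) -> tuple:
    """Collapse duplicate gene symbols, keeping the highest-count row.

    Gene identity is by symbol for all downstream logic; when two rows
    share a symbol the row with the larger total count wins and the drop
    is logged.
    """
    symbols = pd.Series(gene_symbols)
    if symbols.is_unique:
        return sp.csr_matrix(values), list(gene_ids), list(gene_symbols)
    totals = np.asarray(values.sum(axis=1)).ravel()
    order = np.lexsort((-totals, symbols.to_numpy()))
    keep = np.zeros(len(symbols), bool)
    seen: set = set()
    for idx in order:
        if symbols.iloc[idx] not in seen:
            seen.add(symbols.iloc[idx])
            keep[idx] = True
    dropped = int((~keep).sum())
    logger.warning("dropped %d duplicate gene-symbol rows (kept highest-count)", dropped)
    keep_idx = np.flatnonzero(keep)
    return (
        sp.csr_matrix(values)[keep_idx],
        [gene_ids[i] for i in keep_idx],
        [gene_symbols[i] for i in keep_idx],
    )


def read_10x_mtx(
    dir_path: str | Path,
    sample_id: str,
    subject_id: str,
    timepoint: str,
    deduplicate_symbols: bool = True,
) -> CountMatrix:
    """Read a 10x-style MTX triplet directory into a :class:`CountMatrix`.

    Accepts ``matrix.mtx``, ``features.tsv`` (or ``genes.tsv``) and
    ``barcodes.tsv``, plain or gzipped. Coordinate triplets may arrive
    in any order; values are validated as non-negative integers.
    """
    if timepoint not in TIMEPOINTS:
        raise ValidationError(f"timepoint must be one of {TIMEPOINTS}, got {timepoint!r}")
    dir_path = Path(dir_path)
    mtx_path = _find_component(dir_path, "matrix.mtx")
    try:
        feat_path = _find_component(dir_path, "features.tsv")
    except FormatError:
        feat_path = _find_component(dir_path, "genes.tsv")
    bc_path = _find_component(dir_path, "barcodes.tsv")

    with _open_maybe_gz(mtx_path, "rb") as fh:
        try:
            mat = scipy.io.mmread(fh)
        except Exception as exc:  # malformed MatrixMarket content
            raise FormatError(f"cannot parse {mtx_path}: {exc}") from exc
    mat = sp.coo_matrix(mat)
    if mat.nnz:
        if mat.data.min() < 0:
            raise IntegrityError(f"{mtx_path}: negative entries present")
        if not np.allclose(mat.data, np.round(mat.data)):
            raise IntegrityError(f"{mtx_path}: non-integer entries present")
    mat = sp.csr_matrix(mat.astype(np.int64))

    feat_rows = _read_tsv_lines(feat_path)
    if len(feat_rows) != mat.shape[0]:
        raise IntegrityError(
            f"{feat_path}: {len(feat_rows)} features but matrix declares {mat.shape[0]} rows"
        )
    gene_ids = [r[0] for r in feat_rows]
    gene_symbols = [r[1] if len(r) > 1 else r[0] for r in feat_rows]

    bc_rows = _read_tsv_lines(bc_path)
    if len(bc_rows) != mat.shape[1]:
        raise IntegrityError(
            f"{bc_path}: {len(bc_rows)} barcodes but matrix declares {mat.shape[1]} cols"
        )
    barcodes = [r[0] for r in bc_rows]

    if deduplicate_symbols:
        mat, gene_ids, gene_symbols = dedupe_symbols(mat, gene_ids, gene_symbols)

    meta = pd.DataFrame(
        {
            "sample_id": sample_id,
            "subject_id": subject_id,
            "timepoint": timepoint,
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    return CountMatrix(mat, gene_ids, gene_symbols, barcodes, meta)


def write_10x_mtx(m: CountMatrix, dir_path: str | Path) -> Path:
    """Write a CountMatrix as a plain MTX triplet directory.

    The matrix is canonicalized first (explicit zeros removed, triplets
    sorted) so that round-trips are byte-stable. Barcodes are written
    without any ``sample:`` prefix duplication (as stored).
    """
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    vals = sp.coo_matrix(m.values)
    vals.eliminate_zeros()
    vals = vals.tocsc().tocoo()  # canonical column-major order for mmwrite
    with open(dir_path / "matrix.mtx", "wb") as fh:
        scipy.io.mmwrite(fh, vals, field="integer")
    with open(dir_path / "features.tsv", "w") as fh:
        for gid, sym in zip(m.gene_ids, m.gene_symbols):
            fh.write(f"{gid}\t{sym}\tGene Expression\n")
    with open(dir_path / "barcodes.tsv", "w") as fh:
        for bc in m.barcodes:
            fh.write(f"{bc}\n")
    return dir_path


# ---------------------------------------------------------------------------
# Marker reference and GMT
# ---------------------------------------------------------------------------

def read_marker_reference(path: str | Path) -> MarkerReference:
    """Read a TSV with columns ``cell_type``, ``gene_symbol``.

    Symbols are uppercased and duplicates within a type collapsed. An
    optional ``tissue`` column is kept as a per-type tag.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    for col in ("cell_type", "gene_symbol"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if df.empty:
        raise FormatError(f"{path}: no marker rows")
    entries: dict = {}
    tissue: dict = {}
    for _, row in df.iterrows():
        entries.setdefault(row["cell_type"], set()).add(str(row["gene_symbol"]).upper())
        if "tissue" in df.columns and pd.notna(row.get("tissue")):
            tissue[row["cell_type"]] = row["tissue"]
    return MarkerReference(entries=entries, tissue=tissue)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>gene...`` per line."""
    path = Path(path)
    sets: dict = {}
    with _open_maybe_gz(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >=3 tab-separated fields")
            name, desc = fields[0], fields[1]
            genes = {g.upper() for g in fields[2:] if g}
            if name in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
            sets[name] = (desc, genes)
    if not sets:
        raise FormatError(f"{path}: empty GMT file")
    return GeneSetCollection(sets=sets)
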