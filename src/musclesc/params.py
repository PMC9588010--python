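"""Pipeline parameters and flat-file configuration loading.

Every numeric threshold used by the pipeline lives in
:class:`PipelineParams` with its default. Defaults follow the analysis
the package reproduces: cells retained with 200–3000 detected genes and
mitochondrial content below 15%, genes dropped when expressed in at most
20 cells, library-size normalization with a 1e4 scale factor, 2000
highly variable genes, 7 principal components, a 7.5% assumed doublet
formation rate, 50% percent-expressed gates for markers and exercise
differential expression, and a 0.05 FDR level.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ValidationError

__all__ = ["PipelineParams", "load_params"]


@dataclass
class PipelineParams:
    """All tunable thresholds of the pipeline, with study defaults.

    Fractions are expressed on [0, 1] (``max_pct_mito=0.15`` means 15%).
    ``min_cells_per_gene_exclusive`` is an exclusive bound: genes
    expressed in at most that many cells are removed.
    """

    min_genes_per_cell: int = 200
    max_genes_per_cell: int = 3000
    min_cells_per_gene_exclusive: int = 20
    max_pct_mito: float = 0.15
    scale_factor: float = 1e4
    n_hvg: int = 2000
    n_pcs: int = 7
    neighbors_within_batch: int = 3
    knn_k: int = 15
    clustering_resolution: float = 1.0
    doublet_rate: float = 0.075
    marker_min_pct: float = 0.50
    de_min_pct: float = 0.50
    fdr_level: float = 0.05
    bulk_detect_logcpm: float = 4.0
    random_seed: int = 0
    mito_prefix: str = "MT-"
    # numerical/implementation knobs
    hvg_bins: int = 20
    zscore_clip: float = 10.0
    artificial_doublet_frac: float = 0.25
    doublet_cluster_frac: float = 0.60
    curve_span: float = 0.6
    curve_max_iter: int = 50
    curve_tol: float = 1e-4
    start_marker: str = "PAX7"
    myogenic_label: str = "Myogenic"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0 < self.min_genes_per_cell <= self.max_genes_per_cell):
            raise ValidationError(
                "require 0 < min_genes_per_cell <= max_genes_per_cell, got "
                f"{self.min_genes_per_cell}..{self.max_genes_per_cell}"
            )
        for name in (
            "max_pct_mito",
            "doublet_rate",
            "marker_min_pct",
            "de_min_pct",
            "fdr_level",
            "artificial_doublet_frac",
            "doublet_cluster_frac",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be a fraction in [0, 1], got {v}")
        if self.scale_factor <= 0:
            raise ValidationError(f"scale_factor must be positive, got {self.scale_factor}")
        if self.n_pcs < 2:
            raise ValidationError(f"n_pcs must be >= 2, got {self.n_pcs}")
        if self.min_cells_per_gene_exclusive < 0:
            raise ValidationError("min_cells_per_gene_exclusive must be >= 0")
        if not (0 < self.curve_span <= 1):
            raise ValidationError(f"curve_span must be in (0, 1], got {self.curve_span}")
        for name in ("n_hvg", "neighbors_within_batch", "knn_k", "hvg_bins", "curve_max_iter"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be a positive integer")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_FIELDS = {f.name: f for f in dataclasses.fields(PipelineParams)}


def _coerce(name: str, raw: str):
    ftype = _FIELDS[name].type
    raw = raw.strip()
    if ftype in ("int", int):
        try:
            return int(raw)
        except ValueError as exc:
            raise ValidationError(f"key {name!r}: expected integer, got {raw!r}") from exc
    if ftype in ("float", float):
        try:
            return float(raw)
        except ValueError as exc:
            raise ValidationError(f"key {name!r}: expected number, got {raw!r}") from exc
    return raw


def load_params(path: str | Path | None = None) -> PipelineParams:
    """Load parameters from a flat ``key: value`` text file.

    ``None`` returns all defaults. Lines that are blank or start with
    ``#`` are ignored. Unknown keys raise :class:`ValidationError`
    listing the valid keys; out-of-range values raise on construction.
    """
    if path is None:
        return PipelineParams()
    path = Path(path)
    overrides: dict = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if ":" not in stripped:
            raise ValidationError(f"{path}:{lineno}: expected 'key: value', got {line!r}")
        key, _, raw = stripped.partition(":")
        key = key.strip()
        if key not in _FIELDS:
            raise ValidationError(
                f"{path}:{lineno}: unknown key {key!r}; valid keys: "
                + ", ".join(sorted(_FIELDS))
            )
        overrides[key] = _coerce(key, raw)
    return PipelineParams(**overrides)
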