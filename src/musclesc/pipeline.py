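"""End-to-end orchestration: simulate-or-load through the full pipeline.

Stage order mirrors the analysis the package reproduces: QC filtering,
normalization, HVG selection, PCA, per-sample doublet scoring, the
batch-balanced graph and Leiden clustering, removal of called doublets
and doublet-infiltrated clusters, re-clustering, consensus annotation,
marker and exercise differential expression, composition testing, and
the principal-curve pseudotime shift in the myogenic compartment.

Every run writes plain TSV/JSON stage outputs plus a JSON manifest
(parameters, seed, per-stage counts) so any stage can be re-run and
diffed in isolation. Identical config + seed gives identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import MarkerReference, concat_cells, read_10x_mtx, write_10x_mtx
from .params import PipelineParams
from .preprocess import (
    build_batch_balanced_graph,
    compute_qc,
    filter_cells_genes,
    normalize_log1p,
    scale_and_pca,
    select_hvg,
)
from .cluster_annotate import (
    annotate_consensus,
    cluster_graph,
    cluster_mean_profiles,
    doublet_removal_mask,
    find_markers,
    score_doublets,
)
from .differential import composition_shift_test, composition_table, exercise_de
from .synthetic_data import (
    GroundTruth,
    SimDesign,
    expected_type_profiles,
    inject_doublets,
    marker_reference_from_design,
    simulate_atlas,
)
from .trajectory import exercise_shift, fit_principal_curve, project_pseudotime

__all__ = ["run_full", "simulate_to_dir"]

logger = logging.getLogger(__name__)


def _version() -> str:
    from . import __version__

    return __version__


def _write_manifest(out_dir: Path, payload: dict) -> None:
    import datetime

    payload = dict(payload)
    payload["software"] = f"muscle-sc {_version()}"
    payload["written_at"] = datetime.datetime.now().isoformat(timespec="seconds")
    (out_dir / "manifest.json").write_text(json.dumps(payload, indent=2, default=str))


def _file_hash(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def simulate_to_dir(design: SimDesign, out_dir: str | Path) -> Path:
    """Simulate an atlas (with doublets) and write MTX + truth tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    m, gt = simulate_atlas(design)
    m, gt = inject_doublets(m, gt, design.doublet_rate, design.seed + 1)
    write_10x_mtx(m, out_dir / "matrix")
    m.cell_meta.to_csv(out_dir / "cell_meta.tsv", sep="\t")
    gt.cells.to_csv(out_dir / "truth_cells.tsv", sep="\t")
    ref = marker_reference_from_design(design)
    rows = [(t, g) for t, genes in ref.entries.items() for g in sorted(genes)]
    pd.DataFrame(rows, columns=["cell_type", "gene_symbol"]).to_csv(
        out_dir / "marker_reference.tsv", sep="\t", index=False
    )
    (out_dir / "design.json").write_text(json.dumps(design.to_dict(), indent=2))
    return out_dir


def _myogenic_trajectory(norm, consensus_per_cell, params: PipelineParams):
    """Principal-curve pseudotime and shift on the myogenic compartment."""
    myo_mask = np.asarray(
        [str(label) == params.myogenic_label for label in consensus_per_cell]
    )
    result = {"n_myogenic": int(myo_mask.sum())}
    if myo_mask.sum() < 30:
        logger.warning("only %d myogenic cells; skipping trajectory", myo_mask.sum())
        result["skipped"] = True
        return result, None
    sub = norm.subset_cells(myo_mask)
    hvg = select_hvg(sub, params)
    emb = scale_and_pca(sub, hvg, params)
    curve = fit_principal_curve(
        emb.scores, span=params.curve_span, max_iter=params.curve_max_iter,
        tol=params.curve_tol,
    )
    start_expr = sub.gene_row(params.start_marker) if params.start_marker in sub.gene_symbols else None
    if start_expr is None:
        logger.warning("start marker %s absent; keeping default orientation", params.start_marker)
    else:
        cut = np.quantile(start_expr, 0.75)
        start_mask = start_expr >= max(cut, np.min(start_expr[start_expr > 0], initial=0.0))
        if 0 < start_mask.sum() < len(start_mask):
            curve.orient(emb.scores[start_mask], emb.scores[~start_mask])
    pt = project_pseudotime(curve, emb.scores)
    pt["barcode"] = sub.barcodes
    pt["timepoint"] = sub.cell_meta["timepoint"].to_numpy()
    pt["lineage"] = "myogenic"
    pt["curve_length"] = curve.length_
    shifts = exercise_shift(pt, curve_length=curve.length_)
    result.update(
        {
            "curve_length": curve.length_,
            "curve_converged": bool(curve.converged_),
            "curve_iterations": int(curve.n_iter_),
            "shift": {
                lin: {
                    "delta_pct": s.delta_pct,
                    "p_two_sided": s.p_two_sided,
                    "p_one_sided": s.p_one_sided,
                    "n_pre": s.n_pre,
                    "n_post": s.n_post,
                }
                for lin, s in shifts.items()
            },
        }
    )
    return result, {"pseudotime": pt, "curve": curve, "shifts": shifts, "embedding": emb,
                    "norm_sub": sub}


def run_full(
    out_dir: str | Path,
    params: PipelineParams | None = None,
    design: SimDesign | None = None,
    input_dirs=None,
    marker_ref: MarkerReference | None = None,
    ref_profiles: pd.DataFrame | None = None,
    seed: int | None = None,
    write_outputs: bool = True,
) -> dict:
    """Run every pipeline stage; returns a dict of all stage results.

    Exactly one of ``design`` (simulate) or ``input_dirs`` (load MTX
    triplets, given as ``(dir, sample_id, subject_id, timepoint)``
    tuples) must be provided. With a synthetic design, the design's
    marker table doubles as the annotation reference unless an explicit
    ``marker_ref`` is given.
    """
    params = params or PipelineParams()
    if seed is not None:
        params.random_seed = int(seed)
    out_dir = Path(out_dir)
    if write_outputs:
        out_dir.mkdir(parents=True, exist_ok=True)
    res: dict = {"params": params.to_dict(), "seed": params.random_seed}

    # -- stage: load or simulate -----------------------------------
    truth: GroundTruth | None = None
    if (design is None) == (input_dirs is None):
        raise ValidationError("provide exactly one of design= or input_dirs=")
    if design is not None:
        design_seeded = design
        if seed is not None:
            d = design.to_dict()
            d["seed"] = params.random_seed
            d["marker_table"] = {k: [tuple(x) for x in v] for k, v in d["marker_table"].items()}
            d["cell_types"] = [tuple(x) for x in d["cell_types"]]
            design_seeded = SimDesign(**d)
        m, truth = simulate_atlas(design_seeded)
        m, truth = inject_doublets(m, truth, design_seeded.doublet_rate, design_seeded.seed + 1)
        if marker_ref is None:
            marker_ref = marker_reference_from_design(design_seeded)
        if ref_profiles is None:
            ref_profiles = expected_type_profiles(design_seeded)
        res["design"] = design_seeded.to_dict()
    else:
        mats = [read_10x_mtx(d, s, subj, tp) for d, s, subj, tp in input_dirs]
        m = concat_cells(mats)
    if marker_ref is None:
        raise ValidationError("annotation requires a marker reference (marker_ref=)")
    res["input"] = {"n_genes": m.n_genes, "n_cells": m.n_cells}
    logger.info("input: %d genes x %d cells", m.n_genes, m.n_cells)

    # -- stage: QC + filtering -------------------------------------
    qc = compute_qc(m, params)
    filtered, report = filter_cells_genes(m, qc, params)
    res["qc_filter"] = report
    logger.info("QC filter: %s", report)

    # -- stage: normalize + embed ----------------------------------
    norm = normalize_log1p(filtered, params)
    hvg = select_hvg(norm, params)
    emb = scale_and_pca(norm, hvg, params)
    res["embedding"] = {
        "n_hvg": len(hvg),
        "explained_variance": emb.explained_variance.tolist(),
    }

    # -- stage: per-sample doublet scoring -------------------------
    sample_ids = norm.cell_meta["sample_id"].to_numpy()
    lib_totals = np.asarray(filtered.values.sum(axis=0)).ravel().astype(float)
    pann = np.full(norm.n_cells, np.nan)
    call = np.zeros(norm.n_cells, bool)
    # neighbourhood scale: samples of one experiment share chemistry and
    # depth, so pK is selected per sample and the per-experiment median
    # is applied to all samples, making the choice robust to a single
    # sample's noisy bimodality landscape
    scorable = [
        (i, s, sample_ids == s)
        for i, s in enumerate(pd.unique(sample_ids))
        if (sample_ids == s).sum() >= 50
    ]
    for _, s, mask in ((i, s, m) for i, s, m in scorable if m.sum() < 50):
        logger.warning("sample %s has %d cells; doublet scoring skipped", s, mask.sum())
    pk_choices = {}
    for i, s, mask in scorable:
        sc = score_doublets(
            norm.subset_cells(mask), params, seed=params.random_seed + 1000 + i,
            totals=lib_totals[mask],
        )
        pk_choices[s] = sc.pk
    pk_consensus = float(np.median(list(pk_choices.values()))) if pk_choices else None
    for i, s, mask in scorable:
        scores = score_doublets(
            norm.subset_cells(mask), params, seed=params.random_seed + 1000 + i,
            totals=lib_totals[mask], pk_override=pk_consensus,
        )
        pann[mask] = scores.pann
        call[mask] = scores.call
    res["doublets"] = {
        "n_called": int(call.sum()),
        "pk_per_sample": pk_choices,
        "pk_consensus": pk_consensus,
    }

    # -- stage: graph + initial clustering -------------------------
    graph = build_batch_balanced_graph(emb, sample_ids, params)
    clustering0 = cluster_graph(graph, params)
    drop = doublet_removal_mask(clustering0.labels, call, params.doublet_cluster_frac)
    res["doublets"]["n_removed_with_clusters"] = int(drop.sum())
    res["initial_clustering"] = {
        "n_clusters": clustering0.n_clusters,
        "modularity": clustering0.modularity,
    }

    keep = ~drop
    norm_clean = norm.subset_cells(keep)
    emb_scores_clean = emb.scores[keep]
    from .preprocess import EmbeddingSpace

    emb_clean = EmbeddingSpace(
        scores=emb_scores_clean,
        loadings=emb.loadings,
        explained_variance=emb.explained_variance,
        hvg_list=emb.hvg_list,
        barcodes=[b for b, k in zip(emb.barcodes, keep) if k],
    )
    graph_clean = build_batch_balanced_graph(
        emb_clean, norm_clean.cell_meta["sample_id"].to_numpy(), params
    )
    clustering = cluster_graph(graph_clean, params)
    res["clustering"] = {
        "n_clusters": clustering.n_clusters,
        "modularity": clustering.modularity,
        "n_cells": norm_clean.n_cells,
    }

    # -- stage: markers + annotation -------------------------------
    markers = find_markers(norm_clean, clustering, params)
    profiles = cluster_mean_profiles(norm_clean, clustering)
    annotation = annotate_consensus(markers, profiles, marker_ref, ref_profiles, params)
    label_map = annotation.label_map()
    consensus_per_cell = np.array(
        [str(label_map[int(lab)]) for lab in clustering.labels]
    )
    res["annotation"] = {
        "per_cluster": {
            int(k): {"consensus": row["consensus"], "votes": int(row["votes"])}
            for k, row in annotation.table.iterrows()
        }
    }

    # -- stage: exercise DE ----------------------------------------
    de = exercise_de(norm_clean, consensus_per_cell, params)
    res["exercise_de"] = {
        "n_tested": int(len(de)),
        "n_significant": int((de["fdr"] < params.fdr_level).sum()) if len(de) else 0,
    }

    # -- stage: composition ----------------------------------------
    comp = composition_table(consensus_per_cell, norm_clean.cell_meta)
    comp_tests = composition_shift_test(comp, "increase")
    res["composition"] = {
        "tests": {t: float(p) for t, p in comp_tests["p"].items()},
    }

    # -- stage: trajectory -----------------------------------------
    traj_summary, traj_objects = _myogenic_trajectory(norm_clean, consensus_per_cell, params)
    res["trajectory"] = traj_summary

    # -- outputs ----------------------------------------------------
    res["_objects"] = {
        "matrix": m,
        "truth": truth,
        "qc": qc,
        "filtered": filtered,
        "norm": norm_clean,
        "embedding": emb,
        "clustering": clustering,
        "markers": markers,
        "annotation": annotation,
        "consensus_per_cell": consensus_per_cell,
        "de": de,
        "composition": comp,
        "composition_tests": comp_tests,
        "doublet_call": call,
        "doublet_pann": pann,
        "kept_mask": keep,
        "trajectory": traj_objects,
    }
    if write_outputs:
        _write_stage_outputs(out_dir, res)
    return res


def _write_stage_outputs(out_dir: Path, res: dict) -> None:
    obj = res["_objects"]
    obj["qc"].table.to_csv(out_dir / "qc.tsv", sep="\t")
    pd.DataFrame(
        obj["embedding"].scores,
        index=pd.Index(obj["embedding"].barcodes, name="barcode"),
        columns=[f"PC{i + 1}" for i in range(obj["embedding"].scores.shape[1])],
    ).to_csv(out_dir / "embedding.tsv", sep="\t")
    pd.DataFrame(
        {
            "barcode": obj["norm"].barcodes,
            "cluster": obj["clustering"].labels,
            "consensus": obj["consensus_per_cell"],
        }
    ).to_csv(out_dir / "clusters.tsv", sep="\t", index=False)
    obj["markers"].to_csv(out_dir / "markers.tsv", sep="\t", index=False)
    obj["de"].to_csv(out_dir / "exercise_de.tsv", sep="\t", index=False)
    obj["composition"].to_csv(out_dir / "composition.tsv", sep="\t", index=False)
    obj["composition_tests"].to_csv(out_dir / "composition_tests.tsv", sep="\t")
    ann = obj["annotation"].table[
        ["label_marker_rank", "label_overlap_test", "label_profile_corr", "consensus", "votes"]
    ]
    ann.to_csv(out_dir / "annotation.tsv", sep="\t")
    traj = obj["trajectory"]
    if traj is not None:
        traj["pseudotime"].to_csv(out_dir / "pseudotime.tsv", sep="\t", index=False)
        nodes = pd.DataFrame(
            traj["curve"].nodes_,
            columns=[f"PC{i + 1}" for i in range(traj["curve"].nodes_.shape[1])],
        )
        nodes["lambda"] = traj["curve"].node_lambda_
        nodes.to_csv(out_dir / "curve_nodes.tsv", sep="\t", index=False)
        (out_dir / "shift.json").write_text(
            json.dumps(res["trajectory"]["shift"], indent=2)
        )
    manifest = {k: v for k, v in res.items() if k != "_objects"}
    _write_manifest(out_dir, manifest)
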