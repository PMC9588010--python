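"""Shared fixtures: parameter sets, small atlases, and one full run.

The full default-design pipeline run is session-scoped because several
tests (annotation recovery, embedding separation, shift recovery)
measure different aspects of the same experiment.
"""

import logging

import pytest
from hypothesis import settings as hypothesis_settings

import musclesc as ms

logging.getLogger("musclesc").setLevel(logging.ERROR)

# property tests must behave identically on every machine and run
hypothesis_settings.register_profile("deterministic", derandomize=True, deadline=None)
hypothesis_settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def params():
    return ms.PipelineParams()


@pytest.fixture(scope="session")
def small_design():
    """A fast atlas: 2 subjects x 2 timepoints x 300 cells, 800 background genes."""
    return ms.default_design(n_subjects=2, cells_per_sample=300, n_background_genes=800)


@pytest.fixture(scope="session")
def small_atlas(small_design):
    """Simulated small atlas with injected doublets and its truth."""
    m, gt = ms.simulate_atlas(small_design)
    return ms.inject_doublets(m, gt, small_design.doublet_rate, small_design.seed + 1)


@pytest.fixture(scope="session")
def small_normalized(small_atlas, params):
    m, gt = small_atlas
    qc = ms.compute_qc(m, params)
    filtered, _ = ms.filter_cells_genes(m, qc, params)
    norm = ms.normalize_log1p(filtered, params)
    return norm, gt.subset(norm.barcodes)


@pytest.fixture(scope="session")
def full_run(tmp_path_factory):
    """One complete default-design pipeline run (seed 0)."""
    out = tmp_path_factory.mktemp("full_run")
    return ms.run_full(out, design=ms.default_design(), seed=0)


def myogenic_shift_from_run(res):
    """The myogenic pseudotime shift summary of a run_full result."""
    return res["trajectory"]["shift"]["myogenic"]
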