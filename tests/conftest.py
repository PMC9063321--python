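"""Shared fixtures: a tiny synthetic cohort and one full pipeline run.

The tiny study conditions (20 subjects in two equal groups, 12 networks,
158 TRs, two planted evolving motifs, 2:1 signal-motif usage ratio) are
fixed here once and reused by every integration-level test; the pipeline
run on them is session-scoped because the embedding stage dominates the
suite's runtime.
"""

from __future__ import annotations

import numpy as np
import pytest

from evodfnc.config import PipelineConfig
from evodfnc.pipeline import run_pipeline
from evodfnc.synthgen import SynthCohortConfig, simulate_cohort, write_cohort

TINY_COHORT_SEED = 7
TINY_PIPELINE_SEED = 1

# Desk-scale analysis parameters for the 12-network cohort: fewer embedding
# runs and clusters than the full-scale defaults, restart counts scaled to
# the small problem.
TINY_PIPELINE = dict(
    n_runs=5,
    K=6,
    M=6,
    snap_restarts=20,
    exemplar_restarts=50,
    meta_restarts=50,
    seed=TINY_PIPELINE_SEED,
)


@pytest.fixture(scope="session")
def tiny_cohort():
    """(timecourses, manifest, ground_truth) for the tiny preset."""
    return simulate_cohort(SynthCohortConfig(seed=TINY_COHORT_SEED))


@pytest.fixture(scope="session")
def tiny_cohort_dir(tiny_cohort, tmp_path_factory):
    """The tiny cohort written in the pipeline's on-disk input format."""
    tcs, manifest, truth = tiny_cohort
    out = tmp_path_factory.mktemp("tiny_cohort")
    manifest_path = write_cohort(tcs, manifest, out, truth)
    return manifest_path


@pytest.fixture(scope="session")
def tiny_bundle(tiny_cohort_dir, tmp_path_factory):
    """A complete pipeline run on the tiny cohort."""
    out = tmp_path_factory.mktemp("tiny_run")
    return run_pipeline(tiny_cohort_dir, PipelineConfig(**TINY_PIPELINE), out)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
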