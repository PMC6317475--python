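"""Shared fixtures: one seed-17 miniature study per session, written to disk
once, with the full pipeline run on it."""

from __future__ import annotations

import time
import warnings

import pytest

from splicepept import (
    FixtureConfig,
    PipelineConfig,
    build_fixture,
    run_pipeline,
    write_fixture,
)


@pytest.fixture(scope="session")
def bundle():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_fixture(FixtureConfig(seed=17))


@pytest.fixture(scope="session")
def fixture_paths(bundle, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixture")
    return write_fixture(bundle, outdir)


@pytest.fixture(scope="session")
def pipeline_config(fixture_paths, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("pipeline_out")
    keys = [
        "genome", "reference_gtf", "assembled_gtf", "junction_bed",
        "proteome", "contaminants", "psm_table", "exclusion",
        "cp_coding", "cp_noncoding",
    ]
    return PipelineConfig(
        **{k: str(fixture_paths[k]) for k in keys}, outdir=str(outdir)
    )


@pytest.fixture(scope="session")
def pipeline_result(pipeline_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t0 = time.perf_counter()
        result = run_pipeline(pipeline_config)
    result.summary["_wall_seconds"] = time.perf_counter() - t0
    return result
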