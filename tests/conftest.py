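"""Shared fixtures: a small synthetic study generated once per session."""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from mirpipe import simdata
from mirpipe.pipeline import PipelineConfig, run_pipeline

SMALL_DEPTH = 20_000
SMALL_SEED = 101


@pytest.fixture(scope="session")
def small_config() -> simdata.SimConfig:
    return simdata.SimConfig(
        seed=SMALL_SEED, libraries=simdata.default_libraries(SMALL_DEPTH))


@pytest.fixture(scope="session")
def small_reference(small_config):
    return simdata.make_reference(small_config)


@pytest.fixture(scope="session")
def small_study(small_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("study")
    paths = simdata.write_study(small_config, outdir)
    return {k: str(v) for k, v in paths.items()}


@pytest.fixture(scope="session")
def small_run(small_config, small_study, tmp_path_factory):
    """One pipeline run over the small study, shared across tests."""
    outdir = tmp_path_factory.mktemp("report")
    config = PipelineConfig(
        genome=small_study["genome"],
        annotation=small_study["annotation"],
        known_catalog=small_study["known_catalog"],
        fastqs={lib.library_id: small_study[f"fastq:{lib.library_id}"]
                for lib in small_config.libraries},
        transcriptome=small_study["transcriptome"],
        term_map=small_study["term_map"],
        qpcr=small_study["qpcr"],
        outdir=str(outdir),
        adapter=small_config.adapter,
        seed=SMALL_SEED,
    )
    bundle = run_pipeline(config)
    return config, bundle
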