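"""Shared fixtures: one small reciprocal-cross bundle, generated once."""

from __future__ import annotations

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from imprintscan.pipeline import RunConfig, run_pipeline
from imprintscan.synthetic import SimConfig, emit_fixture_bundle, make_bundle

BUNDLE_SEED = 42


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(seed=BUNDLE_SEED)


@pytest.fixture(scope="session")
def bundle(sim_config):
    """In-memory default bundle: genomes, annotation, truth, reads, expected."""
    genomes, annotation, truth, reads, expected = make_bundle(sim_config)
    return {
        "genomes": genomes,
        "annotation": annotation,
        "truth": truth,
        "reads": reads,
        "expected": expected,
        "config": sim_config,
    }


@pytest.fixture(scope="session")
def bundle_dir(sim_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    paths = emit_fixture_bundle(sim_config, outdir)
    return paths


@pytest.fixture(scope="session")
def pipeline_report(bundle_dir, tmp_path_factory):
    """Full pipeline run on the default bundle (reads entry point)."""
    outdir = tmp_path_factory.mktemp("run")
    config = RunConfig(
        genome_a=str(bundle_dir["genome_a"]),
        genome_b=str(bundle_dir["genome_b"]),
        snps=str(bundle_dir["snps_tsv"]),
        annotation=str(bundle_dir["annotation"]),
        reads_a_mother=str(bundle_dir["reads_A_mother"]),
        reads_b_mother=str(bundle_dir["reads_B_mother"]),
        truth=str(bundle_dir["truth"]),
        tissue="endosperm",
        adaptor="AGATCGGAAGAGCACACGTCT",
        outdir=str(outdir),
    )
    return run_pipeline(config), config
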