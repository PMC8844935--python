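"""Shared fixtures: small simulated datasets, generated at test time."""

from __future__ import annotations

import pytest

from regulonkit.pipeline import PipelineConfig
from regulonkit.simulate import (
    SimulationConfig,
    simulate_annotation,
    simulate_regulon,
    write_fixture,
)

SMALL = dict(n_genes=200, n_chroms=2, chrom_len=800_000)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(seed=7, **SMALL)


@pytest.fixture(scope="session")
def noiseless_config() -> SimulationConfig:
    return SimulationConfig(
        seed=11, summit_jitter_sd=0.0, detection_prob=1.0, replicate_cv=0.0, **SMALL
    )


@pytest.fixture(scope="session")
def annotation_sim(small_config):
    return simulate_annotation(small_config)


@pytest.fixture(scope="session")
def regulon_sim(small_config, annotation_sim):
    return simulate_regulon(small_config, annotation_sim)


@pytest.fixture(scope="session")
def noiseless_sim(noiseless_config):
    sim = simulate_annotation(noiseless_config)
    return sim, simulate_regulon(noiseless_config, sim)


def fixture_pipeline_config(directory, outdir) -> PipelineConfig:
    """PipelineConfig pointing at a written fixture directory."""
    d = directory
    return PipelineConfig(
        annotation=str(d / "annotation.gff3"),
        chrom_sizes=str(d / "chrom.sizes"),
        outdir=str(outdir),
        summits={
            "HA": [str(d / "summits/HA_rep1.bed"), str(d / "summits/HA_rep2.bed")],
            "GFP": [str(d / "summits/GFP_rep1.bed"), str(d / "summits/GFP_rep2.bed")],
        },
        genome_fasta=str(d / "genome.fa"),
        reads=str(d / "reads.bed"),
        expression=str(d / "expression.tsv"),
        samples=str(d / "samples.tsv"),
        motifs=str(d / "motifs.tsv"),
        categories=str(d / "categories.tsv"),
        tf_genes=str(d / "tf_genes.txt"),
    )


@pytest.fixture(scope="session")
def noiseless_fixture_dir(noiseless_sim, tmp_path_factory):
    sim, regulon = noiseless_sim
    d = tmp_path_factory.mktemp("noiseless_fixture")
    write_fixture(d, sim, regulon)
    return d, regulon
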