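"""Shared fixtures: simulated datasets are built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from editscan.detect import DetectionParams, build_pileup, detect_sites
from editscan.genome import Genome
from editscan.simulate import (
    SimulationConfig,
    generate_genome,
    plant_editing_sites,
    simulate_dna_reads,
    simulate_reads,
    write_sam,
)


def build_dataset(config: SimulationConfig, tmpdir, detect: bool = True) -> dict:
    genome = generate_genome(config)
    truth = plant_editing_sites(genome, config)
    rna = simulate_reads(genome, truth, config)
    dna = simulate_dna_reads(genome, config)
    rna_sam = str(tmpdir / "rna.sam")
    dna_sam = str(tmpdir / "dna.sam")
    write_sam(rna, genome, rna_sam)
    write_sam(dna, genome, dna_sam)
    rna_pileup = build_pileup(rna_sam, genome)
    dna_pileup = build_pileup(dna_sam, genome)
    out = {
        "config": config,
        "genome": genome,
        "truth": truth,
        "rna_reads": rna,
        "dna_reads": dna,
        "rna_sam": rna_sam,
        "dna_sam": dna_sam,
        "rna_pileup": rna_pileup,
        "dna_pileup": dna_pileup,
    }
    if detect:
        out["sites"] = detect_sites(rna_pileup, dna_pileup, genome, DetectionParams())
    return out


@pytest.fixture(scope="session")
def big_dataset(tmp_path_factory):
    """200 kb genome, 1,000 sites with levels in [0.2, 0.9], 50x, e=0.001."""
    config = SimulationConfig(
        seed=101,
        contig_lengths=[200_000],
        gc_content=0.40,
        n_sites=1000,
        level_distribution={"name": "uniform", "low": 0.2, "high": 0.9},
        coverage=50,
        read_length=100,
        error_rate=0.001,
        dna_coverage=50,
    )
    return build_dataset(config, tmp_path_factory.mktemp("big"))


@pytest.fixture(scope="session")
def clean_dataset(tmp_path_factory):
    """Error-free simulation: 1,000 sites, e=0, 30x; only editing as signal."""
    config = SimulationConfig(
        seed=202,
        contig_lengths=[150_000],
        gc_content=0.40,
        n_sites=1000,
        level_distribution={"name": "uniform", "low": 0.2, "high": 0.9},
        coverage=30,
        read_length=100,
        error_rate=0.0,
        dna_coverage=30,
    )
    return build_dataset(config, tmp_path_factory.mktemp("clean"))


@pytest.fixture(scope="session")
def motif_sim():
    """2,000 sites with strong upstream-G depletion (no reads needed)."""
    config = SimulationConfig(
        seed=303,
        contig_lengths=[400_000],
        gc_content=0.40,
        n_sites=2000,
        motif_bias=0.9,
        coverage=1,
    )
    genome = generate_genome(config)
    truth = plant_editing_sites(genome, config)
    return {"config": config, "genome": genome, "truth": truth}


@pytest.fixture(scope="session")
def hairpin_sim():
    """Half the sites embedded in planted inverted repeats."""
    config = SimulationConfig(
        seed=404,
        contig_lengths=[60_000],
        n_sites=120,
        hairpin_fraction=0.5,
        coverage=1,
    )
    genome = generate_genome(config)
    truth = plant_editing_sites(genome, config)
    return {"config": config, "genome": genome, "truth": truth}


def make_genome(**contigs) -> Genome:
    return Genome(dict(contigs))


def truth_site_keys(truth) -> set:
    return set(zip(truth.records["contig"], truth.records["position"]))


def site_keys(sites) -> set:
    return set(zip(sites["contig"], sites["position"]))
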