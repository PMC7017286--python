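"""Shared fixtures: small simulated cohorts and the QC-scenario libraries.

Expensive simulations are session-scoped so the unit and acceptance tests
share them; everything is generated programmatically from fixed seeds.
"""

from __future__ import annotations

import numpy as np
import pytest

from equichip import readqc
from equichip.readqc import AlignedTag, TagSet
from equichip.simdata import (
    SimConfig,
    make_genes,
    make_genome,
    plant_elements,
    simulate_library,
)


def make_tag(chrom="chr1", start=100, end=150, strand="+", mapq=60, **flags) -> AlignedTag:
    return AlignedTag(chrom, start, end, strand, mapq, **flags)


def tagset(*tags: AlignedTag) -> TagSet:
    return TagSet.from_records(tags)


@pytest.fixture(scope="session")
def qc_config() -> SimConfig:
    """The QC study conditions: 200k reads, dup 0.1, 20-fold enrichment."""
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def qc_truth(qc_config):
    genome = make_genome(qc_config)
    truth, genome = plant_elements(qc_config, genome)
    return truth


@pytest.fixture(scope="session")
def good_library(qc_config, qc_truth):
    chip = simulate_library(qc_truth, "tissue_1", "H3K27ac", 1, qc_config)
    input_ = simulate_library(qc_truth, "tissue_1", "input", 1, qc_config)
    return chip, input_


@pytest.fixture(scope="session")
def good_qc(qc_config, good_library):
    chip, input_ = good_library
    return readqc.qc_panel(chip, input_, qc_config.chrom_lengths)


@pytest.fixture(scope="session")
def degraded_qc():
    """High duplication, no enrichment: the QC panel's failure mode."""
    cfg = SimConfig(seed=1, duplication_rate=0.6, enrichment_fold=1.0)
    genome = make_genome(cfg)
    truth, genome = plant_elements(cfg, genome)
    chip = simulate_library(truth, "tissue_1", "H3K27ac", 1, cfg)
    input_ = simulate_library(truth, "tissue_1", "input", 1, cfg)
    return readqc.qc_panel(chip, input_, cfg.chrom_lengths)


@pytest.fixture(scope="session")
def fragment_shift_estimates():
    """Fragment-peak shifts from 20 independently seeded 200k-read libraries."""
    shifts = []
    for seed in range(1, 21):
        cfg = SimConfig(seed=seed)
        genome = make_genome(cfg)
        truth, genome = plant_elements(cfg, genome)
        chip = simulate_library(truth, "tissue_1", "H3K27ac", 1, cfg)
        chip = readqc.remove_duplicates(readqc.filter_alignments(chip)[0])
        prof = readqc.cross_correlation(chip, cfg.chrom_lengths)
        shifts.append(prof.fragment_shift)
    return shifts


def small_sim_config(seed: int, **overrides) -> SimConfig:
    """A 500 kb, 3-tissue configuration for planted-structure tests."""
    kwargs = dict(
        chrom_lengths={"chr1": 300_000, "chr2": 200_000},
        n_tissues=3,
        reads_per_library=40_000,
        n_shared_elements=5,
        n_specific_elements_per_tissue=3,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    """Genome, genes, truth and H3K4me1/H3K27ac libraries for one small cohort."""
    cfg = small_sim_config(seed=3)
    genome = make_genome(cfg)
    genes = make_genes(cfg)
    truth, genome = plant_elements(cfg, genome, genes)
    libraries = {}
    for tissue in cfg.tissues:
        libraries[(tissue, "input", 1)] = simulate_library(truth, tissue, "input", 1, cfg)
        for mark in ("H3K4me1", "H3K27ac"):
            for rep in (1, 2):
                libraries[(tissue, mark, rep)] = simulate_library(truth, tissue, mark, rep, cfg)
    return cfg, genome, genes, truth, libraries


def random_interval_set(rng: np.random.Generator, genome_len: int = 100_000,
                        max_intervals: int = 20, max_len: int = 4000) -> np.ndarray:
    n = rng.integers(0, max_intervals + 1)
    starts = rng.integers(0, genome_len - max_len, size=n)
    lengths = rng.integers(1, max_len, size=n)
    return np.stack([starts, starts + lengths], axis=1).astype(np.int64) if n else \
        np.empty((0, 2), dtype=np.int64)


def per_base_mask(arr: np.ndarray, genome_len: int = 100_000) -> np.ndarray:
    """Brute-force membership oracle: boolean per base."""
    mask = np.zeros(genome_len, dtype=bool)
    for s, e in np.asarray(arr).reshape(-1, 2):
        mask[s:e] = True
    return mask
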