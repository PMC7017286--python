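"""Simulator contracts: determinism, element placement, read geometry."""

import re

import numpy as np
import pandas as pd
import pytest

from equichip import readqc
from equichip.errors import ConfigurationError, LookupError_, PlacementError
from equichip.simdata import (
    IUPAC,
    SimConfig,
    make_genes,
    make_genome,
    plant_elements,
    simulate_library,
)

TINY = dict(chrom_lengths={"chr1": 60_000, "chr2": 40_000}, n_tissues=2,
            reads_per_library=5_000, n_shared_elements=5,
            n_specific_elements_per_tissue=3, element_spacing=800)


def tiny_config(seed=7, **overrides):
    kwargs = {**TINY, **overrides}
    return SimConfig(seed=seed, **kwargs)


class TestGenome:
    def test_lengths_and_alphabet(self):
        genome = make_genome(tiny_config())
        assert {c: len(s) for c, s in genome.items()} == {"chr1": 60_000, "chr2": 40_000}
        assert set(genome["chr1"]) <= set("ACGT")

    def test_seed_determinism_and_variation(self):
        g1 = make_genome(tiny_config(seed=7))
        g2 = make_genome(tiny_config(seed=7))
        g3 = make_genome(tiny_config(seed=8))
        assert g1 == g2
        assert g1 != g3
        assert {c: len(s) for c, s in g1.items()} == {c: len(s) for c, s in g3.items()}

    @pytest.mark.parametrize("bad", [
        dict(chrom_lengths={}),
        dict(chrom_lengths={"chr1": 0}),
        dict(duplication_rate=1.0),
        dict(read_length=300),
        dict(enrichment_fold=0.5),
    ])
    def test_invalid_configuration_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            tiny_config(**bad)


class TestElements:
    def test_counts_and_disjointness(self):
        cfg = tiny_config()
        truth, _ = plant_elements(cfg, make_genome(cfg))
        shared = [e for e in truth.elements if e.element_class == "shared"]
        specific = [e for e in truth.elements if e.element_class == "tissue_specific"]
        assert len(shared) == 5 and len(specific) == 6
        assert all(e.owner_tissue is None for e in shared)
        for tissue in cfg.tissues:
            assert sum(e.owner_tissue == tissue for e in specific) == 3
        by_chrom = {}
        for e in truth.elements:
            by_chrom.setdefault(e.chrom, []).append((e.start, e.end))
        for spans in by_chrom.values():
            spans.sort()
            assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))

    def test_specific_enhancers_carry_active_marks_and_motif(self):
        cfg = tiny_config()
        truth, genome = plant_elements(cfg, make_genome(cfg))
        pattern = "".join(f"[{IUPAC[b]}]" for b in cfg.motif_consensus)
        rc = "".join(f"[{IUPAC[b]}]" for b in "TRTTTH")  # revcomp of DAAAYA
        for e in truth.elements:
            if e.element_class == "tissue_specific":
                assert {"H3K4me1", "H3K27ac"} <= e.marks_present
                seq = genome[e.chrom][e.start:e.end]
                assert re.search(pattern, seq) or re.search(rc, seq)
        assert len(truth.motif_sites) == 6

    def test_per_tissue_motif_mapping(self):
        cfg = tiny_config(motif_consensus={"tissue_1": "TTTACGCGTAAA"})
        truth, genome = plant_elements(cfg, make_genome(cfg))
        for e in truth.elements:
            if e.element_class != "tissue_specific":
                continue
            seq = genome[e.chrom][e.start:e.end]
            found = "TTTACGCGTAAA" in seq or "TTTACGCGTAAA" in seq[::-1].translate(
                str.maketrans("ACGT", "TGCA"))
            assert found == (e.owner_tissue == "tissue_1")

    def test_overfull_genome_raises_placement_error(self):
        cfg = tiny_config(chrom_lengths={"chr1": 5_000},
                          n_shared_elements=30, n_specific_elements_per_tissue=10)
        with pytest.raises(PlacementError):
            plant_elements(cfg, make_genome(cfg))


@pytest.fixture(scope="module")
def truth():
    cfg = tiny_config()
    truth, _ = plant_elements(cfg, make_genome(cfg))
    return cfg, truth


class TestLibraries:

    def test_tags_within_chromosomes_uniform_mapq(self, truth):
        cfg, t = truth
        tags = simulate_library(t, "tissue_1", "H3K27ac", 1, cfg)
        df = tags.df
        assert len(tags) == cfg.reads_per_library
        assert (df["mapq"] == 60).all()
        assert ((df["end"] - df["start"]) == cfg.read_length).all()
        for chrom, length in cfg.chrom_lengths.items():
            sub = df[df["chrom"] == chrom]
            assert (sub["start"] >= 0).all() and (sub["end"] <= length).all()

    def test_library_determinism(self, truth):
        cfg, t = truth
        a = simulate_library(t, "tissue_1", "H3K4me1", 2, cfg)
        b = simulate_library(t, "tissue_1", "H3K4me1", 2, cfg)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_unknown_tissue_or_mark(self, truth):
        cfg, t = truth
        with pytest.raises(LookupError_):
            simulate_library(t, "tissue_1", "H3K9me3", 1, cfg)
        with pytest.raises(LookupError_):
            simulate_library(t, "liver", "H3K4me1", 1, cfg)

    def test_input_has_no_element_elevation(self, truth):
        cfg, t = truth
        cfg = tiny_config(reads_per_library=60_000, phantom_artifact_fraction=0.0)
        truth2, _ = plant_elements(cfg, make_genome(cfg))
        tags = simulate_library(truth2, "tissue_1", "input", 1, cfg)
        elem_bp = sum(e.end - e.start for e in truth2.elements)
        in_elem = 0
        for e in truth2.elements:
            sub = tags.df[tags.df["chrom"] == e.chrom]
            in_elem += ((sub["start"] < e.end) & (sub["start"] >= e.start)).sum()
        expected = len(tags) * elem_bp / cfg.genome_length
        assert in_elem < 3 * expected + 30  # no systematic elevation

    def test_enrichment_fold_reflected_in_depth(self):
        """Per-base depth in mark-carrying elements ~ enrichment_fold x background."""
        cfg = tiny_config(reads_per_library=150_000, duplication_rate=0.0,
                          phantom_artifact_fraction=0.0, replicate_sigma=0.0)
        truth, _ = plant_elements(cfg, make_genome(cfg))
        tags = simulate_library(truth, "tissue_1", "H3K27ac", 1, cfg)
        active = truth.intervals("tissue_1", "H3K27ac")
        starts = {c: tags.df.loc[tags.df["chrom"] == c, "start"].to_numpy()
                  for c in cfg.chrom_lengths}
        elem_bp = in_elem = 0
        for c, arr in active.items():
            for s, e in arr:
                elem_bp += e - s
                in_elem += int(((starts[c] >= s) & (starts[c] < e)).sum())
        bg_bp = cfg.genome_length - elem_bp
        bg = len(tags) - in_elem
        ratio = (in_elem / elem_bp) / (bg / bg_bp)
        assert 14 < ratio < 26

    def test_zero_duplication_gives_nrf_near_one(self):
        cfg = tiny_config(duplication_rate=0.0, reads_per_library=4_000,
                          phantom_artifact_fraction=0.0)
        truth, _ = plant_elements(cfg, make_genome(cfg))
        tags = simulate_library(truth, "tissue_1", "input", 1, cfg)
        report = readqc.complexity_metrics(tags)
        assert report.NRF > 0.97

    def test_higher_duplication_lowers_nrf(self):
        nrfs = []
        for dup in (0.0, 0.3, 0.6):
            cfg = tiny_config(duplication_rate=dup)
            truth, _ = plant_elements(cfg, make_genome(cfg))
            tags = simulate_library(truth, "tissue_1", "input", 1, cfg)
            nrfs.append(readqc.complexity_metrics(tags).NRF)
        assert nrfs[0] > nrfs[1] > nrfs[2]

    def test_decoy_fraction_adds_low_mapq_tags(self, truth):
        cfg, _ = truth
        cfg = tiny_config(decoy_fraction=0.05)
        t, _ = plant_elements(cfg, make_genome(cfg))
        tags = simulate_library(t, "tissue_1", "H3K4me1", 1, cfg)
        low = tags.df["mapq"] < 30
        assert low.sum() == round(0.05 * cfg.reads_per_library)
        assert tags.df.loc[low, "mapq"].max() < 30


def test_genes_are_disjoint_and_stranded():
    cfg = tiny_config(n_genes=40, gene_length_range=(500, 1500))
    genes = make_genes(cfg)
    assert len(genes) == 40
    assert {g.strand for g in genes} <= {"+", "-"}
    by_chrom = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
    for spans in by_chrom.values():
        spans.sort()
        assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))
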