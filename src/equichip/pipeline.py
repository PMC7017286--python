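"""Stage orchestration: simulate → QC → peaks → consensus → comparisons →
profiles → motifs, with a checksum manifest for reproducibility.

Every stage reads its inputs from the run directory (so the text formats
are exercised end-to-end), writes its outputs there, and appends a manifest
entry recording the resolved parameters and the SHA-256 of every output
file.  Rerunning a stage with the same configuration and seed reproduces
identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from . import io, motifs, peaks, profiles, readqc, simdata, tissuecomp
from .config import RunConfig
from .errors import DependencyError
from .simdata import derive_seed

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "callpeaks", "combine", "compare", "profile", "motifs")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _update_manifest(cfg: RunConfig, stage: str, inputs: list[str], outputs: list[Path]):
    manifest_path = cfg.outdir / "manifest.json"
    manifest = {}
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
    manifest[stage] = {
        "inputs": sorted(inputs),
        "parameters": cfg.to_dict(),
        "outputs": {str(p.relative_to(cfg.outdir)): _sha256(p) for p in sorted(outputs)},
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest[stage]


def _library_path(cfg: RunConfig, tissue: str, mark: str, rep: int) -> Path:
    return cfg.outdir / "sim" / f"{tissue}.{mark}.rep{rep}.tagAlign"


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise DependencyError(f"missing {path}; run the '{stage}' stage first")
    return path


def _chrom_sizes(cfg: RunConfig) -> dict[str, int]:
    return io.read_chrom_sizes(_require(cfg.outdir / "sim" / "genome.chrom.sizes", "simulate"))


def _load_library(cfg: RunConfig, tissue: str, mark: str, rep: int) -> readqc.TagSet:
    return io.read_tagalign(_require(_library_path(cfg, tissue, mark, rep), "simulate"))


def _libraries(cfg: RunConfig):
    for tissue in cfg.sim.tissues:
        for mark in cfg.sim.marks:
            for rep in range(1, cfg.replicates + 1):
                yield tissue, mark, rep


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig) -> dict:
    out = cfg.outdir / "sim"
    out.mkdir(parents=True, exist_ok=True)
    genome, genes, truth, libraries = simdata.simulate_study(cfg.sim, cfg.replicates)
    written = []
    io.write_fasta(genome, out / "genome.fa")
    written.append(out / "genome.fa")
    io.write_chrom_sizes(cfg.sim.chrom_lengths, out / "genome.chrom.sizes")
    written.append(out / "genome.chrom.sizes")
    io.write_genes_bed(genes, out / "genes.bed")
    written.append(out / "genes.bed")
    io.write_table(truth.to_frame(), out / "truth_elements.tsv")
    written.append(out / "truth_elements.tsv")
    motif_df = pd.DataFrame(truth.motif_sites, columns=["chrom", "position", "strand"])
    io.write_table(motif_df, out / "truth_motifs.tsv")
    written.append(out / "truth_motifs.tsv")
    for (tissue, mark, rep), tags in libraries.items():
        path = _library_path(cfg, tissue, mark, rep)
        io.write_tagalign(tags, path)
        written.append(path)
    pwms = make_motif_database(cfg)
    motifs.write_jaspar(pwms, out / "motifs.jaspar")
    written.append(out / "motifs.jaspar")
    return _update_manifest(cfg, "simulate", [], written)


def make_motif_database(cfg: RunConfig) -> list[motifs.PositionWeightMatrix]:
    """Planted consensus motif(s) plus random decoy PFMs, JASPAR-serializable."""
    rng = np.random.default_rng(derive_seed(cfg.seed, "motifdb"))
    pwms: list[motifs.PositionWeightMatrix] = []
    consensi = cfg.sim.motif_consensus
    if isinstance(consensi, str):
        consensi = {"all": consensi}
    seen = set()
    for i, (owner, consensus) in enumerate(sorted(consensi.items()), 1):
        if consensus in seen:
            continue
        seen.add(consensus)
        pwms.append(motifs.pwm_from_iupac(consensus, f"PLANTED{i}", f"planted_{owner}"))
    for i in range(cfg.n_decoy_motifs):
        width = int(rng.integers(8, 13))
        counts = rng.dirichlet(np.ones(4) * 0.5, size=width).T * 100
        pwms.append(motifs.PositionWeightMatrix(f"DECOY{i + 1}", f"decoy_{i + 1}", counts))
    return pwms


def stage_qc(cfg: RunConfig) -> dict:
    sizes = _chrom_sizes(cfg)
    out = cfg.outdir / "qc"
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for tissue, mark, rep in _libraries(cfg):
        chip = _load_library(cfg, tissue, mark, rep)
        input_ = _load_library(cfg, tissue, "input", 1)
        report = readqc.qc_panel(chip, input_, sizes, cfg.thresholds,
                                 max_shift=cfg.xcor_max_shift,
                                 jsd_bin_size=cfg.jsd_bin_size)
        row = {"tissue": tissue, "mark": mark, "replicate": rep}
        row.update({k: round(v, 4) for k, v in report.metrics.items()})
        row.update({f"{k}_pass": v for k, v in report.verdicts.items()})
        rows.append(row)
    table = pd.DataFrame(rows)
    io.write_table(table, out / "qc_report.tsv")
    io.write_json(table.to_dict(orient="records"), out / "qc_report.json")
    return _update_manifest(cfg, "qc", ["sim"], [out / "qc_report.tsv", out / "qc_report.json"])


def _call_one(cfg: RunConfig, tissue: str, mark: str, rep: int, sizes) -> list[peaks.Peak]:
    mark_cfg = cfg.marks[mark]
    chip, _ = readqc.filter_alignments(_load_library(cfg, tissue, mark, rep))
    chip = readqc.remove_duplicates(chip)
    input_, _ = readqc.filter_alignments(_load_library(cfg, tissue, "input", 1))
    input_ = readqc.remove_duplicates(input_)
    ws = peaks.window_scores(chip, input_, sizes, mark_cfg)
    if mark_cfg.peak_type == "broad":
        return peaks.call_islands(ws, mark_cfg)
    return peaks.call_narrow(ws, mark_cfg)


def _peak_path(cfg: RunConfig, tissue: str, mark: str, rep: int) -> Path:
    ext = "broadPeak" if cfg.marks[mark].peak_type == "broad" else "narrowPeak"
    return cfg.outdir / "peaks" / f"{tissue}.{mark}.rep{rep}.{ext}"


def stage_callpeaks(cfg: RunConfig) -> dict:
    sizes = _chrom_sizes(cfg)
    out = cfg.outdir / "peaks"
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for tissue, mark, rep in _libraries(cfg):
        called = _call_one(cfg, tissue, mark, rep, sizes)
        path = _peak_path(cfg, tissue, mark, rep)
        if cfg.marks[mark].peak_type == "broad":
            io.write_broadpeak(called, path)
        else:
            io.write_narrowpeak(called, path)
        written.append(path)
    return _update_manifest(cfg, "callpeaks", ["sim"], written)


def _read_peaks(cfg: RunConfig, tissue: str, mark: str, rep: int) -> list[peaks.Peak]:
    path = _require(_peak_path(cfg, tissue, mark, rep), "callpeaks")
    reader = io.read_broadpeak if cfg.marks[mark].peak_type == "broad" else io.read_narrowpeak
    called = reader(path)
    for p in called:
        p.significant = p.q_value <= cfg.marks[mark].fdr_threshold
    return called


def stage_combine(cfg: RunConfig) -> dict:
    sizes = _chrom_sizes(cfg)
    out = cfg.outdir / "consensus"
    out.mkdir(parents=True, exist_ok=True)
    written = []
    rows = []
    for tissue in cfg.sim.tissues:
        for mark in cfg.sim.marks:
            r1 = _read_peaks(cfg, tissue, mark, 1)
            r2 = _read_peaks(cfg, tissue, mark, 2)
            cps = peaks.combine_replicates(r1, r2, cfg.marks[mark], tissue=tissue)
            path = out / f"{tissue}.{mark}.consensus.bed"
            io.write_consensus_bed(cps, path)
            written.append(path)
            rows.append({
                "tissue": tissue, "mark": mark,
                "combined_peaks": len(cps),
                "rep1_significant": len(peaks.significant(r1)),
                "rep2_significant": len(peaks.significant(r2)),
                "percent_genome_covered": round(
                    peaks.genome_covered_percent(cps, sizes), 4)})
    summary = pd.DataFrame(rows)
    io.write_table(summary, out / "consensus_summary.tsv")
    written.append(out / "consensus_summary.tsv")
    return _update_manifest(cfg, "combine", ["peaks"], written)


def _read_consensus(cfg: RunConfig, tissue: str, mark: str) -> dict[str, np.ndarray]:
    path = _require(cfg.outdir / "consensus" / f"{tissue}.{mark}.consensus.bed", "combine")
    ivs: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.split("\t")
            ivs.setdefault(fields[0], []).append((int(fields[1]), int(fields[2])))
    return {c: np.asarray(v, dtype=np.int64) for c, v in ivs.items()}


def stage_compare(cfg: RunConfig) -> dict:
    out = cfg.outdir / "compare"
    out.mkdir(parents=True, exist_ok=True)
    written = []

    # replicate-level Jaccard per mark (significant per-replicate calls)
    for mark in cfg.sim.marks:
        labelled = {}
        for tissue in cfg.sim.tissues:
            for rep in range(1, cfg.replicates + 1):
                sig = peaks.significant(_read_peaks(cfg, tissue, mark, rep))
                if sig:
                    labelled[f"{tissue}.rep{rep}"] = tissuecomp._normalize(sig)
        if len(labelled) >= 2:
            mat, best = tissuecomp.jaccard_matrix(labelled)
            path = out / f"jaccard.{mark}.tsv"
            mat.round(4).to_csv(path, sep="\t")
            written.append(path)

    # unique/shared consensus peaks per mark
    spec_rows = []
    for mark in cfg.sim.marks:
        per_tissue = {t: _read_consensus(cfg, t, mark) for t in cfg.sim.tissues}
        table, uniques = tissuecomp.unique_peaks(mark, per_tissue)
        spec_rows.append(table.table)
    spec = pd.concat(spec_rows, ignore_index=True)
    io.write_table(spec, out / "unique_peaks.tsv")
    written.append(out / "unique_peaks.tsv")

    # active enhancers and tissue-specific enhancers
    me1 = {t: _read_consensus(cfg, t, "H3K4me1") for t in cfg.sim.tissues}
    ac = {t: _read_consensus(cfg, t, "H3K27ac") for t in cfg.sim.tissues}
    enhancers = {t: tissuecomp.active_enhancers(me1[t], ac[t]) for t in cfg.sim.tissues}
    specific = tissuecomp.tissue_specific_enhancers(enhancers, me1, ac)
    for t in cfg.sim.tissues:
        for label, data in (("active_enhancers", enhancers[t]),
                            ("specific_enhancers", specific[t])):
            path = out / f"{t}.{label}.bed"
            with open(path, "w") as fh:
                for chrom in sorted(data):
                    for s, e in data[chrom]:
                        fh.write(f"{chrom}\t{s}\t{e}\n")
            written.append(path)
    return _update_manifest(cfg, "compare", ["peaks", "consensus"], written)


def stage_profile(cfg: RunConfig) -> dict:
    sizes = _chrom_sizes(cfg)
    genes = io.read_genes_bed(_require(cfg.outdir / "sim" / "genes.bed", "simulate"))
    out = cfg.outdir / "profiles"
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for tissue in cfg.sim.tissues:
        input_ = readqc.remove_duplicates(
            readqc.filter_alignments(_load_library(cfg, tissue, "input", 1))[0])
        for mark in cfg.sim.marks:
            reps = [readqc.remove_duplicates(readqc.filter_alignments(
                _load_library(cfg, tissue, mark, rep))[0])
                for rep in range(1, cfg.replicates + 1)]
            track = profiles.enrichment_track(
                reps[0], reps[1], input_, sizes,
                bin_size=cfg.track_bin_size,
                fragment_size=cfg.marks[mark].fragment_size)
            io.write_bedgraph(track, out / f"{tissue}.{mark}.bedGraph")
            written.append(out / f"{tissue}.{mark}.bedGraph")
            mg = profiles.metagene(track, genes, cfg.flank_bp, cfg.body_bins)
            prof = pd.DataFrame({"column": mg.matrix.columns,
                                 "mean_enrichment": mg.mean_profile})
            io.write_table(prof, out / f"{tissue}.{mark}.metagene.tsv")
            written.append(out / f"{tissue}.{mark}.metagene.tsv")
    return _update_manifest(cfg, "profile", ["sim"], written)


def stage_motifs(cfg: RunConfig) -> dict:
    out = cfg.outdir / "motifs"
    out.mkdir(parents=True, exist_ok=True)
    genome = io.read_fasta(_require(cfg.outdir / "sim" / "genome.fa", "simulate"))
    pwms = motifs.read_jaspar(_require(cfg.outdir / "sim" / "motifs.jaspar", "simulate"))
    rng = np.random.default_rng(derive_seed(cfg.seed, "motif-bg"))
    me1 = {t: _read_consensus(cfg, t, "H3K4me1") for t in cfg.sim.tissues}
    ac = {t: _read_consensus(cfg, t, "H3K27ac") for t in cfg.sim.tissues}
    enhancers = {t: tissuecomp.active_enhancers(me1[t], ac[t]) for t in cfg.sim.tissues}
    specific = tissuecomp.tissue_specific_enhancers(enhancers, me1, ac)
    per_tissue = {}
    written = []
    for tissue in cfg.sim.tissues:
        fg = motifs.extract_sequences(genome, specific[tissue], prefix=tissue)
        if not fg:
            logger.warning("no tissue-specific enhancers for %s; skipping", tissue)
            continue
        bg = motifs.shuffled_background(fg, rng)
        results = motifs.enrich(fg, bg, pwms)
        per_tissue[tissue] = results
        path = out / f"{tissue}.motif_enrichment.tsv"
        io.write_table(motifs.results_frame(results), path)
        written.append(path)
    if len(per_tissue) >= 2:
        unique = motifs.uniquely_detected(per_tissue, alpha=cfg.motif_alpha)
        io.write_json(unique, out / "uniquely_detected.json")
        written.append(out / "uniquely_detected.json")
    return _update_manifest(cfg, "motifs", ["sim", "consensus"], written)


_STAGE_FUNCS: dict[str, Callable[[RunConfig], dict]] = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "callpeaks": stage_callpeaks,
    "combine": stage_combine,
    "compare": stage_compare,
    "profile": stage_profile,
    "motifs": stage_motifs,
}


def run_stage(name: str, cfg: RunConfig) -> dict:
    """Run one named stage (or 'all') and return its manifest entry."""
    if name == "all":
        entry = {}
        for stage in STAGES:
            entry = _STAGE_FUNCS[stage](cfg)
        return entry
    if name not in _STAGE_FUNCS:
        raise DependencyError(f"unknown stage {name!r}; choose from {STAGES + ('all',)}")
    return _STAGE_FUNCS[name](cfg)
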