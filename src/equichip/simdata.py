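"""Synthetic multi-tissue histone ChIP-seq data with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: 50 bp single-end reads from ~200 bp fragments, two biological
replicates per tissue, four histone marks plus an input library per tissue,
PCR-style duplication, and enrichment at planted regulatory elements with a
controlled tissue-sharing structure (elements shared by all tissues versus
specific to one).  Tissue-specific elements are active enhancers (carrying
H3K4me1 and H3K27ac) with a transcription-factor motif consensus substituted
into the genome sequence.

A small fraction of reads is emitted as same-span plus/minus pairs
(``phantom_artifact_fraction``), emulating the mappability artifact that
produces the "phantom peak" at the read length in real strand
cross-correlation profiles; without it the RSC statistic has no phantom
peak to normalize against.

Everything is deterministic under ``SimConfig.seed``: per-library substreams
are derived by stable hashing of (tissue, mark, replicate), so adding a
library never perturbs the others.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, LookupError_, PlacementError
from .readqc import TagSet

DEFAULT_MARKS = ("H3K4me1", "H3K4me3", "H3K27ac", "H3K27me3")

#: marks carried by each planted element class
ELEMENT_CLASS_MARKS = {
    "enhancer": frozenset({"H3K4me1", "H3K27ac"}),
    "promoter": frozenset({"H3K4me3", "H3K27ac"}),
    "repressed": frozenset({"H3K27me3"}),
}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def derive_seed(master: int, *parts) -> int:
    """Stable sub-seed below 2**31 from a master seed and string parts."""
    text = ":".join([str(master), *map(str, parts)])
    return int.from_bytes(hashlib.sha256(text.encode()).digest()[:4], "big") % (2**31)


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the simulator.

    Defaults are the QC-scenario conditions: 200k reads per library,
    duplication rate 0.1, 20-fold enrichment, 50 bp reads from
    Normal(200, 20) fragments, on a 10 Mb two-chromosome genome carrying
    60 shared and 20 per-tissue-specific elements of 500 bp.
    """

    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 6_000_000, "chr2": 4_000_000})
    n_tissues: int = 3
    marks: Sequence[str] = DEFAULT_MARKS
    read_length: int = 50
    fragment_mean: int = 200
    fragment_sd: float = 20.0
    duplication_rate: float = 0.1
    enrichment_fold: float = 20.0
    background_rate: float | None = None  # reads/bp; overrides reads_per_library
    reads_per_library: int = 200_000
    n_shared_elements: int = 60
    n_specific_elements_per_tissue: int = 20
    element_size: int = 500
    broad_element_scale: int = 4     # repressed (H3K27me3) elements are this much wider
    element_spacing: int = 1500      # minimum gap between planted elements
    motif_consensus: str | Mapping[str, str] = "DAAAYA"
    replicate_sigma: float = 0.25    # lognormal per-element replicate jitter
    phantom_artifact_fraction: float = 0.002
    decoy_fraction: float = 0.0      # extra low-MAPQ tags (MAPQ uniform in [0, 30))
    n_genes: int = 150
    gene_length_range: tuple[int, int] = (2_000, 8_000)
    seed: int = 0

    def __post_init__(self):
        if not self.chrom_lengths:
            raise ConfigurationError("chrom_lengths must be non-empty")
        if any(length <= 0 for length in self.chrom_lengths.values()):
            raise ConfigurationError("zero-length chromosome")
        if self.read_length > self.fragment_mean:
            raise ConfigurationError("read_length must not exceed fragment_mean")
        if not 0 <= self.duplication_rate < 1:
            raise ConfigurationError("duplication_rate must be in [0, 1)")
        if self.enrichment_fold < 1:
            raise ConfigurationError("enrichment_fold must be >= 1")

    @property
    def tissues(self) -> tuple[str, ...]:
        return tuple(f"tissue_{i + 1}" for i in range(self.n_tissues))

    @property
    def genome_length(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    def n_reads(self) -> int:
        if self.background_rate is not None:
            return int(round(self.background_rate * self.genome_length))
        return self.reads_per_library

    def motif_for(self, tissue: str) -> str | None:
        if isinstance(self.motif_consensus, str):
            return self.motif_consensus or None
        return self.motif_consensus.get(tissue)


@dataclass(frozen=True)
class Element:
    chrom: str
    start: int
    end: int
    element_class: str          # "shared" or "tissue_specific"
    owner_tissue: str | None    # None means carried by all tissues
    marks_present: frozenset[str]

    def carried_by(self, tissue: str) -> bool:
        return self.owner_tissue is None or self.owner_tissue == tissue


@dataclass
class TruthSet:
    """Simulator ground truth: planted elements and motif positions."""

    elements: list[Element]
    motif_sites: list[tuple[str, int, str]]  # (chrom, position, strand)

    def elements_for(self, tissue: str, mark: str) -> list[Element]:
        return [e for e in self.elements if mark in e.marks_present and e.carried_by(tissue)]

    def intervals(self, tissue: str, mark: str) -> dict[str, np.ndarray]:
        out: dict[str, list] = {}
        for e in self.elements_for(tissue, mark):
            out.setdefault(e.chrom, []).append((e.start, e.end))
        return {c: np.asarray(v, dtype=np.int64) for c, v in out.items()}

    def specific_enhancers(self, tissue: str) -> dict[str, np.ndarray]:
        out: dict[str, list] = {}
        for e in self.elements:
            if (e.element_class == "tissue_specific" and e.owner_tissue == tissue
                    and {"H3K4me1", "H3K27ac"} <= e.marks_present):
                out.setdefault(e.chrom, []).append((e.start, e.end))
        return {c: np.asarray(v, dtype=np.int64) for c, v in out.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"chrom": e.chrom, "start": e.start, "end": e.end,
             "element_class": e.element_class,
             "owner_tissue": e.owner_tissue or "all",
             "marks_present": ",".join(sorted(e.marks_present))}
            for e in self.elements
        ])


@dataclass
class GeneModel:
    chrom: str
    start: int
    end: int
    name: str
    strand: str


Genome = dict[str, str]


# ---------------------------------------------------------------------------
# genome, genes, elements
# ---------------------------------------------------------------------------

def make_genome(config: SimConfig) -> Genome:
    """Uniform-composition random sequences, one per chromosome."""
    rng = np.random.default_rng(derive_seed(config.seed, "genome"))
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = {}
    for chrom, length in config.chrom_lengths.items():
        codes = rng.integers(0, 4, size=int(length))
        genome[chrom] = bases[codes].tobytes().decode("ascii")
    return genome


def make_genes(config: SimConfig) -> list[GeneModel]:
    """Random non-overlapping gene models (for metagene profiling)."""
    rng = np.random.default_rng(derive_seed(config.seed, "genes"))
    lo, hi = config.gene_length_range
    genes: list[GeneModel] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in config.chrom_lengths}
    chroms = list(config.chrom_lengths)
    weights = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    attempts = 0
    while len(genes) < config.n_genes and attempts < config.n_genes * 200:
        attempts += 1
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        length = int(rng.integers(lo, hi + 1))
        limit = config.chrom_lengths[chrom] - length
        if limit <= 0:
            continue
        start = int(rng.integers(0, limit))
        end = start + length
        if any(start < e and s < end for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(chrom, start, end, f"gene_{len(genes) + 1}", strand))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def _substitute(seq: str, pos: int, motif: str) -> str:
    return seq[:pos] + motif + seq[pos + len(motif):]


def _concretize_iupac(consensus: str, rng: np.random.Generator) -> str:
    try:
        choices = [IUPAC[b] for b in consensus.upper()]
    except KeyError as exc:
        raise ConfigurationError(f"invalid IUPAC base in motif consensus: {exc}") from exc
    return "".join(c[rng.integers(0, len(c))] for c in choices)


def plant_elements(
    config: SimConfig,
    genome: Genome,
    genes: Sequence[GeneModel] | None = None,
) -> tuple[TruthSet, Genome]:
    """Place non-overlapping regulatory elements and plant motifs.

    Shared elements rotate through enhancer / promoter / repressed classes
    (so every mark receives signal); tissue-specific elements are active
    enhancers carrying H3K4me1 + H3K27ac with the configured motif consensus
    substituted into the sequence at the element midpoint.  When gene models
    are supplied, shared promoter-class elements are centered on gene TSSs.
    Returns the truth set and the (possibly motif-edited) genome.
    """
    rng = np.random.default_rng(derive_seed(config.seed, "elements"))
    chroms = list(config.chrom_lengths)
    weights = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    genome = dict(genome)

    def place(width: int, at: tuple[str, int] | None = None) -> tuple[str, int, int]:
        pad = config.element_spacing
        for _ in range(2000):
            if at is not None:
                chrom, center = at
                start = max(0, center - width // 2)
            else:
                chrom = chroms[rng.choice(len(chroms), p=weights)]
                limit = config.chrom_lengths[chrom] - width
                if limit <= 0:
                    raise PlacementError(f"element of {width} bp does not fit in {chrom}")
                start = int(rng.integers(0, limit))
            end = start + width
            if end > config.chrom_lengths[chrom]:
                if at is not None:
                    at = None
                    continue
                continue
            if any(start - pad < e and s < end + pad for s, e in occupied[chrom]):
                if at is not None:
                    at = None  # TSS slot collided; fall back to random placement
                continue
            occupied[chrom].append((start, end))
            return chrom, start, end
        raise PlacementError(
            "could not place elements without overlap; genome too small for "
            f"{config.n_shared_elements} shared + "
            f"{config.n_specific_elements_per_tissue}/tissue elements")

    elements: list[Element] = []
    motif_sites: list[tuple[str, int, str]] = []
    classes = ("enhancer", "promoter", "repressed")
    tss_pool = [(g.chrom, g.start if g.strand == "+" else g.end) for g in (genes or [])]
    rng.shuffle(tss_pool)

    for i in range(config.n_shared_elements):
        cls = classes[i % len(classes)]
        width = config.element_size * (config.broad_element_scale if cls == "repressed" else 1)
        at = tss_pool.pop() if cls == "promoter" and tss_pool else None
        chrom, start, end = place(width, at)
        elements.append(Element(chrom, start, end, "shared", None, ELEMENT_CLASS_MARKS[cls]))

    for tissue in config.tissues:
        motif = config.motif_for(tissue)
        for _ in range(config.n_specific_elements_per_tissue):
            chrom, start, end = place(config.element_size)
            elements.append(Element(chrom, start, end, "tissue_specific", tissue,
                                    ELEMENT_CLASS_MARKS["enhancer"]))
            if motif:
                concrete = _concretize_iupac(motif, rng)
                pos = (start + end) // 2 - len(concrete) // 2
                strand = "+" if rng.random() < 0.5 else "-"
                planted = concrete if strand == "+" else _revcomp(concrete)
                genome[chrom] = _substitute(genome[chrom], pos, planted)
                motif_sites.append((chrom, pos, strand))

    elements.sort(key=lambda e: (e.chrom, e.start))
    return TruthSet(elements, motif_sites), genome


_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _global_to_chrom(config: SimConfig, gpos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    chroms = list(config.chrom_lengths)
    bounds = np.cumsum([config.chrom_lengths[c] for c in chroms])
    idx = np.searchsorted(bounds, gpos, side="right")
    offset = gpos - np.concatenate(([0], bounds[:-1]))[idx]
    return idx, offset


def simulate_library(
    truth: TruthSet,
    tissue: str,
    mark: str,
    replicate: int,
    config: SimConfig,
) -> TagSet:
    """Simulate one aligned single-end library as a :class:`TagSet`.

    Fragment lengths ~ Normal(fragment_mean, fragment_sd) truncated at the
    read length.  Fragment starts are uniform over the genome, with rate
    elevated ``enrichment_fold``-fold inside elements that carry ``mark``
    and belong to ``tissue`` (shared or owned); ``mark="input"`` has no
    elevation.  Each fragment emits one read from a uniformly chosen strand:
    plus reads start at the fragment start, minus reads end at the fragment
    end.  A ``duplication_rate`` fraction of reads are exact copies of
    already-emitted reads.  Per-element rates are jittered by an independent
    lognormal factor per replicate.  All tags carry MAPQ 60; an optional
    ``decoy_fraction`` appends extra tags with MAPQ drawn uniform in [0, 30).
    """
    if mark != "input" and mark not in config.marks:
        raise LookupError_(f"unknown mark {mark!r}")
    if tissue not in config.tissues:
        raise LookupError_(f"unknown tissue {tissue!r}")
    rng = np.random.default_rng(derive_seed(config.seed, "library", tissue, mark, replicate))
    chroms = list(config.chrom_lengths)
    chrom_len = np.array([config.chrom_lengths[c] for c in chroms], dtype=np.int64)
    G = int(chrom_len.sum())
    rl = config.read_length

    if mark == "input":
        active: list[Element] = []
    else:
        active = [e for e in truth.elements
                  if mark in e.marks_present and e.carried_by(tissue)]

    n_total = config.n_reads()
    n_phantom_pairs = int(round(config.phantom_artifact_fraction * n_total / 2))
    n_body = n_total - 2 * n_phantom_pairs
    n_dup = int(round(config.duplication_rate * n_body))
    n_fresh = n_body - n_dup

    # mixture weights: background mass G, plus per-element excess mass
    jitter = np.exp(rng.normal(0.0, config.replicate_sigma, size=len(active)))
    elem_len = np.array([e.end - e.start for e in active], dtype=float)
    excess = elem_len * np.maximum(config.enrichment_fold * jitter - 1.0, 0.0)
    masses = np.concatenate(([float(G)], excess))
    probs = masses / masses.sum()

    comp = rng.choice(len(masses), size=n_fresh, p=probs)
    frag_len = np.maximum(
        np.rint(rng.normal(config.fragment_mean, config.fragment_sd, size=n_fresh)),
        rl).astype(np.int64)

    starts = np.empty(n_fresh, dtype=np.int64)
    chrom_idx = np.empty(n_fresh, dtype=np.int64)
    bg = comp == 0
    gpos = rng.integers(0, G, size=int(bg.sum()))
    chrom_idx[bg], starts[bg] = _global_to_chrom(config, gpos)
    if active:
        fg = ~bg
        eidx = comp[fg] - 1
        estart = np.array([e.start for e in active], dtype=np.int64)
        echrom = np.array([chroms.index(e.chrom) for e in active], dtype=np.int64)
        offs = (rng.random(int(fg.sum())) * elem_len[eidx]).astype(np.int64)
        starts[fg] = estart[eidx] + offs
        chrom_idx[fg] = echrom[eidx]
    # keep the whole fragment inside its chromosome
    starts = np.minimum(starts, chrom_len[chrom_idx] - frag_len)
    starts = np.maximum(starts, 0)
    frag_len = np.minimum(frag_len, chrom_len[chrom_idx] - starts)

    minus = rng.random(n_fresh) < 0.5
    tag_start = np.where(minus, starts + frag_len - rl, starts)
    tag_end = tag_start + rl
    strand = np.where(minus, "-", "+")

    if n_dup > 0:
        src = rng.integers(0, n_fresh, size=n_dup)
        tag_start = np.concatenate([tag_start, tag_start[src]])
        tag_end = np.concatenate([tag_end, tag_end[src]])
        strand = np.concatenate([strand, strand[src]])
        chrom_idx = np.concatenate([chrom_idx, chrom_idx[src]])

    if n_phantom_pairs > 0:
        gpos = rng.integers(0, G, size=n_phantom_pairs)
        pc, pp = _global_to_chrom(config, gpos)
        pp = np.minimum(pp, chrom_len[pc] - rl)
        tag_start = np.concatenate([tag_start, pp, pp])
        tag_end = np.concatenate([tag_end, pp + rl, pp + rl])
        strand = np.concatenate([strand, ["+"] * n_phantom_pairs, ["-"] * n_phantom_pairs])
        chrom_idx = np.concatenate([chrom_idx, pc, pc])

    mapq = np.full(len(tag_start), 60, dtype=np.int64)
    if config.decoy_fraction > 0:
        n_decoy = int(round(config.decoy_fraction * n_total))
        gpos = rng.integers(0, G, size=n_decoy)
        dc, dp = _global_to_chrom(config, gpos)
        dp = np.minimum(dp, chrom_len[dc] - rl)
        tag_start = np.concatenate([tag_start, dp])
        tag_end = np.concatenate([tag_end, dp + rl])
        strand = np.concatenate([strand, np.where(rng.random(n_decoy) < 0.5, "-", "+")])
        chrom_idx = np.concatenate([chrom_idx, dc])
        mapq = np.concatenate([mapq, rng.integers(0, 30, size=n_decoy)])

    chrom_names = np.array(chroms, dtype=object)[chrom_idx]
    return TagSet.from_arrays(chrom_names, tag_start, tag_end, strand, mapq)


def simulate_study(config: SimConfig, replicates: int = 2,
                   marks: Sequence[str] | None = None):
    """Simulate genome, truth and every tissue x (marks + input) x replicate library.

    Yields nothing lazily by design: returns (genome, genes, truth, libraries)
    where ``libraries[(tissue, mark, rep)]`` is a :class:`TagSet`; input
    libraries use ``rep = 1`` only.
    """
    genome = make_genome(config)
    genes = make_genes(config)
    truth, genome = plant_elements(config, genome, genes)
    marks = list(marks if marks is not None else config.marks)
    libraries: dict[tuple[str, str, int], TagSet] = {}
    for tissue in config.tissues:
        for mark in marks:
            for rep in range(1, replicates + 1):
                libraries[(tissue, mark, rep)] = simulate_library(truth, tissue, mark, rep, config)
        libraries[(tissue, "input", 1)] = simulate_library(truth, tissue, "input", 1, config)
    return genome, genes, truth, libraries


def with_overrides(config: SimConfig, **kwargs) -> SimConfig:
    return replace(config, **kwargs)
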