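"""Per-replicate enrichment detection and replicate consensus combining.

Two simplified detectors are provided: a narrow caller (merge adjacent
significant fixed-size windows, MACS2-like in spirit) and a broad island
caller (maximal runs of eligible windows allowing bounded gaps, SICER-like).
Both score 200 bp windows against a Poisson background whose rate is the
larger of the input-derived local rate (scaled to ChIP depth) and the global
ChIP rate over the effective genome.

Replicate combining follows the rule used for the published peak sets:
regions of enrichment overlapping in both biological replicates are merged
into one consensus peak whenever at least one contributing call passes the
mark-specific FDR threshold.  "Regions of enrichment" are relaxed-threshold
calls (default q <= 0.5), which is why a consensus set can contain more
peaks than the smaller replicate's significant call count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import intervals
from .errors import ValidationError
from .readqc import TagSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MarkConfig:
    """Per-mark detector parameters (defaults follow the study's settings)."""

    mark: str
    peak_type: str = "narrow"            # "narrow" | "broad"
    fdr_threshold: float = 0.05
    window_size: int = 200
    gap_size: int = 4                    # windows, broad caller only
    genome_fraction: float | None = None  # effective-genome fraction (broad: 0.63)
    effective_genome_size: int = 2_409_143_234  # real-genome constant, reporting only
    fragment_size: int = 200
    relaxed_q: float = 0.5               # "region of enrichment" detection threshold
    island_window_p: float = 0.2         # broad caller per-window eligibility

    def __post_init__(self):
        if not 0 < self.fdr_threshold < 1:
            raise ValidationError("fdr_threshold must be in (0, 1)")
        if self.window_size <= 0:
            raise ValidationError("window_size must be positive")


def default_mark_configs() -> dict[str, MarkConfig]:
    return {
        "H3K4me1": MarkConfig("H3K4me1", "narrow", 0.05),
        "H3K4me3": MarkConfig("H3K4me3", "narrow", 0.01),
        "H3K27ac": MarkConfig("H3K27ac", "narrow", 0.01),
        "H3K27me3": MarkConfig("H3K27me3", "broad", 0.1, genome_fraction=0.63),
    }


@dataclass
class Peak:
    """One enrichment call.  p/q are stored as raw probabilities; the
    narrowPeak/broadPeak writers emit them on the -log10 scale."""

    chrom: str
    start: int
    end: int
    name: str
    score: int
    strand: str
    signal: float
    p_value: float
    q_value: float
    summit: int = -1          # offset from start; -1 for broad peaks
    significant: bool = False

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class WindowScores:
    """Per-window counts and Poisson p-values over a tiled genome."""

    window_size: int
    chrom_lengths: dict[str, int]
    counts: dict[str, np.ndarray]
    lam: dict[str, np.ndarray]
    p: dict[str, np.ndarray]

    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    def flat(self, attr: str) -> np.ndarray:
        d = getattr(self, attr)
        return np.concatenate([d[c] for c in self.chroms()])

    def unflatten(self, values: np.ndarray, attr: str = "counts") -> dict[str, np.ndarray]:
        out, i = {}, 0
        for c in self.chroms():
            n = len(getattr(self, attr)[c])
            out[c] = values[i:i + n]
            i += n
        return out


def _window_counts(tags: TagSet, chrom_lengths: Mapping[str, int],
                   window_size: int, fragment_size: int) -> dict[str, np.ndarray]:
    """Count tags per window at their strand-aware fragment midpoints.

    Each tag is extended to fragment_size in its 3' direction and counted
    once, at the extended-fragment midpoint (plus: 5' + fs/2; minus:
    5' - fs/2) — counting whole extended spans would double-count tags that
    straddle window boundaries.
    """
    shift = fragment_size // 2
    out = {}
    for chrom, length in chrom_lengths.items():
        n_win = -(-int(length) // window_size)
        sub = tags.df[tags.df["chrom"] == chrom]
        minus = sub["strand"].to_numpy() == "-"
        pos = np.where(minus, sub["end"].to_numpy() - shift, sub["start"].to_numpy() + shift)
        pos = np.clip(pos, 0, length - 1)
        out[chrom] = np.bincount(pos // window_size, minlength=n_win)
    return out


def window_scores(
    chip: TagSet,
    input_: TagSet | None,
    chrom_lengths: Mapping[str, int],
    config: MarkConfig,
) -> WindowScores:
    """Poisson-score fixed-size windows of ChIP counts against the input.

    The expected count per window is the larger of the input's local rate
    scaled to ChIP depth and the global ChIP rate over the effective genome
    (genome_fraction x genome length; fraction 1 when unset).  The p-value
    is the upper Poisson tail P(X >= observed).
    """
    chrom_lengths = {c: int(x) for c, x in chrom_lengths.items()}
    counts = _window_counts(chip, chrom_lengths, config.window_size, config.fragment_size)
    n_chip = len(chip)
    fraction = config.genome_fraction if config.genome_fraction else 1.0
    effective = fraction * sum(chrom_lengths.values())
    lam_global = n_chip * config.window_size / effective

    if input_ is None or len(input_) == 0:
        if input_ is not None:
            logger.warning("empty input library; falling back to the global ChIP rate")
        lam = {c: np.full_like(v, lam_global, dtype=float) for c, v in counts.items()}
    else:
        in_counts = _window_counts(input_, chrom_lengths, config.window_size,
                                   config.fragment_size)
        depth_ratio = n_chip / len(input_)
        lam = {c: np.maximum(in_counts[c] * depth_ratio, lam_global) for c in counts}

    p = {c: stats.poisson.sf(counts[c] - 1, lam[c]) for c in counts}
    return WindowScores(config.window_size, chrom_lengths, counts, lam, p)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end) runs of True."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[s]), int(idx[e]) + 1) for s, e in zip(starts, ends)]


def call_narrow(ws: WindowScores, config: MarkConfig) -> list[Peak]:
    """Merge adjacent relaxed-significant windows into narrow peaks.

    Windows with BH q <= relaxed_q form candidate peaks (adjacent windows
    merge); the peak q is the minimum member q, the summit is the midpoint
    of the highest-count member window, and peaks with q <= fdr_threshold
    are flagged significant.
    """
    q_flat = bh_adjust(ws.flat("p"))
    q = ws.unflatten(q_flat)
    peaks: list[Peak] = []
    for chrom in ws.chroms():
        eligible = q[chrom] <= config.relaxed_q
        for w0, w1 in _runs(eligible):
            members = slice(w0, w1)
            counts = ws.counts[chrom][members]
            best = int(np.argmax(counts)) + w0
            start = w0 * ws.window_size
            end = min(w1 * ws.window_size, ws.chrom_lengths[chrom])
            q_min = float(q[chrom][members].min())
            p_min = float(ws.p[chrom][members].min())
            with np.errstate(divide="ignore", invalid="ignore"):
                fold = float(np.max(ws.counts[chrom][members] /
                                    np.maximum(ws.lam[chrom][members], 1e-12)))
            summit = best * ws.window_size + ws.window_size // 2 - start
            peaks.append(Peak(
                chrom, start, end, f"{config.mark}_{chrom}_{len(peaks) + 1}",
                score=int(min(1000, round(10 * fold))), strand=".", signal=fold,
                p_value=p_min, q_value=q_min, summit=min(summit, end - start - 1),
                significant=q_min <= config.fdr_threshold))
    return peaks


def call_islands(ws: WindowScores, config: MarkConfig) -> list[Peak]:
    """SICER-style broad islands from eligible windows with bounded gaps.

    Windows with Poisson p <= island_window_p are eligible; islands are
    maximal runs of eligible windows allowing internal gaps of at most
    gap_size ineligible windows.  The island score sums the eligible
    members' truncation-corrected -log p; the island p-value refers that sum
    to a Gamma(k, 1) tail (exact under the null for continuous p), and BH
    q-values are assigned across islands.  Islands with q <= relaxed_q are
    returned; q <= fdr_threshold flags significance.
    """
    candidates: list[tuple[str, int, int, list[int]]] = []
    for chrom in ws.chroms():
        eligible_idx = np.flatnonzero(ws.p[chrom] <= config.island_window_p)
        if eligible_idx.size == 0:
            continue
        start = prev = int(eligible_idx[0])
        members = [start]
        for w in eligible_idx[1:]:
            w = int(w)
            if w - prev - 1 <= config.gap_size:
                members.append(w)
            else:
                candidates.append((chrom, start, prev + 1, members))
                start, members = w, [w]
            prev = w
        candidates.append((chrom, start, prev + 1, members))

    if not candidates:
        return []

    island_p = []
    scores = []
    for chrom, w0, w1, members in candidates:
        pw = ws.p[chrom][members]
        s = float(np.sum(-np.log(np.maximum(pw, 1e-300) / config.island_window_p)))
        scores.append(s)
        island_p.append(float(stats.gamma.sf(s, a=len(members))))
    q = bh_adjust(island_p)

    peaks: list[Peak] = []
    for (chrom, w0, w1, members), s, p_val, q_val in zip(candidates, scores, island_p, q):
        if q_val > config.relaxed_q:
            continue
        start = w0 * ws.window_size
        end = min(w1 * ws.window_size, ws.chrom_lengths[chrom])
        with np.errstate(divide="ignore", invalid="ignore"):
            fold = float(np.max(ws.counts[chrom][members] /
                                np.maximum(ws.lam[chrom][members], 1e-12)))
        peaks.append(Peak(
            chrom, start, end, f"{config.mark}_{chrom}_island_{len(peaks) + 1}",
            score=int(min(1000, round(s))), strand=".", signal=fold,
            p_value=p_val, q_value=float(q_val), summit=-1,
            significant=q_val <= config.fdr_threshold))
    return peaks


# ---------------------------------------------------------------------------
# replicate consensus
# ---------------------------------------------------------------------------

@dataclass
class ConsensusPeak:
    chrom: str
    start: int
    end: int
    name: str
    q_value: float                     # best member q
    members_rep1: list[str] = field(default_factory=list)
    members_rep2: list[str] = field(default_factory=list)


@dataclass
class ConsensusPeakSet:
    tissue: str
    mark: str
    peaks: list[ConsensusPeak]

    def intervals(self) -> dict[str, np.ndarray]:
        out: dict[str, list] = {}
        for p in self.peaks:
            out.setdefault(p.chrom, []).append((p.start, p.end))
        return {c: np.asarray(v, dtype=np.int64) for c, v in out.items()}

    def __len__(self) -> int:
        return len(self.peaks)


def combine_replicates(
    peaks_rep1: Sequence[Peak],
    peaks_rep2: Sequence[Peak],
    config: MarkConfig,
    tissue: str = "",
) -> ConsensusPeakSet:
    """Combine two replicates' relaxed calls into consensus peaks.

    Builds the >=1 bp overlap graph between the two replicates' intervals;
    every connected component containing at least one interval from EACH
    replicate and at least one member with q <= fdr_threshold emits one
    consensus peak spanning the union of its members.  Symmetric in the two
    replicates.
    """
    chroms1 = {p.chrom for p in peaks_rep1}
    chroms2 = {p.chrom for p in peaks_rep2}
    if chroms1 and chroms2 and not (chroms1 & chroms2):
        raise ValidationError("replicate peak sets share no chromosome names")

    rows = [(p.chrom, p.start, p.end, 1, p.name, p.q_value) for p in peaks_rep1]
    rows += [(p.chrom, p.start, p.end, 2, p.name, p.q_value) for p in peaks_rep2]
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3]))

    consensus: list[ConsensusPeak] = []

    def flush(chrom, start, end, members):
        reps = {m[0] for m in members}
        best_q = min(m[2] for m in members)
        if reps == {1, 2} and best_q <= config.fdr_threshold:
            consensus.append(ConsensusPeak(
                chrom, start, end, f"{config.mark}_consensus_{len(consensus) + 1}",
                best_q,
                [m[1] for m in members if m[0] == 1],
                [m[1] for m in members if m[0] == 2]))

    cur_chrom, cur_start, cur_end, members = None, 0, 0, []
    for chrom, start, end, rep, name, q in rows:
        if cur_chrom == chrom and start < cur_end:
            cur_end = max(cur_end, end)
            members.append((rep, name, q))
        else:
            if members:
                flush(cur_chrom, cur_start, cur_end, members)
            cur_chrom, cur_start, cur_end = chrom, start, end
            members = [(rep, name, q)]
    if members:
        flush(cur_chrom, cur_start, cur_end, members)
    return ConsensusPeakSet(tissue, config.mark, consensus)


def genome_covered_percent(
    peaks: Sequence[Peak] | ConsensusPeakSet | Mapping[str, np.ndarray],
    chrom_lengths: Mapping[str, int],
) -> float:
    """Percent of the genome covered by the union of the peaks."""
    if isinstance(peaks, ConsensusPeakSet):
        ivs = peaks.intervals()
    elif isinstance(peaks, Mapping):
        ivs = {c: intervals.as_array(a) for c, a in peaks.items()}
    else:
        tmp: dict[str, list] = {}
        for p in peaks:
            tmp.setdefault(p.chrom, []).append((p.start, p.end))
        ivs = {c: intervals.as_array(v) for c, v in tmp.items()}
    total = sum(int(x) for x in chrom_lengths.values())
    for chrom, arr in ivs.items():
        if chrom not in chrom_lengths:
            raise ValidationError(f"peak on unknown chromosome {chrom!r}")
        if len(arr) and (arr[:, 0].min() < 0 or arr[:, 1].max() > chrom_lengths[chrom]):
            raise ValidationError(f"peak beyond the end of {chrom}")
    return 100.0 * intervals.total_length(ivs) / total


def significant(peaks: Sequence[Peak]) -> list[Peak]:
    return [p for p in peaks if p.significant]


def relax(config: MarkConfig, relaxed_q: float) -> MarkConfig:
    return replace(config, relaxed_q=relaxed_q)
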