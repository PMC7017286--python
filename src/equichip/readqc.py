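"""Alignment filtering and the six-metric ChIP quality-control panel.

A sequencing library is held as a :class:`TagSet` — a thin wrapper around a
pandas DataFrame with one row per aligned single-end read (tag).  The QC
panel computes:

* library complexity: NRF, PBC1, PBC2 (on filtered, *pre*-dedup tags);
* ChIP enrichment: NSC and RSC from the strand cross-correlation profile
  (on deduplicated tags) and the Jensen–Shannon distance (JSD) between the
  ChIP and input per-bin count distributions;
* strict pass/fail verdicts against the ENCODE/FAANG thresholds
  (NRF>0.5, PBC1>0.5, PBC2>1, NSC>1.05, RSC>0.8, JSD>0.05).

Coordinate conventions: 0-based half-open spans.  The 5' position of a
plus-strand tag is its ``start``; for a minus-strand tag we book-keep the 5'
end at the half-open ``end`` coordinate, so the plus/minus 5'-mode
separation of a fragment of length L is exactly L.  Duplicate keys and the
cross-correlation estimator share this convention.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

from .errors import (
    ConfigurationError,
    IncompleteReportError,
    NoSignalError,
    UndefinedMetricError,
)

FLAG_COLUMNS = ("unmapped", "secondary", "qc_fail", "optical_duplicate", "pcr_duplicate")
MIN_MAPQ = 30  # strict alignment-quality filter


class AlignedTag(NamedTuple):
    """One aligned single-end read."""

    chrom: str
    start: int
    end: int
    strand: str
    mapq: int = 60
    unmapped: bool = False
    secondary: bool = False
    qc_fail: bool = False
    optical_duplicate: bool = False
    pcr_duplicate: bool = False


@dataclass
class TagSet:
    """A library of aligned tags, columnar for vectorized QC."""

    df: pd.DataFrame

    COLUMNS = ("chrom", "start", "end", "strand", "mapq") + FLAG_COLUMNS

    def __post_init__(self):
        for col in FLAG_COLUMNS:
            if col not in self.df.columns:
                self.df[col] = False
        self.df = self.df[list(self.COLUMNS)].reset_index(drop=True)
        self.df = self.df.astype({"start": np.int64, "end": np.int64, "mapq": np.int64,
                                  **{c: bool for c in FLAG_COLUMNS}})

    @classmethod
    def from_records(cls, tags: Iterable[AlignedTag]) -> "TagSet":
        rows = list(tags)
        if not rows:
            return cls(pd.DataFrame(columns=list(cls.COLUMNS)).astype(
                {"start": np.int64, "end": np.int64, "mapq": np.int64}))
        return cls(pd.DataFrame(rows, columns=AlignedTag._fields))

    @classmethod
    def from_arrays(cls, chrom, start, end, strand, mapq=None, **flags) -> "TagSet":
        n = len(start)
        df = pd.DataFrame({
            "chrom": chrom,
            "start": np.asarray(start, dtype=np.int64),
            "end": np.asarray(end, dtype=np.int64),
            "strand": strand,
            "mapq": np.full(n, 60, dtype=np.int64) if mapq is None else np.asarray(mapq),
        })
        for col in FLAG_COLUMNS:
            df[col] = np.asarray(flags[col]) if col in flags else False
        return cls(df)

    def __len__(self) -> int:
        return len(self.df)

    def records(self) -> list[AlignedTag]:
        return [AlignedTag(*row) for row in self.df.itertuples(index=False)]

    def five_prime(self) -> np.ndarray:
        """Strand-aware 5' positions (plus: start; minus: half-open end)."""
        minus = self.df["strand"].to_numpy() == "-"
        return np.where(minus, self.df["end"].to_numpy(), self.df["start"].to_numpy())

    def read_length(self) -> int:
        if len(self.df) == 0:
            raise UndefinedMetricError("empty tag set has no read length")
        lengths = (self.df["end"] - self.df["start"]).to_numpy()
        values, counts = np.unique(lengths, return_counts=True)
        return int(values[np.argmax(counts)])


# ---------------------------------------------------------------------------
# filtering and deduplication
# ---------------------------------------------------------------------------

#: removal criteria in precedence order (a tag counts once, first match wins)
FILTER_ORDER = ("unmapped", "secondary", "qc_fail", "optical_duplicate", "low_mapq")


def filter_alignments(tags: TagSet) -> tuple[TagSet, dict[str, int]]:
    """Apply the strict alignment filters.

    Removes tags that are unmapped, secondary, vendor-failed, optical
    duplicates, or have MAPQ < 30.  Returns the retained tags and a per-
    criterion removal count; each removed tag is attributed to the first
    matching criterion in :data:`FILTER_ORDER`.
    """
    df = tags.df
    stats = dict.fromkeys(FILTER_ORDER, 0)
    removed = np.zeros(len(df), dtype=bool)
    criteria = {
        "unmapped": df["unmapped"].to_numpy(),
        "secondary": df["secondary"].to_numpy(),
        "qc_fail": df["qc_fail"].to_numpy(),
        "optical_duplicate": df["optical_duplicate"].to_numpy(),
        "low_mapq": df["mapq"].to_numpy() < MIN_MAPQ,
    }
    for name in FILTER_ORDER:
        hit = criteria[name] & ~removed
        stats[name] = int(hit.sum())
        removed |= hit
    return TagSet(df[~removed].copy()), stats


def _duplicate_key(ts: TagSet) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": ts.df["chrom"].to_numpy(),
        "pos": ts.five_prime(),
        "strand": ts.df["strand"].to_numpy(),
    })


def mark_pcr_duplicates(tags: TagSet) -> TagSet:
    """Flag PCR duplicates; one tag per (chrom, 5' end, strand) stays unflagged.

    The retained copy is the first in (chrom, start, end, strand) sort
    order, so the operation is deterministic and idempotent.
    """
    df = tags.df.copy()
    order = np.lexsort((
        df["strand"].to_numpy(), df["end"].to_numpy(),
        df["start"].to_numpy(), df["chrom"].to_numpy(),
    ))
    sorted_df = df.iloc[order]
    key = _duplicate_key(TagSet(sorted_df.copy()))
    dup_sorted = key.duplicated(keep="first").to_numpy()
    dup = np.empty(len(df), dtype=bool)
    dup[order] = dup_sorted
    df["pcr_duplicate"] = dup
    return TagSet(df)


def remove_duplicates(tags: TagSet) -> TagSet:
    marked = mark_pcr_duplicates(tags)
    return TagSet(marked.df[~marked.df["pcr_duplicate"]].copy())


# ---------------------------------------------------------------------------
# library complexity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComplexityReport:
    total_tags: int
    distinct_positions: int
    positions_one_read: int
    positions_two_reads: int
    NRF: float
    PBC1: float
    PBC2: float  # math.inf sentinel when no position is seen exactly twice


def complexity_metrics(tags: TagSet) -> ComplexityReport:
    """NRF / PBC1 / PBC2 on filtered (NOT deduplicated) tags.

    Positions are keyed by (chromosome, 5' end, strand).  NRF = distinct /
    total; PBC1 = M1 / distinct; PBC2 = M1 / M2 with an infinity sentinel
    when M2 = 0.
    """
    if len(tags) == 0:
        raise UndefinedMetricError("complexity metrics undefined for an empty library")
    counts = _duplicate_key(tags).value_counts()
    total = len(tags)
    distinct = len(counts)
    m1 = int((counts == 1).sum())
    m2 = int((counts == 2).sum())
    pbc2 = m1 / m2 if m2 > 0 else float("inf")
    return ComplexityReport(total, distinct, m1, m2, distinct / total, m1 / distinct, pbc2)


# ---------------------------------------------------------------------------
# strand cross-correlation
# ---------------------------------------------------------------------------

@dataclass
class XcorProfile:
    shifts: np.ndarray
    cc: np.ndarray
    cc_min: float
    phantom_shift: int
    fragment_shift: int
    NSC: float
    RSC: float


def _strand_vectors(tags: TagSet, chrom: str, length: int) -> tuple[np.ndarray, np.ndarray]:
    sub = tags.df[tags.df["chrom"] == chrom]
    pos = np.where(sub["strand"].to_numpy() == "-", sub["end"].to_numpy(), sub["start"].to_numpy())
    plus = np.bincount(pos[sub["strand"].to_numpy() == "+"], minlength=length + 1)
    minus = np.bincount(pos[sub["strand"].to_numpy() == "-"], minlength=length + 1)
    return plus.astype(np.float64), minus.astype(np.float64)


def _shifted_pearson(plus: np.ndarray, minus: np.ndarray, max_shift: int) -> np.ndarray:
    """Pearson r of plus[:L-d] vs minus[d:] for d = 0..max_shift, via FFT."""
    L = len(plus)
    n_fft = 1 << int(np.ceil(np.log2(L + max_shift + 1)))
    fp = np.fft.rfft(plus, n_fft)
    fm = np.fft.rfft(minus, n_fft)
    # full cross-correlation r[d] = sum_i plus[i] * minus[i + d]
    xc = np.fft.irfft(np.conj(fp) * fm, n_fft)[: max_shift + 1]

    cs = np.concatenate(([0.0], np.cumsum(plus)))
    cs2 = np.concatenate(([0.0], np.cumsum(plus * plus)))
    ms = np.concatenate(([0.0], np.cumsum(minus)))
    ms2 = np.concatenate(([0.0], np.cumsum(minus * minus)))

    d = np.arange(max_shift + 1)
    n = (L - d).astype(np.float64)
    sx = cs[L - d]
    sxx = cs2[L - d]
    sy = ms[L] - ms[d]
    syy = ms2[L] - ms2[d]
    cov = xc / n - (sx / n) * (sy / n)
    vx = sxx / n - (sx / n) ** 2
    vy = syy / n - (sy / n) ** 2
    denom = np.sqrt(np.clip(vx, 0, None) * np.clip(vy, 0, None))
    with np.errstate(invalid="ignore", divide="ignore"):
        cc = np.where(denom > 0, cov / denom, 0.0)
    return cc


def cross_correlation(
    tags: TagSet,
    chrom_lengths: Mapping[str, int],
    max_shift: int = 500,
    exclusion_zone: tuple[int, int] | None = None,
    read_length: int | None = None,
) -> XcorProfile:
    """Strand cross-correlation profile with NSC and RSC.

    cc(d) is the Pearson correlation of the plus-strand 5'-count vector
    against the minus-strand vector shifted left by d, pooled across
    chromosomes by a length-weighted average.  The fragment peak is the
    argmax outside the phantom exclusion zone (default read_length +/- 10);
    NSC = cc(fragment)/cc_min and RSC = (cc(fragment)-cc_min) /
    (cc(read_length)-cc_min).
    """
    strands = tags.df["strand"].to_numpy()
    if (strands == "+").sum() == 0 or (strands == "-").sum() == 0:
        raise NoSignalError("cross-correlation requires tags on both strands")
    rl = read_length if read_length is not None else tags.read_length()
    if max_shift <= rl:
        raise ConfigurationError("max_shift must exceed the read length")
    if exclusion_zone is None:
        exclusion_zone = (rl - 10, rl + 10)

    shifts = np.arange(max_shift + 1)
    pooled = np.zeros(max_shift + 1)
    weight = 0.0
    for chrom, length in chrom_lengths.items():
        plus, minus = _strand_vectors(tags, chrom, int(length))
        if plus.sum() == 0 and minus.sum() == 0:
            continue
        pooled += length * _shifted_pearson(plus, minus, max_shift)
        weight += length
    cc = pooled / weight

    cc_min = float(cc.min())
    lo, hi = exclusion_zone
    allowed = (shifts < lo) | (shifts > hi)
    fragment_shift = int(shifts[allowed][np.argmax(cc[allowed])])
    cc_frag = float(cc[fragment_shift])
    cc_phantom = float(cc[rl])
    nsc = cc_frag / cc_min if cc_min != 0 else float("inf")
    denom = cc_phantom - cc_min
    rsc = (cc_frag - cc_min) / denom if denom != 0 else float("inf")
    return XcorProfile(shifts, cc, cc_min, rl, fragment_shift, nsc, rsc)


# ---------------------------------------------------------------------------
# fingerprint / Jensen-Shannon distance
# ---------------------------------------------------------------------------

@dataclass
class FingerprintReport:
    bin_size: int
    chip_histogram: np.ndarray
    input_histogram: np.ndarray
    JSD: float


def _bin_counts(tags: TagSet, chrom_lengths: Mapping[str, int], bin_size: int) -> np.ndarray:
    counts = []
    for chrom, length in chrom_lengths.items():
        n_bins = -(-int(length) // bin_size)
        sub = tags.df[tags.df["chrom"] == chrom]
        pos = np.where(sub["strand"].to_numpy() == "-",
                       sub["end"].to_numpy() - 1, sub["start"].to_numpy())
        counts.append(np.bincount(np.clip(pos, 0, length - 1) // bin_size, minlength=n_bins))
    return np.concatenate(counts) if counts else np.zeros(0, dtype=np.int64)


def jsd_from_pmfs(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon distance (sqrt of the log2 divergence) of two PMFs."""
    n = max(len(p), len(q))
    p = np.pad(np.asarray(p, dtype=float), (0, n - len(p)))
    q = np.pad(np.asarray(q, dtype=float), (0, n - len(q)))
    return float(jensenshannon(p, q, base=2))


def jsd_fingerprint(
    chip: TagSet,
    input_: TagSet,
    chrom_lengths: Mapping[str, int],
    bin_size: int = 500,
) -> FingerprintReport:
    """JSD between the per-bin count distributions of a ChIP library and its input."""
    if bin_size <= 0:
        raise ConfigurationError("bin_size must be positive")
    if len(chip) == 0 or len(input_) == 0:
        raise UndefinedMetricError("fingerprint requires non-empty libraries")
    chip_counts = _bin_counts(chip, chrom_lengths, bin_size)
    input_counts = _bin_counts(input_, chrom_lengths, bin_size)
    p = np.bincount(chip_counts) / len(chip_counts)
    q = np.bincount(input_counts) / len(input_counts)
    n = max(len(p), len(q))
    p = np.pad(p, (0, n - len(p)))
    q = np.pad(q, (0, n - len(q)))
    return FingerprintReport(bin_size, p, q, jsd_from_pmfs(p, q))


# ---------------------------------------------------------------------------
# thresholds and verdicts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QCThresholds:
    """Strict lower bounds (metric > threshold passes)."""

    nrf_min: float = 0.5
    pbc1_min: float = 0.5
    pbc2_min: float = 1.0
    nsc_min: float = 1.05
    rsc_min: float = 0.8
    jsd_min: float = 0.05

    def as_dict(self) -> dict[str, float]:
        return {"NRF": self.nrf_min, "PBC1": self.pbc1_min, "PBC2": self.pbc2_min,
                "NSC": self.nsc_min, "RSC": self.rsc_min, "JSD": self.jsd_min}


METRIC_NAMES = ("NRF", "PBC1", "PBC2", "NSC", "RSC", "JSD")


@dataclass
class QCReport:
    metrics: dict[str, float]
    verdicts: dict[str, bool] = field(default_factory=dict)

    @property
    def n_failed(self) -> int:
        return sum(not v for v in self.verdicts.values())


def qc_verdict(metrics: Mapping[str, float], thresholds: QCThresholds | None = None) -> QCReport:
    """Strict `metric > threshold` verdicts for the six-metric panel."""
    thresholds = thresholds or QCThresholds()
    bounds = thresholds.as_dict()
    missing = [m for m in METRIC_NAMES if m not in metrics or metrics[m] is None
               or (isinstance(metrics[m], float) and np.isnan(metrics[m]))]
    if missing:
        raise IncompleteReportError(f"missing QC metrics: {', '.join(missing)}")
    verdicts = {m: bool(metrics[m] > bounds[m]) for m in METRIC_NAMES}
    return QCReport(dict(metrics), verdicts)


def qc_panel(
    chip: TagSet,
    input_: TagSet,
    chrom_lengths: Mapping[str, int],
    thresholds: QCThresholds | None = None,
    max_shift: int = 500,
    jsd_bin_size: int = 500,
) -> QCReport:
    """Full six-metric panel: filter, complexity, dedup, xcor, JSD, verdicts."""
    chip_f, _ = filter_alignments(chip)
    input_f, _ = filter_alignments(input_)
    comp = complexity_metrics(chip_f)
    chip_dd = remove_duplicates(chip_f)
    input_dd = remove_duplicates(input_f)
    xcor = cross_correlation(chip_dd, chrom_lengths, max_shift=max_shift)
    fp = jsd_fingerprint(chip_dd, input_dd, chrom_lengths, bin_size=jsd_bin_size)
    metrics = {"NRF": comp.NRF, "PBC1": comp.PBC1, "PBC2": comp.PBC2,
               "NSC": xcor.NSC, "RSC": xcor.RSC, "JSD": fp.JSD}
    return qc_verdict(metrics, thresholds)
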