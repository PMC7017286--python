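"""Cross-replicate and cross-tissue peak comparisons.

Implements the similarity and specificity analyses run on the combined peak
sets: base-pair Jaccard similarity between interval sets, unique-peak
classification (a peak is unique to a tissue iff it overlaps zero bp of the
same mark's peaks in every other tissue), active-enhancer intervals
(H3K4me1 ∩ H3K27ac within one tissue), and tissue-specific active enhancers
(active enhancers with no overlap of either mark in any other tissue).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import intervals
from .errors import UndefinedMetricError, ValidationError

IntervalSet = Mapping[str, np.ndarray]


def _normalize(ivs) -> dict[str, np.ndarray]:
    """Accept an interval dict, a ConsensusPeakSet, or a Peak sequence."""
    if hasattr(ivs, "intervals"):
        ivs = ivs.intervals()
    if isinstance(ivs, Mapping):
        return {c: intervals.as_array(a) for c, a in ivs.items()}
    out: dict[str, list] = {}
    for p in ivs:
        out.setdefault(p.chrom, []).append((p.start, p.end))
    return {c: intervals.as_array(v) for c, v in out.items()}


def jaccard(set_a, set_b) -> float:
    """bp-intersection / bp-union of two interval sets (merged internally)."""
    a = intervals.merge(_normalize(set_a))
    b = intervals.merge(_normalize(set_b))
    len_a = intervals.total_length(a)
    len_b = intervals.total_length(b)
    if len_a == 0 and len_b == 0:
        raise UndefinedMetricError("Jaccard undefined: both interval sets are empty")
    inter = intervals.total_length(intervals.intersect(a, b))
    return inter / (len_a + len_b - inter)


def jaccard_matrix(labelled_sets: Mapping[str, IntervalSet]) -> tuple[pd.DataFrame, pd.Series]:
    """All pairwise Jaccard values plus each row's best (non-self) partner."""
    labels = list(labelled_sets)
    if len(labels) != len(set(labels)):
        raise ValidationError("duplicate labels in Jaccard comparison")
    if len(labels) < 2:
        raise ValidationError("need at least two labelled sets")
    norm = {k: intervals.merge(_normalize(v)) for k, v in labelled_sets.items()}
    mat = pd.DataFrame(np.ones((len(labels), len(labels))), index=labels, columns=labels)
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if j <= i:
                continue
            val = jaccard(norm[a], norm[b])
            mat.iloc[i, j] = mat.iloc[j, i] = val
    off = mat.where(~np.eye(len(labels), dtype=bool))
    return mat, off.idxmax(axis=1)


@dataclass
class SpecificityTable:
    table: pd.DataFrame  # columns: tissue, unique_count, shared_count, unique_fraction


def unique_peaks(
    mark: str,
    tissue_peaks: Mapping[str, object],
) -> tuple[SpecificityTable, dict[str, dict[str, np.ndarray]]]:
    """Classify each tissue's peaks as unique vs shared for one mark.

    A peak is unique iff it overlaps zero bp of every other tissue's
    same-mark peak set (any overlap, down to 1 bp, disqualifies it).
    Returns the per-tissue count table and the unique peak intervals.
    """
    if len(tissue_peaks) < 2:
        raise ValidationError("unique-peak classification needs >= 2 tissues")
    norm = {t: _normalize(v) for t, v in tissue_peaks.items()}
    rows = []
    uniques: dict[str, dict[str, np.ndarray]] = {}
    for tissue, ivs in norm.items():
        others: dict[str, list] = {}
        for other, oivs in norm.items():
            if other == tissue:
                continue
            for c, arr in oivs.items():
                others.setdefault(c, []).append(arr)
        others_merged = {c: intervals.merge_array(np.concatenate(v)) for c, v in others.items()}
        unique_ivs = intervals.subtract_overlapping(ivs, others_merged)
        n_total = sum(len(a) for a in ivs.values())
        n_unique = sum(len(a) for a in unique_ivs.values())
        rows.append({"mark": mark, "tissue": tissue, "unique_count": n_unique,
                     "shared_count": n_total - n_unique,
                     "unique_fraction": n_unique / n_total if n_total else 0.0})
        uniques[tissue] = unique_ivs
    return SpecificityTable(pd.DataFrame(rows)), uniques


def active_enhancers(me1_peaks, ac_peaks) -> dict[str, np.ndarray]:
    """Active-enhancer intervals: bp intersection of H3K4me1 and H3K27ac."""
    a = intervals.merge(_normalize(me1_peaks))
    b = intervals.merge(_normalize(ac_peaks))
    return intervals.intersect(a, b)


def tissue_specific_enhancers(
    enhancers: Mapping[str, IntervalSet],
    me1: Mapping[str, IntervalSet],
    ac: Mapping[str, IntervalSet],
) -> dict[str, dict[str, np.ndarray]]:
    """Per-tissue enhancers with zero overlap of either mark in other tissues.

    An active enhancer of tissue t survives iff it overlaps no bp of any
    OTHER tissue's H3K4me1 peaks nor of any other tissue's H3K27ac peaks
    (the strict raw-mark reading of "no overlap of these marks").
    """
    tissues = list(enhancers)
    if set(me1) != set(tissues) or set(ac) != set(tissues):
        raise ValidationError("enhancers, me1 and ac must cover the same tissues")
    out = {}
    for tissue in tissues:
        enh = _normalize(enhancers[tissue])
        others: dict[str, list] = {}
        for other in tissues:
            if other == tissue:
                continue
            for source in (me1[other], ac[other]):
                for c, arr in _normalize(source).items():
                    others.setdefault(c, []).append(arr)
        others_merged = {c: intervals.merge_array(np.concatenate(v))
                         for c, v in others.items()}
        out[tissue] = intervals.subtract_overlapping(enh, others_merged)
    return out
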