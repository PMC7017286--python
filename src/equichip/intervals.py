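"""Genome-interval arithmetic on 0-based half-open coordinates.

Interval sets are represented per chromosome as ``dict[str, np.ndarray]``
with shape ``(n, 2)`` arrays of ``[start, end)`` rows.  All set operations
assume (and produce) sorted, internally merged arrays; :func:`merge` is the
normalizing entry point.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np

IntervalSet = Mapping[str, np.ndarray]


def as_array(intervals: Iterable[tuple[int, int]]) -> np.ndarray:
    arr = np.asarray(list(intervals), dtype=np.int64)
    if arr.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    return arr.reshape(-1, 2)


def merge_array(arr: np.ndarray) -> np.ndarray:
    """Sort and merge overlapping/adjacent-by-overlap intervals (>=1 bp)."""
    arr = as_array(arr)
    if len(arr) == 0:
        return arr
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    out = []
    cur_s, cur_e = int(arr[0, 0]), int(arr[0, 1])
    for s, e in arr[1:]:
        if s < cur_e:  # touching intervals ([0,5),[5,9)) stay separate
            cur_e = max(cur_e, int(e))
        else:
            out.append((cur_s, cur_e))
            cur_s, cur_e = int(s), int(e)
    out.append((cur_s, cur_e))
    return as_array(out)


def merge(ivs: IntervalSet) -> dict[str, np.ndarray]:
    return {c: merge_array(a) for c, a in ivs.items() if len(as_array(a))}


def total_length(ivs: IntervalSet) -> int:
    """Union length in bp (input merged per chromosome first)."""
    return sum(int((a[:, 1] - a[:, 0]).sum()) for a in merge(ivs).values())


def intersect_arrays(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Intersection of two merged, sorted interval arrays (two-pointer sweep)."""
    a, b = merge_array(a), merge_array(b)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((int(s), int(e)))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return as_array(out)


def intersect(a: IntervalSet, b: IntervalSet) -> dict[str, np.ndarray]:
    chroms = set(a) & set(b)
    out = {}
    for c in sorted(chroms):
        ab = intersect_arrays(a[c], b[c])
        if len(ab):
            out[c] = ab
    return out


def overlaps_any(query: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Boolean per query row: does it overlap >=1 bp of the merged target?"""
    query = as_array(query)
    target = merge_array(target)
    if len(target) == 0 or len(query) == 0:
        return np.zeros(len(query), dtype=bool)
    starts, ends = target[:, 0], target[:, 1]
    # candidate: last target starting strictly before query end
    idx = np.searchsorted(starts, query[:, 1], side="left") - 1
    hit = idx >= 0
    hit[hit] = ends[idx[hit]] > query[hit, 0]
    return hit


def subtract_overlapping(query: IntervalSet, target: IntervalSet) -> dict[str, np.ndarray]:
    """Keep query intervals (whole intervals) with zero overlap to target."""
    out = {}
    for c, arr in query.items():
        arr = as_array(arr)
        if len(arr) == 0:
            continue
        t = target.get(c)
        mask = ~overlaps_any(arr, t if t is not None else np.empty((0, 2)))
        kept = arr[mask]
        if len(kept):
            out[c] = kept
    return out
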