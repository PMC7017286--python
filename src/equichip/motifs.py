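"""Known-motif scanning and enrichment ranking over enhancer sequences.

Position frequency matrices in JASPAR text format are converted to log-odds
matrices (pseudocount 0.25 per cell, uniform background by default) and
slid over both strands of the query sequences; a sequence "contains" a
motif when any window scores at least a fraction (default 80%) of the
matrix's maximum achievable score.  Enrichment of a motif in a foreground
set against a background set is a one-sided Fisher exact test on
sequence-level hit presence, BH-corrected across motifs and ranked by
adjusted p — a fully specified simplification of the AME ranking statistic.
A motif is "uniquely detected" in a tissue when it is significant there and
in no other tissue.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from scipy import stats

from .errors import ParseError, ValidationError
from .peaks import bh_adjust
from .simdata import IUPAC, _revcomp

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass
class PositionWeightMatrix:
    motif_id: str
    name: str
    counts: np.ndarray            # 4 x width, rows A C G T
    pseudocount: float = 0.25
    background: np.ndarray | None = None  # base frequencies, default uniform

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != 4:
            raise ParseError(f"motif {self.motif_id}: expected 4 count rows")
        if np.any(self.counts.sum(axis=0) <= 0):
            raise ParseError(f"motif {self.motif_id}: empty count column")
        if self.background is None:
            self.background = np.full(4, 0.25)

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        """log2((c + pseudocount) / (N + 4*pseudocount) / background) per cell."""
        col_tot = self.counts.sum(axis=0) + 4 * self.pseudocount
        freq = (self.counts + self.pseudocount) / col_tot
        return np.log2(freq / self.background[:, None])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.counts.argmax(axis=0))


def read_jaspar(path_or_handle) -> list[PositionWeightMatrix]:
    """Parse a JASPAR-format PFM file (">ID NAME" + 4 bracketed count rows)."""
    if hasattr(path_or_handle, "read"):
        handle = path_or_handle
    else:
        handle = open(path_or_handle)
    try:
        text = handle.read()
        # structural pre-check: every ">" header must own exactly 4 count rows
        n_rows = 0
        header_seen = False
        for line in text.splitlines():
            if line.startswith(">"):
                if header_seen and n_rows != 4:
                    raise ParseError("JASPAR motif must have exactly 4 count rows")
                header_seen, n_rows = True, 0
            elif line.strip():
                n_rows += 1
        if header_seen and n_rows != 4:
            raise ParseError("JASPAR motif must have exactly 4 count rows")
        parsed = bio_motifs.parse(_io.StringIO(text), "jaspar")
        out = []
        for m in parsed:
            counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
            out.append(PositionWeightMatrix(m.matrix_id or m.name, m.name or m.matrix_id, counts))
        return out
    except ParseError:
        raise
    except Exception as exc:
        raise ParseError(f"malformed JASPAR file: {exc}") from exc
    finally:
        if handle is not path_or_handle:
            handle.close()


def write_jaspar(pwms: Sequence[PositionWeightMatrix], path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id} {pwm.name}\n")
            for base, row in zip("ACGT", pwm.counts):
                cells = " ".join(f"{v:10.2f}" for v in row)
                fh.write(f"{base}  [ {cells} ]\n")


def pwm_from_iupac(consensus: str, motif_id: str, name: str | None = None,
                   total: float = 100.0) -> PositionWeightMatrix:
    """Build a PFM from an IUPAC consensus: counts split among allowed bases."""
    cols = []
    for base in consensus.upper():
        allowed = IUPAC.get(base)
        if allowed is None:
            raise ValidationError(f"invalid IUPAC symbol {base!r}")
        col = np.zeros(4)
        for b in allowed:
            col[_BASE_INDEX[b]] = total / len(allowed)
        cols.append(col)
    return PositionWeightMatrix(motif_id, name or motif_id, np.array(cols).T)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    return codes


def _scores(codes: np.ndarray, lo_ext: np.ndarray) -> np.ndarray:
    """Sliding-window log-odds scores at every offset (N scores as worst base)."""
    w = lo_ext.shape[1]
    n = len(codes) - w + 1
    if n <= 0:
        return np.zeros(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    return lo_ext[windows, np.arange(w)].sum(axis=1)


@dataclass
class MotifHit:
    seq_id: str
    offset: int
    strand: str
    score: float


def scan(
    sequences: Mapping[str, str],
    pwm: PositionWeightMatrix,
    score_threshold: float | None = None,
    threshold_fraction: float = 0.8,
) -> list[MotifHit]:
    """Report every window on either strand scoring >= the threshold.

    The default threshold is ``threshold_fraction`` of the matrix's maximum
    achievable score.  Minus-strand hits are reported at the forward-strand
    offset of the matched window.  Sequences shorter than the motif are
    skipped.
    """
    if score_threshold is None:
        score_threshold = threshold_fraction * pwm.max_score
    lo = pwm.log_odds
    lo_ext = np.vstack([lo, lo.min(axis=0)])  # row 4: N as the worst base
    lo_rc = lo[::-1, ::-1]                    # reverse complement matrix
    lo_rc_ext = np.vstack([lo_rc, lo_rc.min(axis=0)])
    hits: list[MotifHit] = []
    for seq_id, seq in sequences.items():
        codes = _encode(seq)
        if len(codes) < pwm.width:
            continue
        fwd = _scores(codes, lo_ext)
        rev = _scores(codes, lo_rc_ext)
        for off in np.flatnonzero(fwd >= score_threshold):
            hits.append(MotifHit(seq_id, int(off), "+", float(fwd[off])))
        for off in np.flatnonzero(rev >= score_threshold):
            hits.append(MotifHit(seq_id, int(off), "-", float(rev[off])))
    return hits


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

@dataclass
class MotifEnrichmentResult:
    motif_id: str
    consensus: str
    fg_hits: int
    fg_total: int
    bg_hits: int
    bg_total: int
    p_value: float
    adjusted_p: float = float("nan")
    rank: int = 0


def fisher_greater(fg_hit: int, fg_total: int, bg_hit: int, bg_total: int) -> float:
    """One-sided Fisher exact p for foreground hit excess."""
    table = [[fg_hit, fg_total - fg_hit], [bg_hit, bg_total - bg_hit]]
    _, p = stats.fisher_exact(table, alternative="greater")
    return float(p)


def enrich(
    foreground: Mapping[str, str],
    background: Mapping[str, str],
    pwms: Sequence[PositionWeightMatrix],
    threshold_fraction: float = 0.8,
) -> list[MotifEnrichmentResult]:
    """Rank motifs by foreground-vs-background hit enrichment.

    Per motif, sequences are classified by >=1 hit presence; the 2x2 table
    (hit/no-hit x foreground/background) is tested with a one-sided Fisher
    exact test for foreground excess, and p-values are BH-adjusted across
    motifs.  Results are sorted by adjusted p (ties by raw p then id).
    """
    if not foreground:
        raise ValidationError("empty foreground sequence set")
    if not background:
        raise ValidationError("empty background sequence set")
    results = []
    for pwm in pwms:
        fg_hit = len({h.seq_id for h in scan(foreground, pwm,
                                             threshold_fraction=threshold_fraction)})
        bg_hit = len({h.seq_id for h in scan(background, pwm,
                                             threshold_fraction=threshold_fraction)})
        p = fisher_greater(fg_hit, len(foreground), bg_hit, len(background))
        results.append(MotifEnrichmentResult(
            pwm.motif_id, pwm.consensus(), fg_hit, len(foreground),
            bg_hit, len(background), p))
    adj = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, adj):
        r.adjusted_p = float(q)
    results.sort(key=lambda r: (r.adjusted_p, r.p_value, r.motif_id))
    for i, r in enumerate(results):
        r.rank = i + 1
    return results


def results_frame(results: Sequence[MotifEnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "rank": r.rank, "motif_id": r.motif_id, "consensus": r.consensus,
        "fg_hits": r.fg_hits, "fg_total": r.fg_total,
        "bg_hits": r.bg_hits, "bg_total": r.bg_total,
        "p_value": r.p_value, "adjusted_p": r.adjusted_p,
    } for r in results])


def uniquely_detected(
    per_tissue: Mapping[str, Sequence[MotifEnrichmentResult]],
    alpha: float = 0.05,
) -> dict[str, list[str]]:
    """Motifs significant (adjusted p <= alpha) in exactly one tissue."""
    if len(per_tissue) < 2:
        raise ValidationError("unique detection needs >= 2 tissues")
    significant = {t: {r.motif_id for r in res if r.adjusted_p <= alpha}
                   for t, res in per_tissue.items()}
    out: dict[str, list[str]] = {}
    for tissue, motifs_here in significant.items():
        elsewhere = set().union(*(m for t, m in significant.items() if t != tissue))
        out[tissue] = sorted(motifs_here - elsewhere)
    return out


# ---------------------------------------------------------------------------
# background construction
# ---------------------------------------------------------------------------

def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving exact dinucleotide counts (Altschul–Erickson).

    Builds the multigraph of observed base-to-base transitions and returns
    a uniformly random Eulerian path with the original first and last base.
    """
    if len(seq) < 3:
        return seq
    seq = seq.upper()
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    # choose a random last edge into a spanning "arborescence" toward `last`
    # (Wilson-style): walk from each vertex until hitting `last`
    for _ in range(100):
        last_edge: dict[str, str] = {}
        ok = True
        for v in edges:
            if v == last:
                continue
            last_edge[v] = edges[v][rng.integers(0, len(edges[v]))]
        # verify every vertex reaches `last` through chosen edges
        for v in last_edge:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - degenerate composition
        return seq
    shuffled: dict[str, list[str]] = {}
    for v, targets in edges.items():
        rest = list(targets)
        if v in last_edge:
            rest.remove(last_edge[v])
        perm = rng.permutation(len(rest))
        ordered = [rest[i] for i in perm]
        if v in last_edge:
            ordered.append(last_edge[v])
        shuffled[v] = ordered
    out = [seq[0]]
    pos = dict.fromkeys(shuffled, 0)
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled[cur][pos[cur]]
        pos[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def shuffled_background(sequences: Mapping[str, str],
                        rng: np.random.Generator) -> dict[str, str]:
    return {f"shuf_{k}": dinucleotide_shuffle(v, rng) for k, v in sequences.items()}


def extract_sequences(genome: Mapping[str, str],
                      ivs: Mapping[str, np.ndarray],
                      prefix: str = "region") -> dict[str, str]:
    """Pull interval sequences out of an in-memory genome."""
    out = {}
    i = 0
    for chrom in sorted(ivs):
        for start, end in np.asarray(ivs[chrom]).reshape(-1, 2):
            i += 1
            out[f"{prefix}_{i}_{chrom}_{int(start)}"] = genome[chrom][int(start):int(end)]
    return out
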