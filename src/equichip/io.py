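"""Readers and writers for the pipeline's text formats.

All BED-family coordinates are 0-based half-open in memory and on disk;
GTF records are converted at the boundary (1-based closed on disk).  SAM
round-trips go through pysam, FASTA through Biopython.  Writers emit sorted
records so that write(read(x)) is byte-stable for sorted inputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError, ValidationError
from .peaks import ConsensusPeakSet, Peak
from .profiles import BinnedTrack
from .readqc import TagSet
from .simdata import GeneModel


# -- FASTA / chrom.sizes -----------------------------------------------------

def write_fasta(genome: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_chrom_sizes(chrom_lengths: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, length in chrom_lengths.items():
            fh.write(f"{chrom}\t{int(length)}\n")


def read_chrom_sizes(path) -> dict[str, int]:
    out = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise ParseError("chrom.sizes lines need exactly two columns", line=i)
            out[fields[0]] = int(fields[1])
    return out


# -- tagAlign / SAM ----------------------------------------------------------

def write_tagalign(tags: TagSet, path) -> None:
    """BED6 dialect: chrom, start, end, name, MAPQ in the score column, strand."""
    df = tags.df.sort_values(["chrom", "start", "end", "strand"], kind="mergesort")
    with open(path, "w") as fh:
        for i, row in enumerate(df.itertuples(index=False), 1):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\ttag_{i}\t{row.mapq}\t{row.strand}\n")


def read_tagalign(path) -> TagSet:
    try:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "name", "mapq", "strand"],
                         dtype={"chrom": str, "start": np.int64, "end": np.int64,
                                "name": str, "mapq": np.int64, "strand": str})
    except Exception as exc:
        raise ParseError(f"malformed tagAlign file {path}: {exc}") from exc
    return TagSet.from_arrays(df["chrom"].to_numpy(), df["start"].to_numpy(),
                              df["end"].to_numpy(), df["strand"].to_numpy(),
                              df["mapq"].to_numpy())


def write_sam(tags: TagSet, chrom_lengths: Mapping[str, int], path) -> None:
    header = {"HD": {"VN": "1.6"},
              "SQ": [{"SN": c, "LN": int(l)} for c, l in chrom_lengths.items()]}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        df = tags.df.sort_values(["chrom", "start", "end", "strand"], kind="mergesort")
        for i, row in enumerate(df.itertuples(index=False), 1):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"tag_{i}"
            a.reference_name = row.chrom
            a.reference_start = int(row.start)
            a.mapping_quality = int(row.mapq)
            length = int(row.end - row.start)
            a.cigarstring = f"{length}M"
            a.query_sequence = None
            flag = 0
            if row.strand == "-":
                flag |= 0x10
            if row.unmapped:
                flag |= 0x4
            if row.secondary:
                flag |= 0x100
            if row.qc_fail:
                flag |= 0x200
            if row.optical_duplicate or row.pcr_duplicate:
                flag |= 0x400
            a.flag = flag
            out.write(a)


def read_sam(path) -> TagSet:
    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            end = rec.reference_end if rec.reference_end is not None \
                else rec.reference_start + (rec.query_length or 0)
            rows.append((rec.reference_name, rec.reference_start, end,
                         "-" if rec.is_reverse else "+", rec.mapping_quality,
                         rec.is_unmapped, rec.is_secondary, rec.is_qcfail,
                         rec.is_duplicate, False))
    import pandas as _pd
    df = _pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "mapq",
                                      "unmapped", "secondary", "qc_fail",
                                      "optical_duplicate", "pcr_duplicate"])
    return TagSet(df)


# -- narrowPeak / broadPeak --------------------------------------------------

def _neglog10(x: float) -> float:
    return float(-np.log10(max(x, 1e-300)))


def write_narrowpeak(peaks: Sequence[Peak], path) -> None:
    with open(path, "w") as fh:
        for p in sorted(peaks, key=lambda p: (p.chrom, p.start, p.end)):
            fh.write("\t".join(map(str, [
                p.chrom, p.start, p.end, p.name, p.score, p.strand,
                f"{p.signal:.5f}", f"{_neglog10(p.p_value):.5f}",
                f"{_neglog10(p.q_value):.5f}", p.summit])) + "\n")


def write_broadpeak(peaks: Sequence[Peak], path) -> None:
    with open(path, "w") as fh:
        for p in sorted(peaks, key=lambda p: (p.chrom, p.start, p.end)):
            fh.write("\t".join(map(str, [
                p.chrom, p.start, p.end, p.name, p.score, p.strand,
                f"{p.signal:.5f}", f"{_neglog10(p.p_value):.5f}",
                f"{_neglog10(p.q_value):.5f}"])) + "\n")


def _read_peak_file(path, n_cols: int, broad: bool) -> list[Peak]:
    peaks = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != n_cols:
                raise ParseError(
                    f"expected {n_cols} columns, found {len(fields)}", line=i)
            try:
                chrom, start, end, name, score, strand = fields[:6]
                signal, p_log, q_log = map(float, fields[6:9])
                summit = -1 if broad else int(fields[9])
                peaks.append(Peak(chrom, int(start), int(end), name, int(score),
                                  strand, signal, 10 ** -p_log, 10 ** -q_log, summit))
            except ParseError:
                raise
            except Exception as exc:
                raise ParseError(f"malformed peak record: {exc}", line=i) from exc
    return peaks


def read_narrowpeak(path) -> list[Peak]:
    return _read_peak_file(path, 10, broad=False)


def read_broadpeak(path) -> list[Peak]:
    return _read_peak_file(path, 9, broad=True)


def write_consensus_bed(cps: ConsensusPeakSet, path) -> None:
    """BED6+3: standard six columns plus best q, rep1 members, rep2 members."""
    with open(path, "w") as fh:
        for p in sorted(cps.peaks, key=lambda p: (p.chrom, p.start, p.end)):
            fh.write("\t".join(map(str, [
                p.chrom, p.start, p.end, p.name, 0, ".",
                f"{p.q_value:.3e}",
                ",".join(p.members_rep1) or ".",
                ",".join(p.members_rep2) or "."])) + "\n")


# -- gene models -------------------------------------------------------------

def write_genes_bed(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand}\n")


def read_genes_bed(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ParseError("gene BED needs >= 6 columns", line=i)
            genes.append(GeneModel(fields[0], int(fields[1]), int(fields[2]),
                                   fields[3], fields[5]))
    return genes


def read_genes_gtf(path) -> list[GeneModel]:
    """Minimal GTF: gene features, 1-based closed converted to half-open."""
    genes = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError("GTF needs 9 tab-separated columns", line=i)
            if fields[2] != "gene":
                continue
            attrs = fields[8]
            name = f"gene_{i}"
            for token in attrs.split(";"):
                token = token.strip()
                if token.startswith("gene_id"):
                    name = token.split(maxsplit=1)[1].strip('" ')
            genes.append(GeneModel(fields[0], int(fields[3]) - 1, int(fields[4]),
                                   name, fields[6]))
    return genes


def write_genes_gtf(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(f"{g.chrom}\tequichip\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tgene_id \"{g.name}\";\n")


# -- bedGraph / tables -------------------------------------------------------

def write_bedgraph(track: BinnedTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chrom_lengths:
            values = track.data[chrom]
            for b, v in enumerate(values):
                if v == 0:
                    continue
                start = b * track.bin_size
                end = min(start + track.bin_size, track.chrom_lengths[chrom])
                fh.write(f"{chrom}\t{start}\t{end}\t{v:.5f}\n")


def write_xcor_tsv(profile, path) -> None:
    with open(path, "w") as fh:
        fh.write("shift\tcc\n")
        for s, c in zip(profile.shifts, profile.cc):
            fh.write(f"{int(s)}\t{c:.6f}\n")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
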