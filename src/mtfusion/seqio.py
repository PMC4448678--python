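"""Sequence/alignment I/O and coordinate conventions.

All internal coordinates are 0-based, half-open. Conversion to the 1-based
conventions of SAM/VCF happens only at the I/O boundary. Breakpoints are
*between-base* coordinates: breakpoint ``p`` sits between base ``p-1`` and
base ``p``.

The mitochondrial genome is circular; :func:`circ_dist` and the arc helpers
implement distance and interval arithmetic on the circle so that clusters and
segments spanning the origin are handled transparently.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pysam
from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq as _BioSeq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

MT_NAME_DEFAULT = "MT"
RCRS_LENGTH = 16_569

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FastaParseError(ValueError):
    """Malformed FASTA input; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass
class GenomeRef:
    """Reference genome: ordered contigs plus a designated (circular) mt contig."""

    contigs: dict[str, str]
    mt_name: str | None = MT_NAME_DEFAULT
    mt_circular: bool = True

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.mt_name is not None:
            if self.mt_name not in self.contigs:
                raise ValueError(f"mt contig {self.mt_name!r} not present in genome")
            if len(self.contigs[self.mt_name]) == 0:
                raise ValueError("mt contig has zero length")
        allowed = set("ACGTN")
        for name, seq in self.contigs.items():
            bad = set(seq) - allowed
            if bad:
                raise ValueError(f"contig {name!r} contains invalid characters {sorted(bad)}")

    @property
    def mt_len(self) -> int:
        if self.mt_name is None:
            raise ValueError("no mt contig designated")
        return len(self.contigs[self.mt_name])

    @property
    def mt_seq(self) -> str:
        return self.contigs[self.mt_name]

    def is_mt(self, contig: str) -> bool:
        return contig == self.mt_name

    def nuclear_contigs(self) -> list[str]:
        return [c for c in self.contigs if c != self.mt_name]


@dataclass
class AlignedRead:
    """Minimal alignment record: the fields the caller consumes.

    ``cigar`` is a list of ``(op, length)`` with ops in {M, S}; soft clips plus
    the aligned span account for the full read length.
    """

    qname: str
    contig: str
    start: int
    end: int
    strand: str
    mapq: int
    cigar: list[tuple[str, int]]
    mate_contig: str | None
    mate_start: int
    mate_strand: str
    seq: str
    is_paired: bool = True
    mate_unmapped: bool = False
    is_proper: bool = False
    is_read1: bool = True

    @property
    def clip_left(self) -> int:
        return self.cigar[0][1] if self.cigar and self.cigar[0][0] == "S" else 0

    @property
    def clip_right(self) -> int:
        return self.cigar[-1][1] if self.cigar and self.cigar[-1][0] == "S" else 0

    @property
    def clipped(self) -> int:
        return self.clip_left + self.clip_right

    @property
    def aligned_len(self) -> int:
        return self.end - self.start

    @classmethod
    def from_pysam(cls, rec: "pysam.AlignedSegment") -> "AlignedRead":
        cigar: list[tuple[str, int]] = []
        for op, length in rec.cigartuples or []:
            if op == 4:
                cigar.append(("S", length))
            elif op in (0, 7, 8):
                if cigar and cigar[-1][0] == "M":
                    cigar[-1] = ("M", cigar[-1][1] + length)
                else:
                    cigar.append(("M", length))
            # D/I/N do not occur in data this package emits; ignore for span
        return cls(
            qname=rec.query_name,
            contig=rec.reference_name,
            start=rec.reference_start,
            end=rec.reference_end if rec.reference_end is not None else rec.reference_start,
            strand="-" if rec.is_reverse else "+",
            mapq=rec.mapping_quality,
            cigar=cigar,
            mate_contig=None if rec.mate_is_unmapped or rec.next_reference_id < 0 else rec.next_reference_name,
            mate_start=max(rec.next_reference_start, 0),
            mate_strand="-" if rec.mate_is_reverse else "+",
            seq=rec.query_sequence or "",
            is_paired=rec.is_paired,
            mate_unmapped=rec.mate_is_unmapped,
            is_proper=rec.is_proper_pair,
            is_read1=rec.is_read1,
        )


@dataclass
class Annotation:
    """Genomic interval annotation (0-based half-open) with a class label."""

    contig: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"annotation end must exceed start ({self.contig}:{self.start}-{self.end})")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _validate_fasta_lines(path: str) -> None:
    allowed = set("ACGTNacgtn")
    seen_header = False
    n_lines = 0
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            n_lines = i
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if len(line) == 1:
                    raise FastaParseError("empty FASTA header", i)
                seen_header = True
            else:
                if not seen_header:
                    raise FastaParseError("sequence before any FASTA header", i)
                bad = set(line) - allowed
                if bad:
                    raise FastaParseError(f"invalid sequence characters {sorted(bad)}", i)
    if not seen_header:
        raise FastaParseError("no FASTA records found", max(n_lines, 1))


def read_fasta(path: str, mt_name: str | None = MT_NAME_DEFAULT) -> GenomeRef:
    """Read a multi-contig FASTA into a :class:`GenomeRef` (sequences uppercased)."""
    _validate_fasta_lines(path)
    contigs: dict[str, str] = {}
    for rec in _BioSeqIO.parse(path, "fasta"):
        contigs[rec.id] = str(rec.seq).upper()
    if mt_name is not None and mt_name not in contigs:
        mt_name = None
    return GenomeRef(contigs=contigs, mt_name=mt_name)


def write_fasta(genome: GenomeRef, path: str, width: int = 60) -> None:
    records = [_BioSeqRecord(_BioSeq(seq), id=name, description="") for name, seq in genome.contigs.items()]
    with open(path, "w") as fh:
        writer = _BioSeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# SAM/BAM
# ---------------------------------------------------------------------------

def open_alignments(path: str) -> pysam.AlignmentFile:
    mode = "rb" if str(path).endswith(".bam") else "r"
    return pysam.AlignmentFile(path, mode, check_sq=True)


def read_alignments(path: str, region: tuple[str, int, int] | None = None) -> Iterator[AlignedRead]:
    """Stream primary alignments as :class:`AlignedRead`, optionally restricted to a region.

    Region filtering falls back to a full scan when no index is available
    (plain SAM); records whose contig is absent from the header raise at the
    pysam layer.
    """
    with open_alignments(path) as af:
        if region is not None:
            contig, start, end = region
            if contig not in af.references:
                raise ValueError(f"region contig {contig!r} not in header")
            try:
                it = af.fetch(contig, start, end)
            except ValueError:  # no index: stream and filter
                it = (r for r in af if r.reference_name == contig
                      and r.reference_start < end
                      and (r.reference_end or r.reference_start) > start)
        else:
            it = iter(af)
        for rec in it:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            yield AlignedRead.from_pysam(rec)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str) -> list[Annotation]:
    """Read BED3+label (0-based half-open per the BED standard)."""
    out: list[Annotation] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {i}: BED requires >= 3 tab-separated fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {i}: non-integer BED coordinates") from exc
            if end <= start:
                raise ValueError(f"{path}: line {i}: end must exceed start")
            out.append(Annotation(parts[0], start, end, parts[3] if len(parts) > 3 else ""))
    return out


def write_bed(annotations: Iterable[Annotation], path: str) -> None:
    with open(path, "w") as fh:
        for a in annotations:
            fh.write(f"{a.contig}\t{a.start}\t{a.end}\t{a.label}\n")


# ---------------------------------------------------------------------------
# Circular arithmetic
# ---------------------------------------------------------------------------

def circ_dist(a: int, b: int, length: int) -> int:
    """Shortest distance between two positions on a circle of given length."""
    if length <= 0:
        raise ValueError("circle length must be positive")
    if not (0 <= a < length) or not (0 <= b < length):
        raise ValueError(f"positions must lie in [0, {length}): got {a}, {b}")
    d = abs(a - b)
    return min(d, length - d)


def arc_intervals(start: int, end: int, length: int) -> list[tuple[int, int]]:
    """Decompose the forward arc [start, end] (inclusive positions) into linear intervals."""
    start %= length
    end %= length
    if start <= end:
        return [(start, end)]
    return [(start, length - 1), (0, end)]


def arcs_overlap(s1: int, e1: int, s2: int, e2: int, length: int, slop: int = 0) -> bool:
    """Do two inclusive forward arcs on the circle intersect (second arc padded by slop)?"""
    if slop:
        span2 = (e2 - s2) % length + 1 + 2 * slop
        if span2 >= length:
            return True
        s2 = (s2 - slop) % length
        e2 = (e2 + slop) % length
    for a0, a1 in arc_intervals(s1, e1, length):
        for b0, b1 in arc_intervals(s2, e2, length):
            if a0 <= b1 and b0 <= a1:
                return True
    return False


def arc_contains(start: int, end: int, pos: int, length: int) -> bool:
    """Is position inside the inclusive forward arc [start, end]?"""
    return any(a0 <= pos % length <= a1 for a0, a1 in arc_intervals(start, end, length))


class MtAxis:
    """Oriented coordinate axis on the circular mt genome.

    Axis coordinate ``t`` increases in the fusion-forward reading direction of
    an integrated segment. For strand '+', ``t`` maps to circle position
    ``(anchor + t) mod L``; for strand '-', to ``(anchor - t) mod L`` with the
    base complemented. Between-base axis coordinate ``t`` maps to the circle
    between-base coordinate left of base(t).
    """

    def __init__(self, mt_seq: str, strand: str, anchor: int):
        if strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        self.seq = mt_seq
        self.L = len(mt_seq)
        self.strand = strand
        self.anchor = anchor % self.L

    def base_pos(self, t: int) -> int:
        """Circle index of the base at axis coordinate t."""
        if self.strand == "+":
            return (self.anchor + t) % self.L
        return (self.anchor - t) % self.L

    def base(self, t: int) -> str:
        b = self.seq[self.base_pos(t)]
        return b if self.strand == "+" else b.translate(_COMPLEMENT)

    def breakpoint_pos(self, t: int) -> int:
        """Circle between-base coordinate of axis between-base coordinate t.

        For strand '+' this is the boundary left of base(t); for strand '-'
        the boundary right of base(t) on the circle (i.e. left of it in axis
        direction).
        """
        if self.strand == "+":
            return (self.anchor + t) % self.L
        return (self.anchor - t + 1) % self.L
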