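"""Synthetic tumor/normal cohort generator with a planted-event truth set.

The generator emits reference alignments directly from generative
coordinates (no aligner involved): every read knows which haplotype block it
came from, so its SAM record (position, strand, soft clips at fusion
junctions) is exact by construction. This is what makes the whole analysis
runnable and testable without any download.

Planted integration anatomy
---------------------------
An integration inserts an mt segment (an arc on the circular mt genome,
possibly spanning the origin, either strand) at a nuclear position ``p``,
optionally deleting ``deletion`` nuclear bases at the site. Requested
microhomology of length ``m`` at a junction is engineered by copying the
first (last) ``m`` oriented segment bases into the abutting nuclear flank of
the *reference*, so that the junction is genuinely ambiguous over ``m``
bases against both references; the homologous run appears once in the
derived haplotype (derived length = nuclear + segment - mh). Nontemplated
insertions are short junction bases matching neither reference. After
construction, junctions are re-measured with the same homology rule the
caller uses and the *realized* coordinates/annotations are recorded as truth.

Reads are paired-end with Gaussian insert sizes (truncated at the read
length). Fragment counts per haplotype are deterministic
(``round(depth * L / (2 * read_len))``) so that mean depths — and hence the
mt copy-number estimate — are exact up to junction-clipping effects;
fragment positions are uniform. Sequencing errors are uniform substitutions.
"""

from __future__ import annotations

import dataclasses
import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .homology import measure_junction
from .seqio import Annotation, GenomeRef, MtAxis, RCRS_LENGTH, revcomp, write_bed, write_fasta

logger = logging.getLogger(__name__)

#: mt substitution polymorphisms carried by the simulated individual
#: (0-based position -> alternate allele), with the reference alleles the
#: genome builder pins at those positions.
DEFAULT_MT_VARIANTS: dict[int, str] = {
    14904: "A", 15027: "A", 15042: "A", 15325: "G", 15451: "A", 15606: "G",
}
DEFAULT_MT_REF_ALLELES: dict[int, str] = {
    14904: "G", 15027: "C", 15042: "G", 15325: "A", 15451: "C", 15606: "A",
}

_BASES = "ACGT"


class ConstructionError(ValueError):
    """A planted junction could not be made consistent with both references."""


# ---------------------------------------------------------------------------
# Specs and truth records
# ---------------------------------------------------------------------------

@dataclass
class IntegrationSpec:
    """One planted mtDNA integration (germline or somatic)."""

    contig: str
    position: int                 # nuclear insertion point (0-based, between-base)
    mt_start: int                 # segment arc start on the circle (forward)
    mt_end: int                   # segment arc end, exclusive; may wrap the origin
    mt_strand: str = "+"
    mh: tuple[int, int] = (0, 0)  # requested microhomology per junction
    insertion: tuple[str, str] = ("", "")
    germline: bool = False
    deletion: int = 0             # nuclear span deleted at the site
    inversion: tuple[int, int] | None = None  # nearby nuclear inversion (SV co-occurrence)
    name: str = ""

    def seg_len(self, mt_len: int = RCRS_LENGTH) -> int:
        d = (self.mt_end - self.mt_start) % mt_len
        return d if d else mt_len

    def validate(self, mt_len: int = RCRS_LENGTH) -> None:
        if self.mt_strand not in "+-":
            raise ValueError("mt_strand must be '+' or '-'")
        sl = self.seg_len(mt_len)
        if not 1 <= sl <= mt_len:
            raise ValueError(f"segment length {sl} out of [1, {mt_len}]")
        for m, ins in zip(self.mh, self.insertion):
            if m < 0 or m > 10:
                raise ValueError("microhomology length must be in [0, 10]")
            if m > 0 and ins:
                raise ValueError("microhomology and nontemplated insertion are mutually exclusive at a junction")
            if len(ins) > 10:
                raise ValueError("nontemplated insertion longer than 10 bp")
        if sum(self.mh) >= sl:
            raise ValueError("requested microhomology consumes the whole segment")
        if self.deletion < 0:
            raise ValueError("deletion span must be >= 0")


@dataclass
class TruthJunction:
    """Realized (canonical) coordinates of one planted junction."""

    event_id: str
    side: int                 # 1 = segment start, 2 = segment end
    contig: str
    nuc_bp: int               # between-base nuclear breakpoint
    mt_bp: int                # between-base circle coordinate
    orientation: str          # (nuclear strand, mt strand) of supporting pairs, e.g. "+-"
    mh_len: int
    mh_seq: str
    insertion: str
    germline: bool


@dataclass
class TruthEvent:
    event_id: str
    spec: IntegrationSpec
    junctions: list[TruthJunction]

    @property
    def germline(self) -> bool:
        return self.spec.germline


@dataclass
class TruthSet:
    """Planted-event ledger: the oracle for every downstream stage."""

    events: list[TruthEvent]
    mt_len: int = RCRS_LENGTH
    seed: int | None = None

    @property
    def junctions(self) -> list[TruthJunction]:
        return [j for e in self.events for j in e.junctions]

    def somatic_events(self) -> list[TruthEvent]:
        return [e for e in self.events if not e.germline]

    def germline_events(self) -> list[TruthEvent]:
        return [e for e in self.events if e.germline]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.events:
            s = e.spec
            for j in e.junctions:
                rows.append({
                    "event_id": j.event_id, "side": j.side, "germline": int(j.germline),
                    "contig": j.contig, "nuc_bp": j.nuc_bp, "mt_bp": j.mt_bp,
                    "orientation": j.orientation, "mh_len": j.mh_len, "mh_seq": j.mh_seq,
                    "insertion": j.insertion, "seg_strand": s.mt_strand,
                    "spec_position": s.position, "spec_mt_start": s.mt_start,
                    "spec_mt_end": s.mt_end, "deletion": s.deletion,
                })
        return pd.DataFrame(rows)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @staticmethod
    def read(path: str | Path, mt_len: int = RCRS_LENGTH) -> "TruthSet":
        df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"mh_seq": str, "insertion": str})
        events: dict[str, TruthEvent] = {}
        for _, r in df.iterrows():
            eid = str(r["event_id"])
            if eid not in events:
                spec = IntegrationSpec(
                    contig=r["contig"], position=int(r["spec_position"]),
                    mt_start=int(r["spec_mt_start"]), mt_end=int(r["spec_mt_end"]),
                    mt_strand=r["seg_strand"], germline=bool(int(r["germline"])),
                    deletion=int(r["deletion"]), name=eid,
                )
                events[eid] = TruthEvent(event_id=eid, spec=spec, junctions=[])
            events[eid].junctions.append(TruthJunction(
                event_id=eid, side=int(r["side"]), contig=r["contig"],
                nuc_bp=int(r["nuc_bp"]), mt_bp=int(r["mt_bp"]),
                orientation=r["orientation"], mh_len=int(r["mh_len"]),
                mh_seq=str(r["mh_seq"]), insertion=str(r["insertion"]),
                germline=bool(int(r["germline"])),
            ))
        return TruthSet(events=list(events.values()), mt_len=mt_len)


@dataclass
class ReadSimConfig:
    """Read-generation parameters. ``mean_depth`` is the sample's mean autosomal depth."""

    read_len: int = 100
    insert_mean: float = 350.0
    insert_sd: float = 50.0
    mean_depth: float = 30.0
    cmt: float = 495.0            # true mt copies per diploid cell
    error_rate: float = 0.0
    mt_variants: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_MT_VARIANTS))
    mapq: int = 60
    mapq0_regions: list[tuple[str, int, int]] = field(default_factory=list)
    min_clip: int = 1             # junction overlap below which a read is not emitted clipped
    seed: int | None = None

    def validate(self) -> None:
        if min(self.read_len, self.insert_mean, self.mean_depth, self.cmt) <= 0:
            raise ValueError("read_len, insert_mean, mean_depth and cmt must be positive")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.insert_sd < 0:
            raise ValueError("insert_sd must be >= 0")


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

def build_genome(
    lengths: dict[str, int],
    gc: float = 0.5,
    seed: int = 0,
    mt_name: str = "MT",
    mt_len: int = RCRS_LENGTH,
    mt_ref_alleles: dict[int, str] | None = None,
) -> GenomeRef:
    """Random genome: the given nuclear contigs plus a circular mt contig.

    ``mt_ref_alleles`` pins specific mt reference bases so that a polymorphism
    list like :data:`DEFAULT_MT_VARIANTS` is guaranteed to be a substitution.
    """
    if any(l <= 0 for l in lengths.values()) or mt_len <= 0:
        raise ValueError("contig lengths must be positive")
    if mt_name in lengths:
        raise ValueError(f"{mt_name!r} is reserved for the mt contig")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    contigs: dict[str, str] = {}
    for name, L in lengths.items():
        contigs[name] = rng.choice(alphabet, size=L, p=p).tobytes().decode()
    mt = bytearray(rng.choice(alphabet, size=mt_len, p=p).tobytes())
    if mt_ref_alleles is None:
        mt_ref_alleles = DEFAULT_MT_REF_ALLELES if mt_len == RCRS_LENGTH else {}
    for pos, base in mt_ref_alleles.items():
        mt[pos] = ord(base)
    contigs[mt_name] = mt.decode()
    return GenomeRef(contigs=contigs, mt_name=mt_name)


def apply_variants(mt_seq: str, variants: dict[int, str]) -> str:
    out = bytearray(mt_seq, "ascii")
    for pos, alt in variants.items():
        out[pos] = ord(alt)
    return out.decode()


# ---------------------------------------------------------------------------
# Haplotype blocks
# ---------------------------------------------------------------------------

@dataclass
class Block:
    d_start: int
    d_end: int
    kind: str                  # 'nuc' | 'mt' | 'ins'
    contig: str | None
    ref_start: int
    ref_end: int
    strand: str = "+"


@dataclass
class Haplotype:
    name: str
    seq: str
    blocks: list[Block]

    @property
    def starts(self) -> list[int]:
        return [b.d_start for b in self.blocks]


def _axis_for(spec: IntegrationSpec, mt_ref: str) -> MtAxis:
    L = len(mt_ref)
    if spec.mt_strand == "+":
        return MtAxis(mt_ref, "+", spec.mt_start % L)
    return MtAxis(mt_ref, "-", (spec.mt_end - 1) % L)


def _force_breaks(nuc: bytearray, constraints: dict[int, set[str]], engineered: set[int]) -> None:
    """Make each constrained base differ from all its forbidden bases.

    A base may carry constraints from both junctions of a blunt insertion
    (at most two forbidden letters), so a valid letter always exists.
    Engineered (homology) bases are never touched: if a constraint falls on
    one, the accidental extension is simply measured into the realized truth.
    """
    for idx, forbidden in constraints.items():
        if idx < 0 or idx >= len(nuc) or idx in engineered:
            continue
        if chr(nuc[idx]) in forbidden:
            nuc[idx] = ord(next(b for b in _BASES if b not in forbidden))


def _fix_ins(ins: str, first_forbidden: str, last_forbidden: str) -> str:
    out = list(ins)
    if out and out[0] == first_forbidden:
        out[0] = next(b for b in _BASES if b != first_forbidden)
    if out and out[-1] == last_forbidden:
        forbid = {last_forbidden}
        if len(out) == 1:
            forbid.add(first_forbidden)
        out[-1] = next(b for b in _BASES if b not in forbid)
    return "".join(out)


def _engineer_event(nuc: bytearray, mt_ref: str, spec: IntegrationSpec,
                    engineered: set[int]) -> IntegrationSpec:
    """Edit the nuclear reference flanks so the requested junctions exist.

    Returns a copy of the spec with insertion strings adjusted to satisfy the
    no-absorption constraints. Reference edits are recorded in ``engineered``.
    """
    spec.validate(len(mt_ref))
    axis = _axis_for(spec, mt_ref)
    sl = spec.seg_len(len(mt_ref))
    p = spec.position
    p2 = p + spec.deletion
    m1, m2 = spec.mh
    ins1, ins2 = spec.insertion
    if p - m1 - 1 < 0 or p2 + m2 + 1 > len(nuc):
        raise ConstructionError("integration too close to a contig edge")

    # junction 1 (segment start): nuclear left, mt right
    for k in range(m1):
        nuc[p - m1 + k] = ord(axis.base(k))
        engineered.add(p - m1 + k)
    # junction 2 (segment end): mt left, nuclear right
    for k in range(m2):
        nuc[p2 + k] = ord(axis.base(sl - m2 + k))
        engineered.add(p2 + k)

    constraints: dict[int, set[str]] = {}
    if not ins1:
        constraints.setdefault(p - m1 - 1, set()).add(axis.base(-1))
        constraints.setdefault(p, set()).add(axis.base(m1))
    if not ins2:
        constraints.setdefault(p2 + m2, set()).add(axis.base(sl))
        constraints.setdefault(p2 - 1, set()).add(axis.base(sl - m2 - 1))
    _force_breaks(nuc, constraints, engineered)
    if ins1:
        ins1 = _fix_ins(ins1, chr(nuc[p]), axis.base(-1))
    if ins2:
        ins2 = _fix_ins(ins2, axis.base(sl), chr(nuc[p2 - 1]))

    return dataclasses.replace(spec, insertion=(ins1, ins2))


def _realize_truth(nuc_seq: str, mt_ref: str, spec: IntegrationSpec, event_id: str) -> TruthEvent:
    """Measure realized junction coordinates/annotations on the edited references."""
    axis = _axis_for(spec, mt_ref)
    sl = spec.seg_len(len(mt_ref))
    p, p2 = spec.position, spec.position + spec.deletion
    m1, m2 = spec.mh
    ins1, ins2 = spec.insertion
    ori1 = "+-" if spec.mt_strand == "+" else "++"
    ori2 = "-+" if spec.mt_strand == "+" else "--"

    if ins1:
        j1 = TruthJunction(event_id, 1, spec.contig, p, axis.breakpoint_pos(0),
                           ori1, 0, "", ins1, spec.germline)
    else:
        m = measure_junction(nuc_seq, p, axis, m1, "L")
        j1 = TruthJunction(event_id, 1, spec.contig, m.nuc_bp,
                           axis.breakpoint_pos(m.mt_axis_bp), ori1,
                           m.mh_len, m.mh_seq, "", spec.germline)
    if ins2:
        j2 = TruthJunction(event_id, 2, spec.contig, p2, axis.breakpoint_pos(sl),
                           ori2, 0, "", ins2, spec.germline)
    else:
        m = measure_junction(nuc_seq, p2, axis, sl - m2, "R")
        j2 = TruthJunction(event_id, 2, spec.contig, m.nuc_bp,
                           axis.breakpoint_pos(m.mt_axis_bp), ori2,
                           m.mh_len, m.mh_seq, "", spec.germline)
    return TruthEvent(event_id=event_id, spec=spec, junctions=[j1, j2])


def _mt_blocks(spec: IntegrationSpec, mt_len: int, d_off: int, m1: int, m2: int) -> tuple[list[Block], int]:
    """Reference blocks for the unique (non-shared) part of the oriented segment."""
    sl = spec.seg_len(mt_len)
    lo_trim = m1 if spec.mt_strand == "+" else m2
    hi_trim = m2 if spec.mt_strand == "+" else m1
    start = (spec.mt_start + lo_trim) % mt_len
    span = sl - m1 - m2
    blocks: list[Block] = []
    pos, remaining, d = start, span, d_off
    while remaining > 0:
        chunk = min(remaining, mt_len - pos)
        blocks.append(Block(d, d + chunk, "mt", None, pos, pos + chunk, spec.mt_strand))
        d += chunk
        pos = (pos + chunk) % mt_len
        remaining -= chunk
    if spec.mt_strand == "-":
        # derived order is the reverse of circle order: reverse block sequence
        out, d = [], d_off
        for b in reversed(blocks):
            ln = b.d_end - b.d_start
            out.append(Block(d, d + ln, "mt", None, b.ref_start, b.ref_end, "-"))
            d += ln
        blocks = out
    return blocks, span


def _oriented_segment(mt_hap: str, spec: IntegrationSpec, m1: int, m2: int) -> str:
    """Unique oriented segment bases drawn from the individual's mt haplotype."""
    L = len(mt_hap)
    sl = spec.seg_len(L)
    s = spec.mt_start % L
    seg = "".join(mt_hap[(s + i) % L] for i in range(sl)) if s + sl > L else mt_hap[s:s + sl]
    if spec.mt_strand == "-":
        seg = revcomp(seg)
    return seg[m1:sl - m2] if m2 else seg[m1:]


def build_haplotype(genome: GenomeRef, contig: str, specs: list[IntegrationSpec],
                    mt_hap: str, name: str) -> Haplotype:
    """Assemble a derived nuclear haplotype with the given events applied in order."""
    nuc = genome.contigs[contig]
    events = sorted((s for s in specs if s.contig == contig), key=lambda s: s.position)
    for a, b in zip(events, events[1:]):
        if a.position + a.deletion >= b.position:
            raise ConstructionError("planted events overlap")
    seq_parts: list[str] = []
    blocks: list[Block] = []
    cursor = 0   # reference coordinate
    d = 0        # derived coordinate
    for spec in events:
        p, p2 = spec.position, spec.position + spec.deletion
        m1, m2 = spec.mh
        if p > cursor:
            seq_parts.append(nuc[cursor:p])
            blocks.append(Block(d, d + p - cursor, "nuc", contig, cursor, p))
            d += p - cursor
        ins1, ins2 = spec.insertion
        if ins1:
            seq_parts.append(ins1)
            blocks.append(Block(d, d + len(ins1), "ins", None, 0, 0))
            d += len(ins1)
        mtb, span = _mt_blocks(spec, genome.mt_len, d, m1, m2)
        seq_parts.append(_oriented_segment(mt_hap, spec, m1, m2))
        blocks.extend(mtb)
        d += span
        if ins2:
            seq_parts.append(ins2)
            blocks.append(Block(d, d + len(ins2), "ins", None, 0, 0))
            d += len(ins2)
        cursor = p2
    if cursor < len(nuc):
        seq_parts.append(nuc[cursor:])
        blocks.append(Block(d, d + len(nuc) - cursor, "nuc", contig, cursor, len(nuc)))
        d += len(nuc) - cursor
    return Haplotype(name=name, seq="".join(seq_parts), blocks=blocks)


def plant_integration(genome: GenomeRef, spec: IntegrationSpec,
                      mt_variants: dict[int, str] | None = None,
                      event_id: str = "E1") -> tuple[str, TruthEvent]:
    """Plant a single integration: edits the genome's nuclear flanks in place
    and returns the derived haplotype sequence plus realized junction records."""
    mt_ref = genome.mt_seq
    nuc = bytearray(genome.contigs[spec.contig], "ascii")
    eng: set[int] = set()
    spec = _engineer_event(nuc, mt_ref, spec, eng)
    genome.contigs[spec.contig] = nuc.decode()
    truth = _realize_truth(genome.contigs[spec.contig], mt_ref, spec, event_id)
    mt_hap = apply_variants(mt_ref, mt_variants or {})
    hap = build_haplotype(genome, spec.contig, [spec], mt_hap, name=f"{spec.contig}:{event_id}")
    return hap.seq, truth


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

_FLAG_PAIRED, _FLAG_PROPER, _FLAG_MUNMAP = 0x1, 0x2, 0x8
_FLAG_REV, _FLAG_MREV, _FLAG_R1, _FLAG_R2 = 0x10, 0x20, 0x40, 0x80


@dataclass
class _Rec:
    contig: str
    pos: int
    flag: int
    mapq: int
    cigar: str
    rnext: str
    pnext: int
    tlen: int
    seq: str
    qname: str

    def line(self) -> str:
        return (f"{self.qname}\t{self.flag}\t{self.contig}\t{self.pos + 1}\t{self.mapq}\t"
                f"{self.cigar}\t{self.rnext}\t{self.pnext + 1}\t{self.tlen}\t{self.seq}\t*")


def _mapq_for(cfg: ReadSimConfig, contig: str, pos: int, end: int) -> int:
    for c, s, e in cfg.mapq0_regions:
        if c == contig and pos < e and end > s:
            return 0
    return cfg.mapq


def _map_read(hap: Haplotype, a: int, b: int, drawn_rev: bool, cfg: ReadSimConfig,
              starts: list[int]) -> tuple[str, int, int, str, bool, str] | None:
    """Map a derived-interval read to its primary reference alignment.

    Returns (contig, pos, end, cigar, is_reverse, stored_seq) or None if the
    read has no reference block overlap of at least ``min_clip`` bases.
    """
    i = bisect_right(starts, a) - 1
    over: list[tuple[int, Block]] = []
    j = i
    while j < len(hap.blocks) and hap.blocks[j].d_start < b:
        blk = hap.blocks[j]
        if blk.kind != "ins":
            ov = min(b, blk.d_end) - max(a, blk.d_start)
            if ov > 0:
                over.append((ov, blk))
        j += 1
    if not over:
        return None
    ov, blk = max(over, key=lambda t: (t[0], -t[1].d_start))
    qa, qb = max(a, blk.d_start), min(b, blk.d_end)
    m = qb - qa
    if m < max(cfg.min_clip, 1) or (m < (b - a) and m < cfg.min_clip):
        return None
    lc, rc = qa - a, b - qb
    raw = hap.seq[a:b]
    if blk.kind == "nuc" or blk.strand == "+":
        contig = blk.contig if blk.kind == "nuc" else None
        pos = blk.ref_start + (qa - blk.d_start)
        cig = (f"{lc}S" if lc else "") + f"{m}M" + (f"{rc}S" if rc else "")
        return (contig, pos, pos + m, cig, drawn_rev, raw)
    # reverse-strand mt block
    pos = blk.ref_start + (blk.d_end - qb)
    cig = (f"{rc}S" if rc else "") + f"{m}M" + (f"{lc}S" if lc else "")
    return (None, pos, pos + m, cig, not drawn_rev, revcomp(raw))


def _pair_records(hap: Haplotype, mt_name: str, st: int, isz: int, cfg: ReadSimConfig,
                  starts: list[int], qname: str) -> list[_Rec]:
    rl = cfg.read_len
    r1 = _map_read(hap, st, st + rl, False, cfg, starts)
    r2 = _map_read(hap, st + isz - rl, st + isz, True, cfg, starts)
    out: list[_Rec] = []
    for mine, other, isread1 in ((r1, r2, True), (r2, r1, False)):
        if mine is None:
            continue
        contig, pos, end, cig, rev, seq = mine
        contig = contig if contig is not None else mt_name
        flag = _FLAG_PAIRED | (_FLAG_R1 if isread1 else _FLAG_R2)
        if rev:
            flag |= _FLAG_REV
        if other is None:
            flag |= _FLAG_MUNMAP
            rnext, pnext, tlen = "=", pos, 0
        else:
            octg = other[0] if other[0] is not None else mt_name
            orev = other[4]
            if orev:
                flag |= _FLAG_MREV
            rnext = "=" if octg == contig else octg
            pnext = other[1]
            if octg == contig:
                lo, hi = min(pos, other[1]), max(end, other[2])
                tlen = (hi - lo) if pos <= other[1] else -(hi - lo)
                if (rev != orev and hi - lo <= cfg.insert_mean + 4 * cfg.insert_sd
                        and "S" not in cig and "S" not in other[3]):
                    flag |= _FLAG_PROPER
            else:
                tlen = 0
        out.append(_Rec(contig, pos, flag, _mapq_for(cfg, contig, pos, end), cig,
                        rnext, pnext, tlen, seq, qname))
    # proper flag must agree between mates
    if len(out) == 2 and ((out[0].flag & _FLAG_PROPER) != (out[1].flag & _FLAG_PROPER)):
        out[0].flag &= ~_FLAG_PROPER
        out[1].flag &= ~_FLAG_PROPER
    return out


def _apply_errors(seqs: list[str], rng: np.random.Generator, rate: float) -> list[str]:
    if rate <= 0 or not seqs:
        return seqs
    ks = rng.binomial([len(s) for s in seqs], rate)
    for i in np.nonzero(ks)[0]:
        s = list(seqs[i])
        for pos in rng.integers(0, len(s), size=ks[i]):
            cur = s[pos]
            s[pos] = _BASES[(_BASES.index(cur) + rng.integers(1, 4)) % 4] if cur in _BASES else "A"
        seqs[i] = "".join(s)
    return seqs


def _simulate_hap(hap: Haplotype, depth: float, cfg: ReadSimConfig, rng: np.random.Generator,
                  mt_name: str, qprefix: str, buckets: dict[str, list[tuple[np.ndarray, list[str]]]]) -> None:
    """Generate reads for one haplotype at the given mean depth into per-contig buckets."""
    L = len(hap.seq)
    rl = cfg.read_len
    n = int(round(depth * L / (2 * rl)))
    if n <= 0:
        return
    isz = np.rint(rng.normal(cfg.insert_mean, cfg.insert_sd, n)).astype(np.int64)
    isz = np.clip(isz, rl, L)
    st = np.floor(rng.random(n) * (L - isz + 1)).astype(np.int64)
    starts = hap.starts
    bounds = np.array([b.d_start for b in hap.blocks[1:]], dtype=np.int64)
    if bounds.size:
        crosses = np.searchsorted(bounds, st, side="right") != np.searchsorted(bounds, st + isz - 1, side="right")
    else:
        crosses = np.zeros(n, dtype=bool)

    # --- complex fragments: per-fragment mapping through the block table
    for k in np.nonzero(crosses)[0]:
        recs = _pair_records(hap, mt_name, int(st[k]), int(isz[k]), cfg, starts, f"{qprefix}{k}")
        seqs = _apply_errors([r.seq for r in recs], rng, cfg.error_rate)
        for r, s in zip(recs, seqs):
            r.seq = s
            buckets.setdefault(r.contig, []).append((np.array([r.pos]), [r.line()]))

    # --- simple fragments: whole fragment inside one block, vectorized
    simple = np.nonzero(~crosses)[0]
    if simple.size == 0:
        return
    bidx = (np.searchsorted(bounds, st[simple], side="right")) if bounds.size else np.zeros(simple.size, dtype=np.int64)
    for ib in np.unique(bidx):
        blk = hap.blocks[int(ib)]
        if blk.kind == "ins":
            continue
        sel = simple[bidx == ib]
        s0, i0 = st[sel], isz[sel]
        a1, a2 = s0, s0 + i0 - rl
        contig = blk.contig if blk.kind == "nuc" else mt_name
        if blk.kind == "nuc" or blk.strand == "+":
            p1 = blk.ref_start + (a1 - blk.d_start)
            p2 = blk.ref_start + (a2 - blk.d_start)
            f1, f2 = _FLAG_PAIRED | _FLAG_PROPER | _FLAG_MREV | _FLAG_R1, \
                     _FLAG_PAIRED | _FLAG_PROPER | _FLAG_REV | _FLAG_R2
            seqs1 = [hap.seq[a:a + rl] for a in a1]
            seqs2 = [hap.seq[a:a + rl] for a in a2]
        else:
            p1 = blk.ref_start + (blk.d_end - (a1 + rl))
            p2 = blk.ref_start + (blk.d_end - (a2 + rl))
            f1, f2 = _FLAG_PAIRED | _FLAG_PROPER | _FLAG_REV | _FLAG_R1, \
                     _FLAG_PAIRED | _FLAG_PROPER | _FLAG_MREV | _FLAG_R2
            seqs1 = [revcomp(hap.seq[a:a + rl]) for a in a1]
            seqs2 = [revcomp(hap.seq[a:a + rl]) for a in a2]
        seqs1 = _apply_errors(seqs1, rng, cfg.error_rate)
        seqs2 = _apply_errors(seqs2, rng, cfg.error_rate)
        tl = np.abs(p2 - p1) + rl
        sign1 = np.where(p1 <= p2, tl, -tl)
        cig = f"{rl}M"
        mq = cfg.mapq
        if cfg.mapq0_regions:
            mq1 = np.array([_mapq_for(cfg, contig, int(p), int(p) + rl) for p in p1])
            mq2 = np.array([_mapq_for(cfg, contig, int(p), int(p) + rl) for p in p2])
        else:
            mq1 = mq2 = None
        lines1 = [
            f"{qprefix}{k}\t{f1}\t{contig}\t{pp + 1}\t{mq if mq1 is None else mq1[z]}\t{cig}\t=\t{pm + 1}\t{t}\t{sq}\t*"
            for z, (k, pp, pm, t, sq) in enumerate(zip(sel, p1, p2, sign1, seqs1))
        ]
        lines2 = [
            f"{qprefix}{k}\t{f2}\t{contig}\t{pp + 1}\t{mq if mq2 is None else mq2[z]}\t{cig}\t=\t{pm + 1}\t{t}\t{sq}\t*"
            for z, (k, pp, pm, t, sq) in enumerate(zip(sel, p2, p1, -sign1, seqs2))
        ]
        buckets.setdefault(contig, []).append((p1, lines1))
        buckets.setdefault(contig, []).append((p2, lines2))


def simulate_alignments(genome: GenomeRef, haplotypes: list[tuple[Haplotype, float]],
                        cfg: ReadSimConfig, rng: np.random.Generator, out_path: str | Path) -> None:
    """Write a coordinate-sorted SAM for one sample.

    ``haplotypes`` pairs each haplotype with the mean depth it contributes.
    """
    cfg.validate()
    buckets: dict[str, list[tuple[np.ndarray, list[str]]]] = {}
    for hi, (hap, depth) in enumerate(haplotypes):
        _simulate_hap(hap, depth, cfg, rng, genome.mt_name, f"f{hi}_", buckets)
    with open(out_path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for name, seq in genome.contigs.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        fh.write("@PG\tID:mtfusion-simgen\tPN:mtfusion\n")
        for contig in genome.contigs:
            chunks = buckets.get(contig)
            if not chunks:
                continue
            pos = np.concatenate([c[0] for c in chunks])
            lines: list[str] = []
            for _, ls in chunks:
                lines.extend(ls)
            order = np.argsort(pos, kind="stable")
            fh.write("\n".join(lines[int(i)] for i in order))
            fh.write("\n")


# ---------------------------------------------------------------------------
# Cohort-level driver
# ---------------------------------------------------------------------------

def default_events() -> list[IntegrationSpec]:
    """The default planted scenario: six somatic integrations spanning the
    feature space (blunt joins, 1-4 bp microhomology, a nontemplated
    insertion, an origin-spanning segment, a near-full-length segment with a
    20 kb local deletion) plus two germline numts."""
    return [
        IntegrationSpec("chr1", 150_000, 2_000, 2_148, "+", (0, 0), name="E1"),
        IntegrationSpec("chr1", 400_000, 5_000, 6_000, "+", (1, 2),
                        inversion=(430_000, 460_000), name="E2"),
        IntegrationSpec("chr1", 700_000, 13_500, 15_660, "-", (3, 4), name="E3"),
        IntegrationSpec("chr1", 900_000, 8_000, 8_600, "+", (0, 0), germline=True, name="G1"),
        IntegrationSpec("chr2", 150_000, 3_000, 3_500, "+", (0, 1),
                        insertion=("ACGT", ""), name="E4"),
        IntegrationSpec("chr2", 400_000, 15_500, 936, "+", (2, 0), name="E5"),
        IntegrationSpec("chr2", 650_000, 7, 16_563, "+", (1, 1), deletion=20_000, name="E6"),
        IntegrationSpec("chr2", 900_000, 11_000, 11_800, "+", (0, 0), germline=True, name="G2"),
    ]


DEFAULT_GENOME_LENGTHS = {"chr1": 1_000_000, "chr2": 1_000_000}


def generate_te_annotations(genome: GenomeRef, rng: np.random.Generator,
                            coverage: float = 0.35) -> list[Annotation]:
    """RepeatMasker-style annotations: interval classes tiled at ~coverage."""
    labels = ["SINE", "LINE", "LTR", "Simple_repeat", "DNA"]
    out: list[Annotation] = []
    for contig in genome.nuclear_contigs():
        L = len(genome.contigs[contig])
        pos, k = 0, 0
        while pos < L:
            gap = int(rng.exponential(300 / coverage * (1 - coverage))) + 1
            length = int(rng.lognormal(5.5, 0.6)) + 20
            start = pos + gap
            end = min(start + length, L)
            if start >= L:
                break
            out.append(Annotation(contig, start, end, labels[k % len(labels)]))
            pos = end
            k += 1
    return out


@dataclass
class SimOutput:
    out_dir: Path
    genome: GenomeRef
    truth: TruthSet
    paths: dict[str, Path]


def simulate_cohort(out_dir: str | Path, seed: int, cfg: ReadSimConfig | None = None,
                    events: list[IntegrationSpec] | None = None,
                    genome_lengths: dict[str, int] | None = None,
                    gc: float = 0.5,
                    tumor_fraction: float = 1.0,
                    mt_len: int = RCRS_LENGTH) -> SimOutput:
    """Build genome, plant events, emit tumor/normal SAM plus all side files."""
    if not 0 < tumor_fraction <= 1:
        raise ValueError("tumor_fraction must be in (0, 1]")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = cfg or ReadSimConfig()
    cfg = dataclasses.replace(cfg, seed=seed)
    cfg.validate()
    events = default_events() if events is None else events
    lengths = dict(genome_lengths or DEFAULT_GENOME_LENGTHS)
    genome = build_genome(lengths, gc=gc, seed=seed, mt_len=mt_len)
    mt_ref = genome.mt_seq
    if mt_len != RCRS_LENGTH:
        cfg = dataclasses.replace(cfg, mt_variants={p: a for p, a in cfg.mt_variants.items() if p < mt_len})

    # engineer all events against the shared reference, then realize truth
    engineered: dict[str, set[int]] = {c: set() for c in genome.nuclear_contigs()}
    final_specs: list[IntegrationSpec] = []
    for spec in events:
        nuc = bytearray(genome.contigs[spec.contig], "ascii")
        final_specs.append(_engineer_event(nuc, mt_ref, spec, engineered[spec.contig]))
        genome.contigs[spec.contig] = nuc.decode()
    truth_events = []
    for i, spec in enumerate(final_specs):
        eid = spec.name or f"EV{i + 1}"
        truth_events.append(_realize_truth(genome.contigs[spec.contig], mt_ref, spec, eid))
    truth = TruthSet(events=truth_events, mt_len=mt_len, seed=seed)

    mt_hap_seq = apply_variants(mt_ref, cfg.mt_variants)
    mt_hap = Haplotype("mt", mt_hap_seq, [Block(0, mt_len, "mt", genome.mt_name, 0, mt_len, "+")])

    def nuclear_haps(specs: list[IntegrationSpec], tag: str) -> dict[str, Haplotype]:
        return {c: build_haplotype(genome, c, specs, mt_hap_seq, f"{c}:{tag}")
                for c in genome.nuclear_contigs()}

    ref_haps = nuclear_haps([], "ref")
    germ_haps = nuclear_haps([s for s in final_specs if s.germline], "germ")
    full_haps = nuclear_haps(final_specs, "full")

    d = cfg.mean_depth
    rng = np.random.default_rng(seed)
    tumor_haps: list[tuple[Haplotype, float]] = []
    normal_haps: list[tuple[Haplotype, float]] = []
    for c in genome.nuclear_contigs():
        tumor_haps.append((full_haps[c], tumor_fraction * d / 2))
        if tumor_fraction < 1:
            tumor_haps.append((germ_haps[c], (1 - tumor_fraction) * d / 2))
        tumor_haps.append((ref_haps[c], d / 2))
        normal_haps.append((germ_haps[c], d / 2))
        normal_haps.append((ref_haps[c], d / 2))
    tumor_haps.append((mt_hap, d * cfg.cmt / 2))
    normal_haps.append((mt_hap, d * cfg.cmt / 2))

    paths = {
        "ref": out / "ref.fa", "tumor": out / "tumor.sam", "normal": out / "normal.sam",
        "truth": out / "truth.tsv", "numts": out / "numts.bed", "te": out / "te.bed",
        "sv": out / "sv_breakpoints.tsv", "config": out / "sim_config.yaml",
    }
    write_fasta(genome, paths["ref"])
    simulate_alignments(genome, tumor_haps, cfg, rng, paths["tumor"])
    simulate_alignments(genome, normal_haps, cfg, rng, paths["normal"])
    truth.write(paths["truth"])

    numts: list[Annotation] = []
    for e in truth.germline_events():
        lo = min(j.nuc_bp for j in e.junctions) - 100
        hi = max(j.nuc_bp for j in e.junctions) + 100
        numts.append(Annotation(e.spec.contig, max(lo, 0), hi, "numt"))
    for c in genome.nuclear_contigs()[:2]:
        L = len(genome.contigs[c])
        numts.append(Annotation(c, L // 3, L // 3 + 400, "numt_decoy"))
    write_bed(numts, paths["numts"])
    write_bed(generate_te_annotations(genome, np.random.default_rng(seed + 1)), paths["te"])

    sv_rows = []
    for spec in final_specs:
        if spec.deletion:
            sv_rows.append({"contig": spec.contig, "pos": spec.position, "kind": "deletion"})
            sv_rows.append({"contig": spec.contig, "pos": spec.position + spec.deletion, "kind": "deletion"})
        if spec.inversion:
            sv_rows.append({"contig": spec.contig, "pos": spec.inversion[0], "kind": "inversion"})
            sv_rows.append({"contig": spec.contig, "pos": spec.inversion[1], "kind": "inversion"})
    pd.DataFrame(sv_rows, columns=["contig", "pos", "kind"]).to_csv(paths["sv"], sep="\t", index=False)

    cfg_dump = dataclasses.asdict(cfg)
    cfg_dump["tumor_fraction"] = tumor_fraction
    cfg_dump["genome_lengths"] = lengths
    cfg_dump["mt_len"] = mt_len
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg_dump, fh, sort_keys=True)
    return SimOutput(out_dir=out, genome=genome, truth=truth, paths=paths)
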