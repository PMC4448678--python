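"""Base-pair junction resolution from split reads.

Each surviving cluster is resolved by an exhaustive split search: for every
candidate read near the cluster, every split point (and short nontemplated
gap) is scored against the nuclear window and the orientation-consistent mt
window by substitution distance; the best admissible split places the
junction. The modal placement over supporting reads is the consensus, which
is then annotated with microhomology (maximal bidirectional extension
against both references) or a nontemplated insertion, and canonicalized so
the homologous run is assigned to the nuclear side.

Junction orientation follows the discordant-pair convention: the class
``(nuclear strand, mt strand)`` of supporting pairs. Classes with nuclear
strand '+' have their nuclear partner left of the fusion point; the mt
strand then encodes the reading direction of the integrated segment, which
is how two junctions of one insertion are recognized as complementary.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .discover import Cluster
from .homology import measure_junction
from .seqio import AlignedRead, GenomeRef, MtAxis, arc_contains, revcomp

logger = logging.getLogger(__name__)

MIN_SEED_DEFAULT = 20
MAX_GAP_DEFAULT = 10
CANDIDATE_RADIUS_DEFAULT = 1000
MIN_CLIP_DEFAULT = 20
PAIR_DISTANCE_DEFAULT = 1_000_000
SV_WINDOW_DEFAULT = 100_000


@dataclass
class Junction:
    """Nucleotide-resolution nuclear<->mt fusion junction (canonical placement)."""

    contig: str
    nuc_bp: int               # between-base nuclear breakpoint
    mt_bp: int                # between-base circle coordinate
    orientation: str          # (nuclear strand, mt strand)
    mh_len: int = 0
    mh_seq: str = ""
    insertion: str = ""
    split_support: int = 0
    discordant_support: int = 0
    ambiguous: bool = False
    sample: str = ""
    event_id: str = ""
    near_sv: bool = False

    @property
    def nuc_side(self) -> str:
        """'L' when the nuclear partner is left of the fusion point."""
        return "L" if self.orientation[0] == "+" else "R"


@dataclass
class IntegrationEvent:
    """One mtDNA insertion: two complementary junctions, or one if unresolved."""

    event_id: str
    contig: str
    junctions: list[Junction]
    seg_start: int | None = None   # forward arc of the uniquely inserted mt segment
    seg_end: int | None = None
    seg_strand: str | None = None
    seg_len: int | None = None
    sample: str = ""
    near_sv: bool = False


@dataclass
class SplitHit:
    """Best admissible split of one read."""

    read_orient: str          # '+' = stored sequence, '-' = reverse complement tried
    oriented_seq: str
    split_i: int              # read prefix length
    split_j: int              # suffix start; bases [i, j) are the nontemplated gap
    mismatches: int
    nuc_bp: int               # genomic between-base nuclear breakpoint
    mt_axis_bp: int           # between-base coordinate on the mt window axis
    insertion: str


@dataclass
class ResolvedJunction:
    junction: Junction
    hits: list[SplitHit]
    axis: MtAxis


# ---------------------------------------------------------------------------
# Candidate collection
# ---------------------------------------------------------------------------

def _near_cluster(r: AlignedRead, cluster: Cluster, mt_name: str, mt_len: int, radius: int) -> bool:
    if r.contig == cluster.contig:
        return r.end > cluster.nuc_start - radius and r.start < cluster.nuc_end + radius
    if r.contig == mt_name:
        lo = (cluster.mt_start - radius) % mt_len
        hi = (cluster.mt_end + radius) % mt_len
        span = (cluster.mt_end - cluster.mt_start) % mt_len + 2 * radius
        if span >= mt_len:
            return True
        return arc_contains(lo, hi, r.start, mt_len) or arc_contains(lo, hi, max(r.end - 1, 0), mt_len)
    return False


def collect_candidate_reads(source, cluster: Cluster, mt_name: str, mt_len: int,
                            radius: int = CANDIDATE_RADIUS_DEFAULT,
                            min_clip: int = MIN_CLIP_DEFAULT) -> list[AlignedRead]:
    """Soft-clipped (clip >= min_clip) or mate-unmapped reads near the cluster.

    ``source`` is either an iterable of :class:`AlignedRead` (e.g. a cached
    scan of the sample) or an indexed :class:`pysam.AlignmentFile`.
    """
    if isinstance(source, pysam.AlignmentFile):
        reads: list[AlignedRead] = []
        regions = [(cluster.contig, max(cluster.nuc_start - radius, 0), cluster.nuc_end + radius)]
        lo = (cluster.mt_start - radius) % mt_len
        hi = ((cluster.mt_end + radius) % mt_len) + 1
        if lo < hi:
            regions.append((mt_name, lo, hi))
        else:
            regions.extend([(mt_name, lo, mt_len), (mt_name, 0, hi)])
        for contig, s, e in regions:
            for rec in source.fetch(contig, s, min(e, source.get_reference_length(contig))):
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                reads.append(AlignedRead.from_pysam(rec))
    else:
        reads = [r for r in source if _near_cluster(r, cluster, mt_name, mt_len, radius)]
    out, seen = [], set()
    for r in reads:
        if r.clipped >= min_clip or r.mate_unmapped:
            key = (r.qname, r.is_read1, r.contig, r.start)
            if key not in seen:
                seen.add(key)
                out.append(r)
    return sorted(out, key=lambda r: (r.contig, r.start, r.qname))


# ---------------------------------------------------------------------------
# Split alignment
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _fit_tables(window: np.ndarray, read: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative mismatch table over all read frames against a window.

    Returns (cumz, total): ``cumz[k, s]`` is the mismatch count of read
    prefix of length ``s`` at frame ``k`` (frame offset in window =
    ``k - n``); positions outside the window count as mismatches.
    """
    n = len(read)
    pad = np.full(n, ord("#"), dtype=np.uint8)
    wp = np.concatenate([pad, window, pad])
    frames = np.lib.stride_tricks.sliding_window_view(wp, n)
    mism = frames != read
    cum = np.cumsum(mism, axis=1, dtype=np.int32)
    cumz = np.concatenate([np.zeros((cum.shape[0], 1), dtype=np.int32), cum], axis=1)
    return cumz, cumz[:, -1]


def _best_prefix(cumz: np.ndarray, w: int, n: int, s: int) -> tuple[int, int]:
    """(mismatches, frame) of the best fully-inside placement of prefix length s."""
    ks = slice(n, n + w - s + 1)
    col = cumz[ks, s]
    k = int(np.argmin(col))
    return int(col[k]), n + k


def _best_suffix(cumz: np.ndarray, total: np.ndarray, w: int, n: int, j: int) -> tuple[int, int]:
    """(mismatches, frame) of the best fully-inside placement of suffix starting at j."""
    # suffix occupies window offsets [t + j, t + n); need t + j >= 0, t + n <= w
    k_lo, k_hi = n - j, w  # frame k = t + n
    col = (total - cumz[:, j])[k_lo:k_hi + 1]
    k = int(np.argmin(col))
    return int(col[k]), k_lo + k


def split_align(read_seq: str, nuc_window: str, mt_window: str, orientation: str,
                min_seed: int = MIN_SEED_DEFAULT, max_mismatch: int | None = None,
                max_gap: int = MAX_GAP_DEFAULT) -> SplitHit | None:
    """Exhaustive best split of a read across the nuclear and mt windows.

    The cluster orientation fixes the assignment order (nuclear part first
    for classes with nuclear strand '+') and the mt window is assumed
    already oriented in the fusion-forward reading direction. Both the
    stored sequence and its reverse complement are tried. Returns None when
    no split with both parts >= min_seed reaches the mismatch tolerance
    (default: 5% of the read length, rounded up).
    """
    n = len(read_seq)
    if n < 2 * min_seed:
        return None
    if max_mismatch is None:
        max_mismatch = math.ceil(0.05 * n)
    nuclear_first = orientation[0] == "+"
    wn, wm = len(nuc_window), len(mt_window)
    nuc_enc, mt_enc = _encode(nuc_window), _encode(mt_window)

    best: tuple | None = None   # (mm, gap, -prefix_len, pre_frame, suf_frame, payload)
    for ro in "+-":
        seq = read_seq if ro == "+" else revcomp(read_seq)
        renc = _encode(seq)
        if nuclear_first:
            pre_cumz, pre_tot = _fit_tables(nuc_enc, renc)
            suf_cumz, suf_tot = _fit_tables(mt_enc, renc)
            w_pre, w_suf = wn, wm
        else:
            pre_cumz, pre_tot = _fit_tables(mt_enc, renc)
            suf_cumz, suf_tot = _fit_tables(nuc_enc, renc)
            w_pre, w_suf = wm, wn
        pre_best = {s: _best_prefix(pre_cumz, w_pre, n, s) for s in range(min_seed, n - min_seed + 1)}
        suf_best = {j: _best_suffix(suf_cumz, suf_tot, w_suf, n, j) for j in range(min_seed, n - min_seed + 1)}
        for s, (mm_p, k_p) in pre_best.items():
            for g in range(0, max_gap + 1):
                j = s + g
                if j not in suf_best:
                    continue
                mm_s, k_s = suf_best[j]
                mm = mm_p + mm_s
                if mm > max_mismatch:
                    continue
                key = (mm, g, n - s, k_p - n, k_s - n, 0 if ro == "+" else 1)
                if best is None or key < best[0]:
                    t_pre, t_suf = k_p - n, k_s - n
                    if nuclear_first:
                        payload = (ro, seq, s, j, mm, t_pre + s, t_suf + j, seq[s:j])
                    else:
                        payload = (ro, seq, s, j, mm, t_suf + j, t_pre + s, seq[s:j])
                    best = (key, payload)
    if best is None:
        return None
    ro, seq, s, j, mm, nuc_off, mt_off, gap_seq = best[1]
    return SplitHit(read_orient=ro, oriented_seq=seq, split_i=s, split_j=j, mismatches=mm,
                    nuc_bp=nuc_off, mt_axis_bp=mt_off, insertion=gap_seq)


# ---------------------------------------------------------------------------
# Junction resolution
# ---------------------------------------------------------------------------

def _windows_for_cluster(cluster: Cluster, genome: GenomeRef, pad: int,
                         read_len_hint: int = 150) -> tuple[int, str, MtAxis, str]:
    """Nuclear window (start, seq) and oriented mt window (axis, seq)."""
    L = genome.mt_len
    pad = pad + read_len_hint
    nuc_seq = genome.contigs[cluster.contig]
    n_lo = max(cluster.nuc_start - pad, 0)
    n_hi = min(cluster.nuc_end + pad, len(nuc_seq))
    span = (cluster.mt_end - cluster.mt_start) % L + 1 + 2 * pad
    span = min(span, L)
    fwd = cluster.orientation[0] != cluster.orientation[1]
    if fwd:
        axis = MtAxis(genome.mt_seq, "+", (cluster.mt_start - pad) % L)
    else:
        axis = MtAxis(genome.mt_seq, "-", (cluster.mt_end + pad) % L)
    mt_window = "".join(axis.base(t) for t in range(span))
    return n_lo, nuc_seq[n_lo:n_hi], axis, mt_window


def resolve_junction(cluster: Cluster, reads: Sequence[AlignedRead], genome: GenomeRef,
                     min_seed: int = MIN_SEED_DEFAULT, max_gap: int = MAX_GAP_DEFAULT,
                     max_mismatch: int | None = None,
                     pad: int = CANDIDATE_RADIUS_DEFAULT,
                     sample: str = "") -> ResolvedJunction | None:
    """Consensus junction for one cluster from candidate split reads.

    The modal (nuclear, mt, insertion) placement over admissible splits wins;
    ties are broken toward higher split support, then the leftmost nuclear
    coordinate, and flagged ambiguous. Returns None when no read yields an
    admissible split (the cluster stays unresolved).
    """
    n_lo, nuc_window, axis, mt_window = _windows_for_cluster(cluster, genome, pad)
    placements: list[tuple[tuple[int, int, str], SplitHit]] = []
    for r in reads:
        if not r.seq:
            continue
        hit = split_align(r.seq, nuc_window, mt_window, cluster.orientation,
                          min_seed=min_seed, max_mismatch=max_mismatch, max_gap=max_gap)
        if hit is None:
            continue
        hit.nuc_bp += n_lo
        placements.append(((hit.nuc_bp, hit.mt_axis_bp, hit.insertion), hit))
    if not placements:
        return None
    counts = Counter(p for p, _ in placements)
    top = max(counts.values())
    modal = sorted([p for p, c in counts.items() if c == top])
    key = modal[0]
    ambiguous = len(modal) > 1
    hits = [h for p, h in placements if p == key]
    nuc_bp, mt_axis_bp, ins = key
    side = "L" if cluster.orientation[0] == "+" else "R"
    if ins:
        mh_len, mh_seq = 0, ""
    else:
        m = measure_junction(genome.contigs[cluster.contig], nuc_bp, axis, mt_axis_bp, side)
        nuc_bp, mt_axis_bp, mh_len, mh_seq = m.nuc_bp, m.mt_axis_bp, m.mh_len, m.mh_seq
    junction = Junction(
        contig=cluster.contig, nuc_bp=nuc_bp, mt_bp=axis.breakpoint_pos(mt_axis_bp),
        orientation=cluster.orientation, mh_len=mh_len, mh_seq=mh_seq, insertion=ins,
        split_support=top, discordant_support=cluster.support, ambiguous=ambiguous,
        sample=sample or cluster.sample,
    )
    return ResolvedJunction(junction=junction, hits=hits, axis=axis)


# ---------------------------------------------------------------------------
# Polymorphism concordance
# ---------------------------------------------------------------------------

@dataclass
class PolymorphismCheck:
    position: int             # 0-based circle position
    expected_alt: str
    observed: str | None      # majority allele over junction reads, None if uncovered
    n_reads: int
    status: str               # 'match' | 'mismatch' | 'uncovered'


def check_polymorphisms(resolved: ResolvedJunction, variants: dict[int, str],
                        mt_len: int) -> list[PolymorphismCheck]:
    """Compare mt alleles carried by junction-supporting reads to the expected list."""
    comp = dict(zip("ACGTN", "TGCAN"))
    alleles: dict[int, Counter] = {v: Counter() for v in variants}
    for h in resolved.hits:
        t0 = h.mt_axis_bp if resolved.junction.nuc_side == "L" else h.mt_axis_bp - (h.split_i)
        # mt part occupies axis offsets [t0, t0 + part_len)
        if resolved.junction.nuc_side == "L":
            part = h.oriented_seq[h.split_j:]
        else:
            part = h.oriented_seq[:h.split_i]
            t0 = h.mt_axis_bp - len(part)
        for i, base in enumerate(part):
            pos = resolved.axis.base_pos(t0 + i)
            if pos in alleles:
                alleles[pos][base if resolved.axis.strand == "+" else comp.get(base, "N")] += 1
    out = []
    for pos, alt in sorted(variants.items()):
        c = alleles[pos]
        if not c:
            out.append(PolymorphismCheck(pos, alt, None, 0, "uncovered"))
        else:
            obs, _ = max(c.items(), key=lambda kv: (kv[1], kv[0]))
            out.append(PolymorphismCheck(pos, alt, obs, sum(c.values()),
                                         "match" if obs == alt else "mismatch"))
    return out


# ---------------------------------------------------------------------------
# Pairing junctions into events
# ---------------------------------------------------------------------------

def pair_junctions(junctions: Sequence[Junction], mt_len: int,
                   max_pair_distance: int = PAIR_DISTANCE_DEFAULT) -> list[IntegrationEvent]:
    """Greedily pair complementary junctions into integration events.

    Two junctions pair when they lie on the same nuclear contig within
    ``max_pair_distance``, have complementary orientations (one nuclear-left,
    one nuclear-right, with opposite mt strands), and thus delimit a single
    arc on the circle. Unpaired junctions become single-junction events.
    """
    left = [j for j in junctions if j.orientation[0] == "+"]
    right = [j for j in junctions if j.orientation[0] == "-"]
    cands = []
    for jl in left:
        for jr in right:
            if jl.contig != jr.contig or jl.orientation[1] == jr.orientation[1]:
                continue
            d = abs(jl.nuc_bp - jr.nuc_bp)
            if d <= max_pair_distance:
                cands.append((d, jl.nuc_bp, jr.nuc_bp, jl, jr))
    cands.sort(key=lambda t: (t[0], t[1], t[2]))
    used: set[int] = set()
    events: list[IntegrationEvent] = []
    for d, _, _, jl, jr in cands:
        if id(jl) in used or id(jr) in used:
            continue
        used.update((id(jl), id(jr)))
        strand = "+" if jl.orientation == "+-" else "-"
        if strand == "+":
            s, e = jl.mt_bp, jr.mt_bp
        else:
            s, e = jr.mt_bp, jl.mt_bp
        seg_len = (e - s) % mt_len or mt_len
        events.append(IntegrationEvent(
            event_id="", contig=jl.contig, junctions=[jl, jr],
            seg_start=s, seg_end=e, seg_strand=strand, seg_len=seg_len,
            sample=jl.sample or jr.sample,
        ))
    for j in junctions:
        if id(j) not in used:
            events.append(IntegrationEvent(event_id="", contig=j.contig, junctions=[j],
                                           sample=j.sample))
    events.sort(key=lambda e: (e.contig, min(j.nuc_bp for j in e.junctions)))
    for i, e in enumerate(events, start=1):
        e.event_id = f"EV{i}"
        for j in e.junctions:
            j.event_id = e.event_id
    return events


def flag_nearby_rearrangements(events: Sequence[IntegrationEvent],
                               sv_breakpoints: Sequence[tuple[str, int]],
                               window: int = SV_WINDOW_DEFAULT) -> list[IntegrationEvent]:
    """Flag events with a nuclear SV breakpoint within ``window`` of a junction."""
    for e in events:
        e.near_sv = any(
            c == e.contig and abs(pos - j.nuc_bp) <= window
            for (c, pos) in sv_breakpoints for j in e.junctions
        )
        for j in e.junctions:
            j.near_sv = e.near_sv
    return list(events)


# ---------------------------------------------------------------------------
# Tables and VCF-BND output
# ---------------------------------------------------------------------------

def junctions_to_frame(junctions: Iterable[Junction]) -> pd.DataFrame:
    rows = [{
        "sample": j.sample, "event_id": j.event_id, "contig": j.contig, "nuc_bp": j.nuc_bp,
        "mt_bp": j.mt_bp, "orientation": j.orientation, "mh_len": j.mh_len, "mh_seq": j.mh_seq,
        "insertion": j.insertion, "split_support": j.split_support,
        "discordant_support": j.discordant_support, "ambiguous": int(j.ambiguous),
        "near_sv": int(j.near_sv),
    } for j in junctions]
    return pd.DataFrame(rows, columns=["sample", "event_id", "contig", "nuc_bp", "mt_bp",
                                       "orientation", "mh_len", "mh_seq", "insertion",
                                       "split_support", "discordant_support", "ambiguous", "near_sv"])


def read_junctions(path) -> list[Junction]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [Junction(contig=str(r["contig"]), nuc_bp=int(r["nuc_bp"]), mt_bp=int(r["mt_bp"]),
                     orientation=str(r["orientation"]), mh_len=int(r["mh_len"]),
                     mh_seq=str(r["mh_seq"]), insertion=str(r["insertion"]),
                     split_support=int(r["split_support"]),
                     discordant_support=int(r["discordant_support"]),
                     ambiguous=bool(int(r["ambiguous"])), sample=str(r["sample"]),
                     event_id=str(r["event_id"]), near_sv=bool(int(r["near_sv"])))
            for _, r in df.iterrows()]


def events_to_frame(events: Iterable[IntegrationEvent]) -> pd.DataFrame:
    rows = []
    for e in events:
        nucs = sorted(j.nuc_bp for j in e.junctions)
        rows.append({
            "event_id": e.event_id, "sample": e.sample, "contig": e.contig,
            "n_junctions": len(e.junctions), "nuc_bp_1": nucs[0],
            "nuc_bp_2": nucs[1] if len(nucs) > 1 else "",
            "seg_start": e.seg_start if e.seg_start is not None else "",
            "seg_end": e.seg_end if e.seg_end is not None else "",
            "seg_strand": e.seg_strand or "", "seg_len": e.seg_len if e.seg_len is not None else "",
            "near_sv": int(e.near_sv),
        })
    return pd.DataFrame(rows, columns=["event_id", "sample", "contig", "n_junctions",
                                       "nuc_bp_1", "nuc_bp_2", "seg_start", "seg_end",
                                       "seg_strand", "seg_len", "near_sv"])


def write_vcf_bnd(junctions: Sequence[Junction], genome: GenomeRef, path) -> None:
    """Write junctions as VCF 4.2 breakend records (MATEID-paired per event)."""
    lines = ["##fileformat=VCFv4.2",
             "##source=mtfusion",
             '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
             '##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend">',
             '##INFO=<ID=MHLEN,Number=1,Type=Integer,Description="Microhomology length">',
             '##INFO=<ID=INSSEQ,Number=1,Type=String,Description="Nontemplated insertion">']
    for name, seq in genome.contigs.items():
        lines.append(f"##contig=<ID={name},length={len(seq)}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    by_event: dict[str, list[Junction]] = {}
    for j in junctions:
        by_event.setdefault(j.event_id or f"J{id(j)}", []).append(j)
    for eid, js in sorted(by_event.items()):
        for k, j in enumerate(js):
            jid = f"{eid}_bnd{k + 1}"
            mate = f"{eid}_bnd{2 - k}" if len(js) == 2 else "."
            # anchor base: last nuclear base for nuclear-left, first for nuclear-right
            if j.nuc_side == "L":
                pos = j.nuc_bp  # 1-based position of base nuc_bp-1
                ref = genome.contigs[j.contig][j.nuc_bp - 1]
                mt_side = f"{genome.mt_name}:{j.mt_bp + 1}"
                alt = f"{ref}{j.insertion}[{mt_side}[" if j.orientation[1] == "-" else f"{ref}{j.insertion}]{mt_side}]"
            else:
                pos = j.nuc_bp + 1
                ref = genome.contigs[j.contig][j.nuc_bp]
                mt_side = f"{genome.mt_name}:{j.mt_bp}"
                alt = f"]{mt_side}]{j.insertion}{ref}" if j.orientation[1] == "+" else f"[{mt_side}[{j.insertion}{ref}"
            info = f"SVTYPE=BND;MATEID={mate};MHLEN={j.mh_len}"
            if j.insertion:
                info += f";INSSEQ={j.insertion}"
            lines.append(f"{j.contig}\t{pos}\t{jid}\t{ref}\t{alt}\t.\tPASS\t{info}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
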