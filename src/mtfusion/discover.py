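"""Discordant read-pair extraction and clustering.

A discordant pair has one end uniquely aligned to the mt genome and the
other to a nuclear contig, both with mapping quality greater than zero.
Pairs are clustered within orientation class — the (nuclear strand,
mt strand) tuple, four classes — by single linkage: two pairs link when
their nuclear positions are within the clustering window AND their mt
positions are within the window by circular distance. Clusters below the
support threshold (default: five discordant reads) are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .seqio import AlignedRead, circ_dist

logger = logging.getLogger(__name__)

CLUSTER_WINDOW_DEFAULT = 500
MIN_SUPPORT_DEFAULT = 5


@dataclass(frozen=True)
class DiscordantPair:
    """One nuclear-end / mt-end read pair."""

    qname: str
    contig: str
    nuc_pos: int
    nuc_strand: str
    nuc_mapq: int
    mt_pos: int
    mt_strand: str
    mt_mapq: int

    @property
    def orientation(self) -> str:
        return self.nuc_strand + self.mt_strand


@dataclass
class Cluster:
    """A group of discordant pairs pointing at one putative junction."""

    contig: str
    nuc_start: int
    nuc_end: int               # half-open over member nuclear positions
    mt_start: int              # inclusive arc endpoints on the circle (forward arc)
    mt_end: int
    orientation: str
    members: list[DiscordantPair] = field(default_factory=list)
    sample: str = ""

    @property
    def support(self) -> int:
        return len({m.qname for m in self.members})


def extract_discordant(reads: Iterable[AlignedRead], mt_name: str) -> list[DiscordantPair]:
    """Collect mt<->nuclear pairs with both ends mapped at mapq > 0.

    Both mates must be present in the stream (each contributes its own mapq);
    duplicate read names collapse to one pair.
    """
    half: dict[str, AlignedRead] = {}
    pairs: dict[str, DiscordantPair] = {}
    for r in reads:
        if not r.is_paired or r.mate_unmapped or r.mate_contig is None:
            continue
        if r.contig == r.mate_contig:
            continue
        if (r.contig == mt_name) == (r.mate_contig == mt_name):
            continue  # nuclear-nuclear interchromosomal (or mt-mt): not ours
        if r.qname in pairs:
            continue
        other = half.pop(r.qname, None)
        if other is None:
            half[r.qname] = r
            continue
        nuc, mt = (other, r) if r.contig == mt_name else (r, other)
        if nuc.contig == mt_name or mt.contig != mt_name:
            continue  # inconsistent mate info
        if nuc.mapq <= 0 or mt.mapq <= 0:
            continue
        pairs[r.qname] = DiscordantPair(
            qname=r.qname, contig=nuc.contig, nuc_pos=nuc.start, nuc_strand=nuc.strand,
            nuc_mapq=nuc.mapq, mt_pos=mt.start, mt_strand=mt.strand, mt_mapq=mt.mapq,
        )
    return sorted(pairs.values(), key=lambda p: (p.contig, p.nuc_pos, p.mt_pos, p.qname))


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _mt_arc(positions: list[int], mt_len: int) -> tuple[int, int]:
    """Smallest forward arc (inclusive endpoints) containing all positions."""
    pos = sorted(set(positions))
    if len(pos) == 1:
        return pos[0], pos[0]
    gaps = [(pos[i + 1] - pos[i], i) for i in range(len(pos) - 1)]
    gaps.append((pos[0] + mt_len - pos[-1], len(pos) - 1))
    _, imax = max(gaps, key=lambda t: (t[0], -t[1]))
    if imax == len(pos) - 1:
        return pos[0], pos[-1]
    return pos[imax + 1], pos[imax]


def cluster_pairs(pairs: Iterable[DiscordantPair], mt_len: int,
                  window: int = CLUSTER_WINDOW_DEFAULT, mode: str = "gap",
                  sample: str = "") -> list[Cluster]:
    """Single-linkage clustering of discordant pairs.

    mode='gap' (default): two pairs link when nuclear distance < window and
    circular mt distance < window; linkage is transitive, so a chain of
    sub-window gaps may span more than one window. mode='span' additionally
    starts a new cluster once the nuclear span would reach the window.
    """
    if mode not in ("gap", "span"):
        raise ValueError("mode must be 'gap' or 'span'")
    by_class: dict[tuple[str, str], list[DiscordantPair]] = {}
    for p in pairs:
        by_class.setdefault((p.contig, p.orientation), []).append(p)

    clusters: list[Cluster] = []
    for (contig, orient), grp in by_class.items():
        grp = sorted(grp, key=lambda p: (p.nuc_pos, p.mt_pos, p.qname))
        # one vote per fragment
        seen: set[str] = set()
        grp = [p for p in grp if not (p.qname in seen or seen.add(p.qname))]
        uf = _UnionFind(len(grp))
        for i in range(len(grp)):
            for j in range(i + 1, len(grp)):
                if grp[j].nuc_pos - grp[i].nuc_pos >= window:
                    break
                if circ_dist(grp[i].mt_pos, grp[j].mt_pos, mt_len) < window:
                    uf.union(i, j)
        comp: dict[int, list[DiscordantPair]] = {}
        for i, p in enumerate(grp):
            comp.setdefault(uf.find(i), []).append(p)
        for members in comp.values():
            if mode == "span":
                members_sorted = sorted(members, key=lambda p: (p.nuc_pos, p.mt_pos, p.qname))
                chunk: list[DiscordantPair] = []
                for p in members_sorted:
                    if chunk and p.nuc_pos - chunk[0].nuc_pos >= window:
                        clusters.append(_make_cluster(contig, orient, chunk, mt_len, sample))
                        chunk = []
                    chunk.append(p)
                if chunk:
                    clusters.append(_make_cluster(contig, orient, chunk, mt_len, sample))
            else:
                clusters.append(_make_cluster(contig, orient, members, mt_len, sample))
    clusters.sort(key=lambda c: (c.contig, c.nuc_start, c.mt_start, c.orientation))
    return clusters


def _make_cluster(contig: str, orient: str, members: list[DiscordantPair],
                  mt_len: int, sample: str) -> Cluster:
    members = sorted(members, key=lambda p: (p.nuc_pos, p.mt_pos, p.qname))
    arc = _mt_arc([m.mt_pos for m in members], mt_len)
    return Cluster(
        contig=contig,
        nuc_start=min(m.nuc_pos for m in members),
        nuc_end=max(m.nuc_pos for m in members) + 1,
        mt_start=arc[0], mt_end=arc[1],
        orientation=orient, members=members, sample=sample,
    )


def filter_support(clusters: Iterable[Cluster], min_support: int = MIN_SUPPORT_DEFAULT) -> list[Cluster]:
    """Keep clusters supported by at least ``min_support`` discordant reads."""
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    clusters = list(clusters)
    kept = [c for c in clusters if c.support >= min_support]
    logger.info("filter_support(min=%d): kept %d / %d clusters", min_support, len(kept), len(clusters))
    return kept


# ---------------------------------------------------------------------------
# TSV serialization
# ---------------------------------------------------------------------------

def clusters_to_frame(clusters: Iterable[Cluster]) -> pd.DataFrame:
    rows = []
    for c in clusters:
        rows.append({
            "contig": c.contig, "nuc_start": c.nuc_start, "nuc_end": c.nuc_end,
            "mt_start": c.mt_start, "mt_end": c.mt_end, "orientation": c.orientation,
            "support": c.support, "sample": c.sample,
            "read_names": ";".join(m.qname for m in c.members),
        })
    return pd.DataFrame(rows, columns=["contig", "nuc_start", "nuc_end", "mt_start",
                                       "mt_end", "orientation", "support", "sample", "read_names"])


def write_clusters(clusters: Iterable[Cluster], path) -> None:
    clusters_to_frame(clusters).to_csv(path, sep="\t", index=False)


def read_clusters(path) -> list[Cluster]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        c = Cluster(contig=str(r["contig"]), nuc_start=int(r["nuc_start"]), nuc_end=int(r["nuc_end"]),
                    mt_start=int(r["mt_start"]), mt_end=int(r["mt_end"]),
                    orientation=str(r["orientation"]), sample=str(r.get("sample", "")))
        names = str(r.get("read_names", "")).split(";") if r.get("read_names", "") else []
        c.members = [DiscordantPair(q, c.contig, c.nuc_start, c.orientation[0], 60,
                                    c.mt_start, c.orientation[1], 60) for q in names]
        out.append(c)
    return out
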