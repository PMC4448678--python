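"""Germline and artifact filtering of tumor clusters.

Inherited events and recurrent artifacts are removed by three subtractions:
clusters called from the matched normal (at the more tolerant support >= 2),
clusters from a panel of unmatched normals (same criteria per sample), and
known germline numt annotations. Cluster-vs-cluster subtraction requires
overlap on BOTH sides (nuclear interval and mt arc, each padded by ``slop``);
numt subtraction consults the nuclear side only, since a reference numt
locus attracts mt-like pairs regardless of which mt arc it resembles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .discover import Cluster, cluster_pairs, extract_discordant, filter_support
from .seqio import AlignedRead, Annotation, arcs_overlap

logger = logging.getLogger(__name__)

SLOP_DEFAULT = 500
NORMAL_MIN_SUPPORT = 2


@dataclass
class Removal:
    cluster: Cluster
    cause: str          # 'matched' | 'panel' | 'numt'
    blocker: object


def call_normal_clusters(reads: Iterable[AlignedRead], mt_name: str, mt_len: int,
                         window: int = 500, min_support: int = NORMAL_MIN_SUPPORT,
                         sample: str = "normal") -> list[Cluster]:
    """Cluster a normal sample's discordant pairs with tolerant support (>1 read)."""
    pairs = extract_discordant(reads, mt_name)
    return filter_support(cluster_pairs(pairs, mt_len, window=window, sample=sample), min_support)


def _clusters_overlap(a: Cluster, b: Cluster, slop: int, mt_len: int) -> bool:
    if a.contig != b.contig:
        return False
    if a.nuc_start - slop >= b.nuc_end + slop or b.nuc_start - slop >= a.nuc_end + slop:
        return False
    return arcs_overlap(a.mt_start, a.mt_end, b.mt_start, b.mt_end, mt_len, slop=slop)


def subtract_overlapping(tumor: Sequence[Cluster], blockers: Sequence[Cluster],
                         mt_len: int, slop: int = SLOP_DEFAULT,
                         cause: str = "matched") -> tuple[list[Cluster], list[Removal]]:
    """Drop tumor clusters overlapping a blocking (normal/panel) cluster on both sides."""
    retained: list[Cluster] = []
    removals: list[Removal] = []
    for t in tumor:
        hit = next((b for b in blockers if _clusters_overlap(t, b, slop, mt_len)), None)
        if hit is None:
            retained.append(t)
        else:
            removals.append(Removal(t, cause, hit))
    logger.info("subtract_overlapping(%s): removed %d / %d clusters", cause, len(removals), len(tumor))
    return retained, removals


def subtract_known_numts(tumor: Sequence[Cluster], numts: Sequence[Annotation],
                         slop: int = SLOP_DEFAULT) -> tuple[list[Cluster], list[Removal]]:
    """Drop tumor clusters whose nuclear interval (padded) hits a known-numt locus."""
    trees: dict[str, IntervalTree] = {}
    for a in numts:
        trees.setdefault(a.contig, IntervalTree()).addi(a.start, a.end, a)
    retained: list[Cluster] = []
    removals: list[Removal] = []
    for t in tumor:
        tree = trees.get(t.contig)
        hits = sorted(tree.overlap(max(t.nuc_start - slop, 0), t.nuc_end + slop)) if tree else []
        if hits:
            removals.append(Removal(t, "numt", hits[0].data))
        else:
            retained.append(t)
    logger.info("subtract_known_numts: removed %d / %d clusters", len(removals), len(tumor))
    return retained, removals
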