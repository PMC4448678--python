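"""Junction microhomology: the package's single measuring rule.

Microhomology at a nuclear<->mt fusion junction is the maximal run of bases
immediately at the junction that is identical to BOTH the nuclear reference
continuing past the nuclear breakpoint AND the mt reference continuing past
the mt breakpoint, read in the fusion orientation. It is measured by
extending left and right from a given junction placement; the total
(left + right extension) is the microhomology length.

Because any placement inside the homologous run describes the same physical
junction, placements are canonicalized so that the shared bases are assigned
to the *nuclear* side: for a junction whose nuclear partner lies left of the
fusion point the placement is shifted right by the right-extension, and
symmetrically for a nuclear-right junction. Canonical coordinates are what
the simulator records as truth and what the resolver reports, so exact
breakpoint comparison is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import MtAxis

MAX_EXTENSION = 100


@dataclass
class JunctionMeasure:
    """Canonicalized junction placement plus homology annotation."""

    nuc_bp: int        # between-base nuclear breakpoint, canonical
    mt_axis_bp: int    # between-base coordinate on the oriented mt axis, canonical
    mh_len: int
    mh_seq: str


def measure_junction(
    nuc_seq: str,
    nuc_bp: int,
    axis: MtAxis,
    mt_axis_bp: int,
    nuc_side: str,
    max_ext: int = MAX_EXTENSION,
) -> JunctionMeasure:
    """Measure homology extensions at a junction placement and canonicalize.

    Parameters
    ----------
    nuc_seq:
        Nuclear contig sequence.
    nuc_bp:
        Between-base nuclear breakpoint of the supplied placement.
    axis:
        Oriented mt axis (fusion-forward reading direction of the segment).
    mt_axis_bp:
        Between-base coordinate on ``axis`` of the supplied placement.
    nuc_side:
        ``'L'`` if the nuclear partner lies left of the fusion point in
        fusion-forward orientation, ``'R'`` otherwise.

    Notes
    -----
    Left extension ``l``: bases just left of the junction match the other
    partner's continuation leftward; right extension ``r`` symmetrically.
    ``mh_len = l + r`` regardless of side. The canonical shift assigns the
    homologous run to the nuclear side.
    """
    if nuc_side not in ("L", "R"):
        raise ValueError("nuc_side must be 'L' or 'R'")
    n = len(nuc_seq)

    def nuc_base(i: int) -> str | None:
        if 0 <= i < n:
            return nuc_seq[i]
        return None

    l = 0
    while l < max_ext:
        nb = nuc_base(nuc_bp - 1 - l)
        if nb is None or nb != axis.base(mt_axis_bp - 1 - l) or nb == "N":
            break
        l += 1
    r = 0
    while r < max_ext:
        nb = nuc_base(nuc_bp + r)
        if nb is None or nb != axis.base(mt_axis_bp + r) or nb == "N":
            break
        r += 1

    mh_len = l + r
    if nuc_side == "L":
        # shift right so homology bases sit in the nuclear part
        new_nuc = nuc_bp + r
        new_mt = mt_axis_bp + r
        mh_seq = nuc_seq[new_nuc - mh_len:new_nuc] if mh_len else ""
    else:
        # nuclear part is right of the junction: shift left
        new_nuc = nuc_bp - l
        new_mt = mt_axis_bp - l
        mh_seq = nuc_seq[new_nuc:new_nuc + mh_len] if mh_len else ""
    return JunctionMeasure(nuc_bp=new_nuc, mt_axis_bp=new_mt, mh_len=mh_len, mh_seq=mh_seq)
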