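"""Quantitative models: mt copy number, translocation rates, escape model,
positional/microhomology/TE enrichment, and primary/metastasis sharing.

Copy number: with RD_mt the mean mt depth and RD_auto the mean autosomal
depth of a (diploid) sample, the mt copies per diploid cell are
``Cmt = 2 * RD_mt / RD_auto``.

Rates per megabase per sample: for a nuclear chromosome,
``R_ch = N_ch / (2 * L_ch) / N_sam`` with L_ch the nonredundant chromosome
length in Mb (two copies per cell); for the mt genome,
``R_mt = N_mt / (Cmt * L_mt) / N_sam`` with L_mt = 0.016569 Mb.

Escape model: observed fusion events satisfy
``N_tr = N_sam * N_gen * rho_escape * rho_integration`` over N_gen cell
generations, giving the per-cell per-generation fusion rate as the product
of an escape rate (mtDNA reaching the nucleus) and an integration rate.

All chi-square tests are Pearson without continuity correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .breakpoints import IntegrationEvent
from .homology import measure_junction
from .seqio import Annotation, GenomeRef, MtAxis

logger = logging.getLogger(__name__)

MT_LENGTH_MB = 0.016569

#: Default mt-genome bins for breakpoint positional enrichment: seven 2-kb
#: intervals plus the arc spanning the origin (14 kb across 0 to 500 bp),
#: which contains the heavy-strand replication origin region.
DEFAULT_MT_BINS: list[tuple[int, int]] = [
    (500, 2_000), (2_000, 4_000), (4_000, 6_000), (6_000, 8_000),
    (8_000, 10_000), (10_000, 12_000), (12_000, 14_000), (14_000, 500),
]


# ---------------------------------------------------------------------------
# Copy number
# ---------------------------------------------------------------------------

@dataclass
class DepthSummary:
    rd_autosome: float
    rd_mt: float

    def __post_init__(self) -> None:
        if self.rd_autosome <= 0 or self.rd_mt <= 0:
            raise ValueError("mean depths must be positive")


@dataclass
class CopyNumberEstimate:
    cmt: float


def estimate_cmt(depths: DepthSummary) -> CopyNumberEstimate:
    """Mt copies per diploid cell from the mt/autosome depth ratio."""
    return CopyNumberEstimate(cmt=2.0 * depths.rd_mt / depths.rd_autosome)


def compute_depth_summary(path: str, mt_name: str) -> DepthSummary:
    """Mean aligned depth over nuclear contigs and the mt contig from a SAM/BAM."""
    with pysam.AlignmentFile(path, "rb" if str(path).endswith(".bam") else "r") as af:
        lengths = dict(zip(af.references, af.lengths))
        nuc_len = sum(l for c, l in lengths.items() if c != mt_name)
        mt_len = lengths.get(mt_name, 0)
        nuc_bases = mt_bases = 0
        for rec in af:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            aln = rec.query_alignment_length or 0
            if rec.reference_name == mt_name:
                mt_bases += aln
            else:
                nuc_bases += aln
    if nuc_len == 0 or mt_len == 0:
        raise ValueError("header must include nuclear and mt contigs")
    return DepthSummary(rd_autosome=nuc_bases / nuc_len, rd_mt=mt_bases / mt_len)


# ---------------------------------------------------------------------------
# Translocation rates
# ---------------------------------------------------------------------------

@dataclass
class NuclearRateInputs:
    junction_counts: dict[str, int]    # per-chromosome interchromosomal junction count
    lengths_mb: dict[str, float]       # nonredundant length per chromosome, Mb
    n_samples: int

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        for ch, n in self.junction_counts.items():
            if n < 0:
                raise ValueError(f"negative junction count for {ch}")
            if self.lengths_mb.get(ch, 0) <= 0:
                raise ValueError(f"missing or nonpositive length for {ch}")


@dataclass
class NuclearRates:
    per_chromosome: dict[str, float]
    genome_wide: float                 # total junctions / (2 * total Mb) / n_samples


def rate_nuclear(inputs: NuclearRateInputs) -> NuclearRates:
    inputs.validate()
    per = {ch: n / (2.0 * inputs.lengths_mb[ch]) / inputs.n_samples
           for ch, n in inputs.junction_counts.items()}
    total_n = sum(inputs.junction_counts.values())
    total_l = sum(inputs.lengths_mb[ch] for ch in inputs.junction_counts)
    return NuclearRates(per_chromosome=per,
                        genome_wide=total_n / (2.0 * total_l) / inputs.n_samples)


@dataclass
class MtRateInputs:
    n_junctions: int
    cmt: float
    n_samples: int
    l_mt_mb: float = MT_LENGTH_MB

    def validate(self) -> None:
        if self.n_junctions < 0 or self.cmt <= 0 or self.n_samples <= 0 or self.l_mt_mb <= 0:
            raise ValueError("invalid mt rate inputs")


def rate_mt(inputs: MtRateInputs) -> float:
    """Mt->nuclear junction rate per megabase of cellular mtDNA per sample."""
    inputs.validate()
    return inputs.n_junctions / (inputs.cmt * inputs.l_mt_mb) / inputs.n_samples


@dataclass
class EscapeRates:
    fusion_rate_pcpg: float            # rho_escape * rho_integration
    rho_escape: float
    rho_integration: float
    generations_per_escape: float


def escape_rates(n_events: int, n_samples: int, n_generations: int,
                 rho_integration: float = 0.1) -> EscapeRates:
    """Solve the escape model for the per-cell per-generation rates."""
    if n_samples <= 0 or n_generations <= 0:
        raise ValueError("n_samples and n_generations must be positive")
    if not 0 < rho_integration <= 1:
        raise ValueError("rho_integration must be in (0, 1]")
    product = n_events / (n_samples * n_generations)
    rho_escape = product / rho_integration
    return EscapeRates(fusion_rate_pcpg=product, rho_escape=rho_escape,
                       rho_integration=rho_integration,
                       generations_per_escape=1.0 / rho_escape if rho_escape > 0 else float("inf"))


def per_individual_generation_to_pcpg(rate_per_generation: float, cell_divisions: float = 100.0) -> float:
    """Convert a per-individual-generation germline rate to per cell generation."""
    if cell_divisions <= 0:
        raise ValueError("cell_divisions must be positive")
    return rate_per_generation / cell_divisions


# ---------------------------------------------------------------------------
# Enrichment tests
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    table: pd.DataFrame                # bins/categories with observed, expected, ratio
    chi2: float
    df: int
    p_value: float
    seed: int | None = None
    note: str = ""


def chi_square_gof(observed: Sequence[float], expected: Sequence[float]) -> tuple[float, int, float]:
    """Pearson goodness-of-fit chi-square (no continuity correction)."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if np.any(exp <= 0):
        raise ValueError("expected counts must be positive")
    if (exp < 5).any():
        logger.warning("chi-square with expected counts < 5")
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = len(obs) - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))


def mt_positional_enrichment(mt_breakpoints: Sequence[int], mt_len: int,
                             bins: Sequence[tuple[int, int]] | None = None) -> EnrichmentResult:
    """Observed vs length-proportional expected breakpoint counts per mt-genome bin.

    Bins are forward arcs [start, end) on the circle (a bin may span the
    origin) and must partition the circle.
    """
    bins = list(bins) if bins is not None else list(DEFAULT_MT_BINS)
    if not mt_breakpoints:
        raise ValueError("need at least one breakpoint")
    arc_len = [((e - s) % mt_len) or mt_len for s, e in bins]
    if sum(arc_len) != mt_len:
        raise ValueError("bins must partition the circle")
    obs = np.zeros(len(bins), dtype=float)
    for bp in mt_breakpoints:
        bp = bp % mt_len
        for i, (s, e) in enumerate(bins):
            off = (bp - s) % mt_len
            if off < arc_len[i]:
                obs[i] += 1
                break
    exp = np.array(arc_len, dtype=float) / mt_len * obs.sum()
    chi2, df, p = chi_square_gof(obs, exp)
    table = pd.DataFrame({
        "bin_start": [s for s, _ in bins], "bin_end": [e for _, e in bins],
        "arc_len": arc_len, "observed": obs, "expected": exp,
        "ratio": np.divide(obs, exp, out=np.full_like(obs, np.nan), where=exp > 0),
    })
    return EnrichmentResult(table=table, chi2=chi2, df=df, p_value=p)


_MH_CATS = ["0", "1", "2", "3", ">=4"]


def _mh_category_counts(mh_lengths: Sequence[int]) -> np.ndarray:
    counts = np.zeros(5, dtype=float)
    for m in mh_lengths:
        counts[min(m, 4)] += 1
    return counts


def analytic_mh_null() -> np.ndarray:
    """Single-sided geometric null: P(MH >= k) = 4**-k under uniform composition."""
    p = [0.25 ** k - 0.25 ** (k + 1) for k in range(4)]
    return np.array(p + [0.25 ** 4])


def sample_random_junction_mh(genome: GenomeRef, rng: np.random.Generator) -> int:
    """Microhomology of one random nuclear/mt junction under the package's rule."""
    contigs = genome.nuclear_contigs()
    lens = np.array([len(genome.contigs[c]) for c in contigs], dtype=float)
    c = contigs[rng.choice(len(contigs), p=lens / lens.sum())]
    nuc_bp = int(rng.integers(50, len(genome.contigs[c]) - 50))
    mt_bp = int(rng.integers(0, genome.mt_len))
    strand = "+" if rng.integers(2) else "-"
    side = "L" if rng.integers(2) else "R"
    axis = MtAxis(genome.mt_seq, strand, mt_bp)
    return measure_junction(genome.contigs[c], nuc_bp, axis, 0, side).mh_len


def microhomology_enrichment(mh_lengths: Sequence[int], null_model: str = "monte_carlo",
                             genome: GenomeRef | None = None, n_draws: int = 10_000,
                             seed: int = 0) -> EnrichmentResult:
    """Observed microhomology-length spectrum vs a random-junction null.

    null_model='analytic' uses the geometric model P(MH>=k)=4^-k;
    'monte_carlo' (default) re-draws random nuclear/mt breakpoint pairs on
    the provided genome and measures microhomology with the same rule used
    for real junctions.
    """
    n = len(mh_lengths)
    if n == 0:
        raise ValueError("no junctions")
    obs = _mh_category_counts(mh_lengths)
    if null_model == "analytic":
        probs = analytic_mh_null()
        note = "analytic geometric null"
    elif null_model == "monte_carlo":
        if genome is None:
            raise ValueError("monte_carlo null requires a genome")
        rng = np.random.default_rng(seed)
        draws = [sample_random_junction_mh(genome, rng) for _ in range(n_draws)]
        probs = _mh_category_counts(draws) / n_draws
        probs = np.clip(probs, 1e-12, None)
        probs = probs / probs.sum()
        note = f"monte_carlo null, {n_draws} draws"
    else:
        raise ValueError("null_model must be 'analytic' or 'monte_carlo'")
    exp = probs * n
    chi2, df, p = chi_square_gof(obs, exp)
    table = pd.DataFrame({"mh": _MH_CATS, "observed": obs, "expected": exp,
                          "ratio": obs / exp})
    return EnrichmentResult(table=table, chi2=chi2, df=df, p_value=p,
                            seed=seed if null_model == "monte_carlo" else None, note=note)


# ---------------------------------------------------------------------------
# Transposable-element proximity
# ---------------------------------------------------------------------------

TE_CATEGORIES = ["A", "B", "C", "D"]


def categorize_te_distance(distance: int) -> str:
    """A: inside a TE (distance 0); B: within 15 bp; C: 16-150 bp; D: beyond."""
    if distance == 0:
        return "A"
    if distance <= 15:
        return "B"
    if distance <= 150:
        return "C"
    return "D"


def nearest_te_distance(contig: str, pos: int, te_by_contig: dict[str, np.ndarray]) -> int:
    """Distance (bp) from a position to the nearest TE interval; 0 if inside."""
    iv = te_by_contig.get(contig)
    if iv is None or iv.size == 0:
        return 10 ** 9
    starts, ends = iv[:, 0], iv[:, 1]
    i = int(np.searchsorted(starts, pos, side="right")) - 1
    best = 10 ** 9
    if i >= 0:
        if pos < ends[i]:
            return 0
        best = min(best, pos - int(ends[i]) + 1)
    if i + 1 < len(starts):
        best = min(best, int(starts[i + 1]) - pos)
    return best


def _te_arrays(te: Sequence[Annotation]) -> dict[str, np.ndarray]:
    """Per-contig sorted, merged interval arrays (distance is to the union)."""
    by: dict[str, list[tuple[int, int]]] = {}
    for a in te:
        by.setdefault(a.contig, []).append((a.start, a.end))
    out: dict[str, np.ndarray] = {}
    for c, ivs in by.items():
        merged: list[list[int]] = []
        for s, e in sorted(ivs):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[c] = np.array(merged, dtype=np.int64)
    return out


def _n_runs(seq: str, min_len: int = 10) -> list[tuple[int, int]]:
    runs, start = [], None
    for i, b in enumerate(seq + "X"):
        if b == "N":
            if start is None:
                start = i
        elif start is not None:
            if i - start >= min_len:
                runs.append((start, i))
            start = None
    return runs


@dataclass
class TEProximityResult:
    observed: dict[str, int]
    simulated: dict[str, int]
    chi2: float
    df: int
    p_value: float
    seed: int
    n_simulated: int


def te_proximity_test(breakpoints: Sequence[tuple[str, int]], te: Sequence[Annotation],
                      genome: GenomeRef, n_factor: int = 40, seed: int = 0) -> TEProximityResult:
    """Observed vs in-silico breakpoint proximity to transposable elements.

    Simulated breakpoints are drawn uniformly per chromosome, ``n_factor``
    times the observed count on that chromosome; positions falling in
    reference N-gaps (runs >= 10 bp) are redrawn. The 2x4 observed-vs-
    simulated category table is compared by chi-square without correction.
    """
    if not te:
        logger.warning("empty TE annotation set: all breakpoints fall in category D")
    te_by = _te_arrays(te)
    rng = np.random.default_rng(seed)
    obs = {c: 0 for c in TE_CATEGORIES}
    for contig, pos in breakpoints:
        obs[categorize_te_distance(nearest_te_distance(contig, pos, te_by))] += 1
    sim = {c: 0 for c in TE_CATEGORIES}
    n_sim = 0
    gaps = {c: _n_runs(genome.contigs[c]) for c in genome.nuclear_contigs()}
    per_chrom = {}
    for contig, _ in breakpoints:
        per_chrom[contig] = per_chrom.get(contig, 0) + 1
    for contig, k in sorted(per_chrom.items()):
        L = len(genome.contigs[contig])
        need = k * n_factor
        drawn = 0
        while drawn < need:
            pos = int(rng.integers(0, L))
            if any(s <= pos < e for s, e in gaps.get(contig, [])):
                continue
            sim[categorize_te_distance(nearest_te_distance(contig, pos, te_by))] += 1
            drawn += 1
        n_sim += need
    obs_v = np.array([obs[c] for c in TE_CATEGORIES], dtype=float)
    sim_v = np.array([sim[c] for c in TE_CATEGORIES], dtype=float)
    keep = (obs_v + sim_v) > 0
    tab = np.vstack([obs_v[keep], sim_v[keep]])
    if tab.shape[1] < 2 or tab.sum() == 0:
        chi2, df, p = 0.0, 0, 1.0
    else:
        chi2, p, df, _ = stats.chi2_contingency(tab, correction=False)
    return TEProximityResult(observed=obs, simulated=sim, chi2=float(chi2), df=int(df),
                             p_value=float(p), seed=seed, n_simulated=n_sim)


# ---------------------------------------------------------------------------
# Primary / metastasis sharing
# ---------------------------------------------------------------------------

@dataclass
class SharedPartition:
    shared: list[tuple[IntegrationEvent, IntegrationEvent]]
    private_a: list[IntegrationEvent]
    private_b: list[IntegrationEvent]


def _events_match(a: IntegrationEvent, b: IntegrationEvent, tol: int) -> bool:
    if a.contig != b.contig or len(a.junctions) != len(b.junctions):
        return False
    ja = sorted(a.junctions, key=lambda j: j.nuc_bp)
    jb = sorted(b.junctions, key=lambda j: j.nuc_bp)
    return all(abs(x.nuc_bp - y.nuc_bp) <= tol and abs(x.mt_bp - y.mt_bp) <= tol
               and x.orientation == y.orientation
               for x, y in zip(ja, jb))


def compare_samples(events_a: Sequence[IntegrationEvent], events_b: Sequence[IntegrationEvent],
                    match_tolerance: int = 10) -> SharedPartition:
    """Partition two samples' events into shared and private sets."""
    used_b: set[int] = set()
    shared, private_a = [], []
    for ea in events_a:
        hit = next((eb for eb in events_b
                    if id(eb) not in used_b and _events_match(ea, eb, match_tolerance)), None)
        if hit is None:
            private_a.append(ea)
        else:
            used_b.add(id(hit))
            shared.append((ea, hit))
    private_b = [eb for eb in events_b if id(eb) not in used_b]
    return SharedPartition(shared=shared, private_a=private_a, private_b=private_b)
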