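"""End-to-end workflow: simulate -> detect -> filter -> breakpoints -> stats -> report.

Each sample's alignments are consumed in a single streaming pass that
accumulates mean depths, caches the mt<->nuclear discordant candidates, and
caches soft-clipped / mate-unmapped reads (the split-read candidates). The
stage funnel (clusters called, removed by matched normal / panel / known
numts, resolved to junctions) is logged and echoed into the report together
with every threshold, so a run is fully reproducible from its report
metadata.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

from . import breakpoints as bp
from . import discover, germline, rates, simgen
from .seqio import AlignedRead, GenomeRef, read_bed, read_fasta

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 11,
    "mt_name": "MT",
    "simulate": {
        "enabled": True,
        "genome": dict(simgen.DEFAULT_GENOME_LENGTHS),
        "mt_len": 16_569,
        "events": "default",
        "tumor_fraction": 1.0,
        "gc": 0.5,
        "read": {},          # ReadSimConfig overrides
    },
    "inputs": {              # used when simulate.enabled is false
        "ref": None, "tumor": None, "normal": None,
        "numts": None, "te": None, "sv": None, "truth": None, "panel": [],
    },
    "detect": {"window": 500, "min_support": 5, "mode": "gap"},
    "filter": {"slop": 500, "normal_min_support": 2},
    "breakpoints": {"radius": 1000, "min_clip": 20, "min_seed": 20, "max_gap": 10,
                    "max_mismatch": None, "pair_distance": 1_000_000, "sv_window": 100_000},
    "stats": {"mt_bins": "default", "mh_null": "monte_carlo", "mh_draws": 5000,
              "te_n_factor": 40, "nuclear_rates": None,
              "escape": {"n_generations": 1000, "rho_integration": 0.1}},
}


def merge_config(base: dict, override: dict | None) -> dict:
    out = {}
    for k, v in base.items():
        out[k] = dict(v) if isinstance(v, dict) else v
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = merge_config(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return merge_config(DEFAULT_CONFIG, {})
    with open(path) as fh:
        return merge_config(DEFAULT_CONFIG, yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# Sample scanning
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    depth: rates.DepthSummary
    pairs: list[discover.DiscordantPair]
    clipped: list[AlignedRead]
    n_records: int


def scan_sample(path: str | Path, mt_name: str, min_clip: int = 20) -> ScanResult:
    """One pass over a sample: depths, discordant candidates, split-read candidates."""
    nuc_bases = mt_bases = n = 0
    cross: list[AlignedRead] = []
    clipped: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), "rb" if str(path).endswith(".bam") else "r") as af:
        lengths = dict(zip(af.references, af.lengths))
        for rec in af:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            n += 1
            aln = rec.query_alignment_length or 0
            if rec.reference_name == mt_name:
                mt_bases += aln
            else:
                nuc_bases += aln
            interesting = False
            if rec.is_paired and not rec.mate_is_unmapped and rec.reference_id != rec.next_reference_id:
                if (rec.reference_name == mt_name) != (rec.next_reference_name == mt_name):
                    interesting = True
            clip = (rec.query_length or 0) - aln
            is_clipped = clip >= min_clip or (rec.is_paired and rec.mate_is_unmapped)
            if interesting or is_clipped:
                ar = AlignedRead.from_pysam(rec)
                if interesting:
                    cross.append(ar)
                if is_clipped:
                    clipped.append(ar)
    nuc_len = sum(l for c, l in lengths.items() if c != mt_name)
    mt_len = lengths.get(mt_name, 0)
    depth = rates.DepthSummary(rd_autosome=max(nuc_bases / nuc_len, 1e-9) if nuc_len else 1e-9,
                               rd_mt=max(mt_bases / mt_len, 1e-9) if mt_len else 1e-9)
    pairs = discover.extract_discordant(cross, mt_name)
    return ScanResult(depth=depth, pairs=pairs, clipped=clipped, n_records=n)


# ---------------------------------------------------------------------------
# Truth evaluation
# ---------------------------------------------------------------------------

def evaluate_against_truth(junctions: Sequence[bp.Junction], truth: simgen.TruthSet,
                           match_window: int = 50) -> dict[str, Any]:
    """Score resolved junctions against the planted (somatic) truth."""
    somatic = [j for j in truth.junctions if not j.germline]
    matched: list[tuple] = []
    used: set[int] = set()
    for tj in somatic:
        best = None
        for j in junctions:
            if id(j) in used or j.contig != tj.contig or j.orientation != tj.orientation:
                continue
            d = abs(j.nuc_bp - tj.nuc_bp)
            if d <= match_window and (best is None or d < best[0]):
                best = (d, j)
        if best is not None:
            used.add(id(best[1]))
            matched.append((tj, best[1]))
    n_exact = sum(1 for tj, j in matched if j.nuc_bp == tj.nuc_bp and j.mt_bp == tj.mt_bp)
    n_mh_exact = sum(1 for tj, j in matched
                     if j.mh_len == tj.mh_len and j.insertion == tj.insertion)
    events_hit = {tj.event_id for tj, _ in matched}
    somatic_events = {e.event_id for e in truth.somatic_events()}
    offsets = [abs(j.nuc_bp - tj.nuc_bp) + abs(j.mt_bp - tj.mt_bp) for tj, j in matched]
    return {
        "n_truth_junctions": len(somatic),
        "n_called_junctions": len(junctions),
        "n_matched": len(matched),
        "junction_recall": len(matched) / len(somatic) if somatic else 1.0,
        "event_recall": len(events_hit & somatic_events) / len(somatic_events) if somatic_events else 1.0,
        "precision": len(matched) / len(junctions) if junctions else 1.0,
        "n_breakpoint_exact": n_exact,
        "breakpoint_exact_fraction": n_exact / len(matched) if matched else 0.0,
        "n_mh_exact": n_mh_exact,
        "mh_exact_fraction": n_mh_exact / len(matched) if matched else 0.0,
        "max_offset": max(offsets) if offsets else None,
    }


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize_events(junctions: Sequence[bp.Junction],
                     events: Sequence[bp.IntegrationEvent]) -> dict[str, Any]:
    """Cohort-style summary: junction/event counts, microhomology and
    rearrangement-association percentages, segment-length range."""
    n_j = len(junctions)
    n_mh = sum(1 for j in junctions if j.mh_len >= 1)
    n_ins = sum(1 for j in junctions if j.insertion)
    n_sv = sum(1 for j in junctions if j.near_sv)
    seg_lens = [e.seg_len for e in events if e.seg_len is not None]
    return {
        "n_junctions": n_j,
        "n_events": len(events),
        "n_with_microhomology": n_mh,
        "pct_microhomology": 100.0 * n_mh / n_j if n_j else 0.0,
        "n_with_insertion": n_ins,
        "n_near_rearrangement": n_sv,
        "pct_near_rearrangement": 100.0 * n_sv / n_j if n_j else 0.0,
        "segment_length_min": min(seg_lens) if seg_lens else None,
        "segment_length_max": max(seg_lens) if seg_lens else None,
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, Path):
        return str(obj)
    return obj


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: dict | None = None, out_dir: str | Path = "run",
                 seed: int | None = None) -> dict[str, Any]:
    """Run the full workflow; returns the report dict (also written as JSON)."""
    cfg = merge_config(DEFAULT_CONFIG, config or {})
    if seed is not None:
        cfg["seed"] = seed
    seed = int(cfg["seed"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mt_name = cfg["mt_name"]
    report: dict[str, Any] = {"parameters": _jsonable(cfg), "stages": {}}

    # --- inputs / simulation
    if cfg["simulate"]["enabled"]:
        sim_cfg = simgen.ReadSimConfig(**cfg["simulate"]["read"])
        events = None if cfg["simulate"]["events"] == "default" else [
            simgen.IntegrationSpec(**e) for e in cfg["simulate"]["events"]]
        sim = simgen.simulate_cohort(
            out / "sim", seed=seed, cfg=sim_cfg, events=events,
            genome_lengths=cfg["simulate"]["genome"], gc=cfg["simulate"]["gc"],
            tumor_fraction=cfg["simulate"]["tumor_fraction"], mt_len=cfg["simulate"]["mt_len"])
        paths = {k: str(v) for k, v in sim.paths.items()}
        truth: simgen.TruthSet | None = sim.truth
        genome = sim.genome
        panel_paths: list[str] = []
    else:
        ins = cfg["inputs"]
        paths = {k: ins[k] for k in ("ref", "tumor", "normal", "numts", "te", "sv", "truth")}
        if not paths["ref"] or not paths["tumor"]:
            raise ValueError("inputs.ref and inputs.tumor are required when simulation is off")
        genome = read_fasta(paths["ref"], mt_name=mt_name)
        truth = simgen.TruthSet.read(paths["truth"]) if paths.get("truth") else None
        panel_paths = list(ins.get("panel") or [])
    mt_len = genome.mt_len
    report["inputs"] = {k: v for k, v in paths.items() if v}

    # --- detect
    det = cfg["detect"]
    tumor_scan = scan_sample(paths["tumor"], mt_name, min_clip=cfg["breakpoints"]["min_clip"])
    clusters = discover.cluster_pairs(tumor_scan.pairs, mt_len, window=det["window"],
                                      mode=det["mode"], sample="tumor")
    supported = discover.filter_support(clusters, det["min_support"])
    discover.write_clusters(supported, out / "clusters.tsv")
    report["stages"]["detect"] = {
        "n_discordant_pairs": len(tumor_scan.pairs),
        "n_clusters": len(clusters),
        "n_clusters_supported": len(supported),
    }

    # --- germline filtering
    flt = cfg["filter"]
    removals: list[germline.Removal] = []
    retained = supported
    normal_clusters: list[discover.Cluster] = []
    if paths.get("normal"):
        normal_scan = scan_sample(paths["normal"], mt_name, min_clip=cfg["breakpoints"]["min_clip"])
        normal_clusters = discover.filter_support(
            discover.cluster_pairs(normal_scan.pairs, mt_len, window=det["window"], sample="normal"),
            flt["normal_min_support"])
        retained, rem = germline.subtract_overlapping(retained, normal_clusters, mt_len,
                                                      slop=flt["slop"], cause="matched")
        removals.extend(rem)
    for p in panel_paths:
        panel_scan = scan_sample(p, mt_name, min_clip=cfg["breakpoints"]["min_clip"])
        pcl = discover.filter_support(
            discover.cluster_pairs(panel_scan.pairs, mt_len, window=det["window"], sample=str(p)),
            flt["normal_min_support"])
        retained, rem = germline.subtract_overlapping(retained, pcl, mt_len,
                                                      slop=flt["slop"], cause="panel")
        removals.extend(rem)
    if paths.get("numts"):
        numts = read_bed(paths["numts"])
        retained, rem = germline.subtract_known_numts(retained, numts, slop=flt["slop"])
        removals.extend(rem)
    discover.write_clusters(retained, out / "somatic_clusters.tsv")
    report["stages"]["filter"] = {
        "n_normal_clusters": len(normal_clusters),
        "n_removed_matched": sum(1 for r in removals if r.cause == "matched"),
        "n_removed_panel": sum(1 for r in removals if r.cause == "panel"),
        "n_removed_numt": sum(1 for r in removals if r.cause == "numt"),
        "n_somatic_clusters": len(retained),
    }

    # --- breakpoints
    bkp = cfg["breakpoints"]
    resolved: list[bp.ResolvedJunction] = []
    unresolved = 0
    for cl in retained:
        cand = bp.collect_candidate_reads(tumor_scan.clipped, cl, mt_name, mt_len,
                                          radius=bkp["radius"], min_clip=bkp["min_clip"])
        rj = bp.resolve_junction(cl, cand, genome, min_seed=bkp["min_seed"],
                                 max_gap=bkp["max_gap"], max_mismatch=bkp["max_mismatch"],
                                 pad=bkp["radius"], sample="tumor")
        if rj is None:
            unresolved += 1
        else:
            resolved.append(rj)
    junctions = [r.junction for r in resolved]
    events = bp.pair_junctions(junctions, mt_len, max_pair_distance=bkp["pair_distance"])
    sv_breakpoints: list[tuple[str, int]] = []
    if paths.get("sv"):
        sv_df = pd.read_csv(paths["sv"], sep="\t")
        sv_breakpoints = [(str(r["contig"]), int(r["pos"])) for _, r in sv_df.iterrows()]
    bp.flag_nearby_rearrangements(events, sv_breakpoints, window=bkp["sv_window"])
    bp.junctions_to_frame(junctions).to_csv(out / "junctions.tsv", sep="\t", index=False)
    bp.events_to_frame(events).to_csv(out / "events.tsv", sep="\t", index=False)
    bp.write_vcf_bnd(junctions, genome, out / "junctions.vcf")
    report["stages"]["breakpoints"] = {
        "n_resolved": len(junctions), "n_unresolved": unresolved, "n_events": len(events),
    }

    # --- polymorphism concordance (simulated cohorts carry a variant list)
    variants = {}
    if cfg["simulate"]["enabled"]:
        variants = simgen.ReadSimConfig(**cfg["simulate"]["read"]).mt_variants
        variants = {p: a for p, a in variants.items() if p < mt_len}
    if variants:
        checks = []
        for r in resolved:
            for c in bp.check_polymorphisms(r, variants, mt_len):
                checks.append({"junction": f"{r.junction.contig}:{r.junction.nuc_bp}",
                               "position": c.position, "expected_alt": c.expected_alt,
                               "observed": c.observed, "n_reads": c.n_reads, "status": c.status})
        covered = [c for c in checks if c["status"] != "uncovered"]
        report["stages"]["polymorphisms"] = {
            "n_checks": len(checks),
            "n_checks_covered": len(covered),
            "n_match": sum(1 for c in covered if c["status"] == "match"),
            "covered_checks": covered,
        }

    # --- stats
    st = cfg["stats"]
    cmt = rates.estimate_cmt(tumor_scan.depth)
    stats_report: dict[str, Any] = {
        "depth": {"rd_autosome": tumor_scan.depth.rd_autosome, "rd_mt": tumor_scan.depth.rd_mt},
        "cmt": cmt.cmt,
    }
    if junctions:
        bins = None if st["mt_bins"] == "default" else [tuple(b) for b in st["mt_bins"]]
        enr = rates.mt_positional_enrichment([j.mt_bp for j in junctions], mt_len, bins=bins)
        stats_report["mt_positional_enrichment"] = {
            "chi2": enr.chi2, "df": enr.df, "p_value": enr.p_value, "table": enr.table}
        mh = rates.microhomology_enrichment(
            [j.mh_len for j in junctions], null_model=st["mh_null"], genome=genome,
            n_draws=st["mh_draws"], seed=seed)
        stats_report["microhomology_enrichment"] = {
            "chi2": mh.chi2, "df": mh.df, "p_value": mh.p_value, "null": mh.note, "table": mh.table}
        if paths.get("te"):
            te = read_bed(paths["te"])
            tep = rates.te_proximity_test([(j.contig, j.nuc_bp) for j in junctions], te,
                                          genome, n_factor=st["te_n_factor"], seed=seed)
            stats_report["te_proximity"] = {
                "observed": tep.observed, "simulated": tep.simulated,
                "chi2": tep.chi2, "df": tep.df, "p_value": tep.p_value, "seed": tep.seed}
        mt_rate = rates.rate_mt(rates.MtRateInputs(n_junctions=len(junctions), cmt=cmt.cmt, n_samples=1))
        stats_report["mt_rate_per_mb_per_sample"] = mt_rate
    nr = st.get("nuclear_rates")
    if nr:
        df = pd.read_csv(nr["counts_tsv"], sep="\t")
        inputs = rates.NuclearRateInputs(
            junction_counts={str(r["chrom"]): int(r["n_junctions"]) for _, r in df.iterrows()},
            lengths_mb={str(r["chrom"]): float(r["length_mb"]) for _, r in df.iterrows()},
            n_samples=int(nr["nsam"]))
        nrr = rates.rate_nuclear(inputs)
        stats_report["nuclear_rates"] = {"per_chromosome": nrr.per_chromosome,
                                         "genome_wide": nrr.genome_wide}
    esc = st["escape"]
    stats_report["escape_model"] = dataclasses.asdict(rates.escape_rates(
        n_events=len(events), n_samples=1, n_generations=esc["n_generations"],
        rho_integration=esc["rho_integration"]))
    report["stats"] = stats_report
    report["summary"] = summarize_events(junctions, events)

    if truth is not None:
        report["truth_eval"] = evaluate_against_truth(junctions, truth)
        report["truth_eval"]["n_germline_survivors"] = sum(
            1 for j in junctions
            if any(abs(j.nuc_bp - tj.nuc_bp) <= 50 and j.contig == tj.contig
                   for tj in truth.junctions if tj.germline))

    outputs = {p.name: _sha256(p) for p in sorted(out.glob("*.tsv")) if p.is_file()}
    report["outputs_sha256"] = outputs
    report = _jsonable(report)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    logger.info("pipeline complete: %s", out / "report.json")
    return report
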