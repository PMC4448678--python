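"""End-to-end discovery on a small synthetic tumor/normal pair.

Simulates a 2 x 120 kb nuclear genome plus circular mt genome, plants three
somatic mtDNA integrations and one germline numt, then runs the full
pipeline: discordant-pair clustering, matched-normal/known-numt filtering,
and split-read breakpoint resolution. Prints the detection funnel and the
resolved junction table next to the planted truth.
"""

import tempfile
from pathlib import Path

from mtfusion import pipeline, simgen

events = [
    simgen.IntegrationSpec("chr1", 30_000, 2_000, 2_148, "+", (0, 0), name="blunt_148bp"),
    simgen.IntegrationSpec("chr1", 70_000, 5_000, 6_000, "+", (1, 2), name="mh_1kb"),
    simgen.IntegrationSpec("chr2", 60_000, 15_500, 400, "-", (3, 0), name="origin_spanning"),
    simgen.IntegrationSpec("chr2", 90_000, 8_000, 8_600, "+", (0, 0), germline=True,
                           name="germline_numt"),
]

with tempfile.TemporaryDirectory() as tmp:
    sim = simgen.simulate_cohort(Path(tmp) / "sim", seed=11,
                                 cfg=simgen.ReadSimConfig(mean_depth=30, cmt=60),
                                 events=events,
                                 genome_lengths={"chr1": 120_000, "chr2": 120_000})
    cfg = {"simulate": {"enabled": False},
           "inputs": {key: str(sim.paths[k]) for key, k in
                      [("ref", "ref"), ("tumor", "tumor"), ("normal", "normal"),
                       ("numts", "numts"), ("te", "te"), ("sv", "sv"), ("truth", "truth")]},
           "stats": {"mh_draws": 1000}}
    report = pipeline.run_pipeline(cfg, out_dir=Path(tmp) / "run", seed=11)

print("detection funnel (tumor):")
for stage, counts in report["stages"].items():
    if stage in ("detect", "filter", "breakpoints"):
        print(f"  {stage}: {counts}")
print()
ev = report["truth_eval"]
print(f"  somatic junction recall: {ev['junction_recall']:.0%} "
      f"({ev['n_matched']}/{ev['n_truth_junctions']}), "
      f"breakpoints exact: {ev['breakpoint_exact_fraction']:.0%}, "
      f"germline survivors: {ev['n_germline_survivors']}")
print(f"  mt copy number estimate: {report['stats']['cmt']:.1f} (simulated truth 60)")
# The funnel shows every tumor cluster, what the matched normal and known-numt
# filters removed (the planted germline numt), and that each surviving somatic
# cluster resolved to a base-pair-exact junction.
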