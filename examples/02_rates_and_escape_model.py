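"""Translocation-rate comparison and the mtDNA escape-rate model.

Evaluates the closed-form cohort statistics from their published inputs:
25 somatic mt-nuclear junctions across 587 tumor/normal pairs, a median of
~500 mt genome copies per diploid cancer cell, and an assumed 1000 cell
generations from the fertilized egg.
"""

from mtfusion.rates import (MtRateInputs, NuclearRateInputs, escape_rates,
                            per_individual_generation_to_pcpg, rate_mt, rate_nuclear)

# --- per-megabase fusion rate of cellular mtDNA
r_mt = rate_mt(MtRateInputs(n_junctions=25, cmt=500, n_samples=587))
print(f"mt->nuclear fusion rate: {r_mt:.2e} junctions per Mb of mtDNA per sample")
print("  (with ~500 copies x 16.5 kb = ~8.2 Mb of mtDNA per cell, this is the same")
print("   order as interchromosomal translocation rates of mid-sized autosomes)")

# --- a worked nuclear-rate table (synthetic counts, for shape comparison)
nuc = rate_nuclear(NuclearRateInputs(
    junction_counts={"chr2": 1500, "chr4": 1300, "chr13": 700},
    lengths_mb={"chr2": 160.0, "chr4": 125.0, "chr13": 65.0},
    n_samples=587))
for ch, r in nuc.per_chromosome.items():
    print(f"  {ch}: {r:.2e} junctions per Mb per sample (example input counts)")

# --- escape model: N_tr = N_sam * N_gen * rho_escape * rho_integration
esc = escape_rates(n_events=12, n_samples=587, n_generations=1000, rho_integration=0.1)
print(f"\nfusion rate (rho_escape x rho_integration): {esc.fusion_rate_pcpg:.1e} "
      "per cell per cell generation")
print(f"escape rate at rho_integration=0.1: {esc.rho_escape:.1e} pcpg, i.e. one "
      f"escape event per {esc.generations_per_escape:.0f} cell generations")

# --- germline comparison: ~5e-6 numt insertions per individual generation,
#     spread over ~100 germline cell divisions
germ = per_individual_generation_to_pcpg(5e-6, 100)
print(f"germline numt insertion rate: {germ:.0e} pcpg "
      f"(~{esc.fusion_rate_pcpg / germ:.0f}x lower than in these cancers)")
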