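# mtfusion

Discovery and quantification of **somatic mitochondrial→nuclear DNA
fusions** in paired tumor/normal whole-genome sequencing.

Human cells carry hundreds of copies of the 16,569 bp circular mitochondrial
genome, separated from nuclear chromatin by four membranes and the
cytoplasm. Despite those barriers, fragments of mtDNA occasionally end up
fused into nuclear chromosomes of cancer cells — somatic analogues of the
inherited *numts* that accumulated over primate evolution. Finding these
events in WGS, and measuring how often they happen per base pair of
available DNA, is the problem this package addresses. It is aimed at cancer
genomicists who want a transparent, fully testable implementation of the
whole chain: read-level detection → germline filtering → base-pair
breakpoint resolution → cohort-level rate and enrichment models.

## What it computes

**Detection.** Mt↔nuclear *discordant read pairs* (one end uniquely on the
mt genome, one on a nuclear contig, both with mapping quality > 0) are
clustered by single linkage within orientation class — the
(nuclear strand, mt strand) tuple — linking pairs closer than 500 bp on both
genomes, with circular distance on the mt side. Clusters with fewer than
five supporting fragments are discarded. Germline events are removed by
subtracting clusters called from the matched normal and a panel of
unmatched normals at the tolerant support ≥ 2, plus known-numt annotations.
Surviving clusters are resolved to single-base junctions by exhaustive
split-read alignment, annotated with **microhomology** (maximal bidirectional
sequence overlap between the two fusion partners at the junction —
the NHEJ/MMBIR signature) or a nontemplated insertion, and paired into
integration events (two complementary junctions delimit one inserted
segment of the circle).

**Quantification.** With `RD_mt` and `RD_auto` the mean mt and autosomal
read depths of a diploid sample, the mt copy number is

    C_mt = 2 · RD_mt / RD_auto

The fusion rate per megabase of cellular mtDNA per sample, comparable with
interchromosomal translocation rates of nuclear chromosomes
(`R_ch = N_ch / (2·L_ch) / N_sam`), is

    R_mt = N_mt / (C_mt · L_mt) / N_sam ,   L_mt = 0.016569 Mb

and the escape model decomposes the observed event count over `N_gen` cell
generations as `N_tr = N_sam · N_gen · ρ_escape · ρ_integration`.
Chi-square machinery covers breakpoint positional enrichment on the circle,
the microhomology spectrum against analytic or Monte Carlo random-junction
nulls, and proximity of integration sites to transposable elements against
40× in-silico breakpoint redraws.

**Synthetic cohorts.** `mtfusion.simgen` builds a random genome, plants
integrations with engineered microhomology/insertions (including
origin-spanning and near-full-length segments, local deletions, and mt
polymorphisms carried into the integrated segment), and emits
coordinate-sorted tumor/normal SAM directly from generative coordinates
together with a machine-readable truth set — so every pipeline stage is
testable against planted ground truth without downloading anything.

## Worked example

```bash
python examples/02_rates_and_escape_model.py
```

prints

```
mt->nuclear fusion rate: 5.14e-03 junctions per Mb of mtDNA per sample
fusion rate (rho_escape x rho_integration): 2.0e-05 per cell per cell generation
escape rate at rho_integration=0.1: 2.0e-04 pcpg, i.e. one escape event per 4892 cell generations
germline numt insertion rate: 5e-08 pcpg (~409x lower than in these cancers)
```

Reading: across a 587-sample cohort with 25 somatic junctions and ~500 mt
copies (~8.2 Mb of mtDNA) per cell, mtDNA fuses to the nuclear genome at
5.1×10⁻³ junctions per Mb per sample — the same order as interchromosomal
translocation between mid-sized autosomes. Under the escape model that is
2×10⁻⁵ fusions per cell per cell generation, and with a conservative
integration probability of 0.1, at least one mtDNA escape to the nucleus
every ~5,000 cell generations — orders of magnitude above the germline numt
insertion rate (5×10⁻⁸ pcpg).

`examples/01_detect_planted_fusions.py` runs the whole pipeline on a small
synthetic tumor/normal pair and prints the detection funnel
(8 clusters → 2 removed by the matched normal → 6 somatic clusters → 6
base-pair-exact junctions in 3 events, 0 germline survivors, C_mt estimate
60.1 vs a simulated truth of 60); `03_breakpoint_anatomy.py` dissects one
junction (split support, 3 bp microhomology, concordance of the 15,326 A>G
mt polymorphism in junction reads); `04_enrichment_statistics.py` exercises
the three chi-square tests.

A thin CLI mirrors the stages: `mtfusion simulate | detect | filter |
breakpoints | stats | report | run-all` (see `mtfusion --help`).

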