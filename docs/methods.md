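# Methods

This note records the models, conventions, parameter choices and known
limitations of `mtfusion`, in the order the pipeline runs.

## Coordinates and conventions

All internal coordinates are 0-based, half-open; breakpoints are
*between-base* coordinates (breakpoint `p` lies between bases `p-1` and
`p`). SAM/VCF 1-based conversion happens only at I/O boundaries. The mt
contig is identified by configured name (default `MT`), never by length
heuristics, and is treated as circular: distances use
`min(|a-b|, L-|a-b|)` and arcs may span the origin. BED inputs are 0-based
half-open per the standard.

Junction orientation is the (nuclear strand, mt strand) tuple of supporting
discordant pairs, four classes. Classes with nuclear strand `+` have their
nuclear partner left of the fusion point; the mt strand then encodes the
reading direction of the integrated segment. The two junctions of one
insertion therefore appear as complementary classes (`+-`/`-+` for a
forward segment, `++`/`--` for a reverse one), which is what the pairing
step keys on.

## Detection

Discordant extraction requires one end uniquely on the mt genome and one on
a nuclear contig; "uniquely" is operationalized as mapping quality > 0 on
*both* ends (reads with mapq 0 are retained in streams and dropped here).
Duplicate read names collapse to one vote. Clustering is single linkage
within orientation class: two pairs link when their nuclear positions and
their mt positions (circular) are each closer than the window (default
500 bp). We read the window as a per-link gap bound, so a chain of
sub-window gaps may span more than one window; a `span` mode that also caps
the cluster's nuclear span is available behind a flag. Tumor clusters need
≥ 5 supporting fragments; normal and panel samples are called at ≥ 2 so
that subtraction errs toward sensitivity.

Cluster-vs-cluster subtraction removes a tumor cluster when both its
nuclear interval and its mt arc (each padded by `slop`, default 500 bp —
the overlap geometry is not otherwise constrained) intersect a blocking
cluster. Known-numt subtraction consults the nuclear side only: a reference
numt locus attracts mt-like read pairs at its nuclear position regardless
of which mt arc it resembles. Every removal records its cause
(matched | panel | numt).

## Breakpoint resolution

Candidate reads are soft-clipped (clip ≥ 20 bp) or mate-unmapped reads
within 1 kb of a cluster on either genome. Each read is split exhaustively:
over both read orientations, all split points with both parts ≥ 20 bp, and
nontemplated gaps up to 10 bp, the prefix and suffix are placed anywhere in
the nuclear window and the orientation-consistent mt window, scored by
substitution count (the simulator's error model is substitution-only, so
mismatch count equals edit distance on all data this package generates).
A split is admissible below ⌈5% of read length⌉ total mismatches; ties
break toward fewer mismatches, then smaller gap, then maximal prefix, then
leftmost window placement. The modal (nuclear, mt, insertion) placement
over reads is the consensus; count ties are flagged ambiguous and broken
toward the leftmost nuclear coordinate.

Microhomology is the maximal run of bases at the junction identical to both
the nuclear reference continuing past the nuclear breakpoint and the mt
reference continuing past the mt breakpoint, measured by extending left and
right from the consensus placement; `mh_len` is the sum of the two
extensions, and placements are canonicalized by assigning the homologous
run to the nuclear side. The same measuring routine realizes the
simulator's truth coordinates, so "breakpoint exact" comparisons are
well-defined; an independent brute-force overlap scan backs it in tests.
Microhomology and nontemplated insertion are mutually exclusive by
construction (a gap implies `mh_len` 0).

Junctions pair greedily by ascending nuclear distance (same contig, within
1 Mb, complementary orientations); the inserted segment is the forward arc
between the canonical mt breakpoints, so its length is the *uniquely
attributable* arc — planted length minus the homologous bases shared with
the nuclear flanks. Unpaired junctions become single-junction events.
Events with a nuclear SV breakpoint within 100 kb (configurable; "vicinity"
is a judgment call) of a junction are flagged rearrangement-associated.

## Quantitative models

Copy number: `C_mt = 2·RD_mt/RD_auto`, with depths measured as aligned
bases over contig length from the alignments themselves. Rates:
`R_ch = N_ch/(2·L_ch)/N_sam` per chromosome (the genome-wide mean uses
total junctions over twice the summed nonredundant length — the weighting
is our choice and per-chromosome values are always emitted alongside) and
`R_mt = N_mt/(C_mt·L_mt)/N_sam`. Escape model:
`N_tr = N_sam·N_gen·ρ_escape·ρ_integration`, solved for the product and,
given an assumed `ρ_integration`, for `ρ_escape` and its reciprocal
("one escape per N generations").

All chi-square tests are Pearson without continuity correction; expected
counts below 5 are logged as warnings. Positional enrichment bins are a
config input; the defaults are seven 2-kb arcs plus the origin-spanning
14 kb→500 bp arc containing the heavy-strand replication origin, and bins
must partition the circle. The microhomology null is either analytic —
the single-sided geometric `P(MH≥k)=4^-k` — or, by default, Monte Carlo:
random nuclear/mt breakpoint pairs on the provided genome measured with
the same homology rule as real junctions. The two differ: the measured
rule extends in both directions, giving `P(MH≥1)=1-(3/4)²=7/16` on random
sequence (verified by simulation in the test suite), which is why the
Monte Carlo null is the default. TE proximity categories are A (inside),
B (≤15 bp), C (16–150 bp), D (>150 bp) against the merged TE interval
union; in-silico breakpoints are drawn uniformly per chromosome at 40× the
observed count, redrawing positions inside N-runs ≥ 10 bp, and compared in
a 2×4 table.

## The synthetic cohort

The generator emulates the study conditions rather than a sequencing
instrument. Reads are 100 bp paired-end with Gaussian 350±50 bp inserts
(truncated at the read length) — conventional short-insert values; the
source data specify only ≥25× coverage. `mean_depth` (default 30) is the
sample's mean autosomal depth; each of the two nuclear haplotypes
contributes half. The mt genome is simulated at `mean_depth·C_mt/2`
(default `C_mt` 495, the cohort median), so the depth-ratio estimator
recovers `C_mt` by construction; fragment counts per haplotype are
deterministic (`round(depth·L/(2·read_len))`) with uniform positions, so
mean depths are exact up to junction-clipping and the mt reads contributed
by integrated segments (~1% upward bias on `C_mt` in the default scenario,
well inside the 5% recovery tolerance). Mt background fragments do not
span the origin (their starts are restricted), which biases *local* depth
near position 0 slightly but leaves mean depth — the only quantity used —
unchanged.

Integrations are planted by engineering the nuclear reference flank: the
requested homology bases are copied from the oriented segment ends into the
flank, flanking bases are forced to differ so the run stops where intended,
and nontemplated insertions are adjusted so neither edge can be absorbed by
an adjacent partner. Where two junctions of a blunt insertion constrain the
same base, both constraints are honored simultaneously; where a constraint
falls on another junction's engineered homology bases (possible only at a
shared insertion point), the accidental extension is left in place. In all
cases the *realized* junction — re-measured with the caller's own homology
rule after construction — is what the truth set records, so acceptance
compares the caller against what was actually built, not what was asked
for. Germline events go into both samples' derived haplotypes (one allele);
somatic events only into the tumor's, mixed by `tumor_fraction` (default
1.0). mt polymorphisms (six defaults at the classic positions, with the
matching reference alleles pinned at genome build time) are applied to the
individual's mt haplotype and hence carried into integrated segments and mt
background reads. Sequencing errors are uniform substitutions, default
rate 0.0: the recovery guarantees in the tests are stated for error-free
data, and noisy variants set the rate explicitly. mapq is 60 everywhere
except optional configured decoy regions emitted at mapq 0 to exercise the
mapq filter. The "local inversion" co-occurrence descriptor is realized as
a nearby nuclear inversion recorded in the SV table (exercising the
rearrangement-association flag); the local-deletion descriptor removes the
deleted span from the derived haplotype and shifts the right junction
accordingly.

What passing tests on this generator do *not* show about real data:
alignment ambiguity in repeats (reads are emitted at their generative
coordinates; there is no aligner), indel sequencing errors, PCR duplicates,
chimeric library artifacts, subclonal copy-number structure, or realistic
base-quality models. The mapq-0 decoy mechanism is a stand-in for mapping
ambiguity, not a model of it.

## Problem sizes and defaults

The default study runs a 2 × 1 Mb nuclear genome at depth 30 with
`C_mt` 495 (~1.8 M reads per sample) — small enough to simulate, scan and
resolve in well under a minute on one core while preserving the depth
ratios, support distributions and junction anatomy of the full-scale
setting. The test suite uses 2 × 120 kb cohorts with `C_mt` 60 for the same
reason. Thresholds (window 500, support 5/2, slop 500, radius 1 kb, seed)
are echoed into `report.json` along with SHA-256 checksums of every stage
output.

## Known limitations

Nuclear-nuclear rearrangement calling is out of scope; interchromosomal
junction counts for the rate comparison are a TSV input. The split aligner
scores substitutions only (no indels near junctions). Panel subtraction
re-calls clusters per panel sample rather than pooling raw pair evidence.
The cohort-scale discovery numbers (25 junctions in 12 of 587 cancers)
depend on controlled-access data and are represented here only through the
closed-form statistics computed from their published inputs.
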