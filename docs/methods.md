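# Methods

## The question and the model

Memory T cells re-induce cytokine and other rapid-recall genes within
minutes to hours of restimulation, much faster than naive cells. The
poising hypothesis holds that this is a chromatin property of the
*resting* cell: activating marks (H3K4me3 at promoters in particular)
are already present at the recall genes in memory cells while the genes
are transcriptionally silent. This package operationalizes the
hypothesis as three measurable claims on ChIP-Seq + RNA-Seq data:

1. genes inducible in one subset but not the other (by FPKM
   thresholds) can be separated into subset-specific induction groups;
2. islands of activating marks can be called and compared between
   subsets after depth normalization;
3. subset-specific inducibility co-occurs with subset-specific island
   gain/loss near the TSS far above the rate seen for genes whose
   inducibility does not differ.

Everything downstream of alignment is in scope; alignment itself, peak
browsing, motif enrichment and GO analysis are not.

## Coverage and counting

Tags are stranded BED6 intervals, 0-based half-open everywhere (the TSS
of a minus-strand gene is the `end − 1` position). Each tag is extended
from its 5′ end to the estimated fragment length (default 150 bp,
configurable; no estimator is run by default — determinism is preferred
over a strand cross-correlation fit, which can be added externally).
Coverage adds 10⁶/total_mapped per covered base (FPM). Internally the
accumulation is integer fragment depth scaled once at the end, so
per-base values are exact products and testable against a per-base
loop. Tag-in-interval counting uses the extended-fragment midpoint
(strand-symmetric); 5′-end and any-overlap modes exist as options.

## TSS metaprofiles

For a gene set, each tag's 5′ end is shifted by half the fragment
length in the read's direction and contributes at exactly one relative
position within ±2000 bp of a TSS; X/Y-chromosome tags weigh 2 (one
copy in male-derived libraries), applied to raw counts before any
normalization. Counts are divided by (total_mapped/10⁶) and by the
number of genes, then smoothed with a centered 100 bp moving average,
truncated at the array edges. Profiles are transcription-oriented by
default (minus-strand genes flipped so +x is downstream); a
genome-oriented mode is available.

## Expression classes and induction groups

Thresholds: expressed FPKM > 5 at rest; silent < 2 at rest and < 5
activated; inducible < 2 at rest and > 5 activated; anything else —
including values exactly at 2 or 5, since the rules use strict
inequalities — is ambiguous. The rationale is that ~5–8 FPKM
corresponds to roughly one transcript per cell, so "silent" means below
one copy. "After activation" defaults to the 150 min timepoint, the one
the induction-ratio definition names; an any-timepoint mode is a flag.

The induction ratio between TEM and naive uses absolute FPKM deltas
with a 0.1 offset in numerator and denominator (so unexpressed genes
give finite, symmetric ratios); ≥ 3 is TEM-specific, ≤ 1/3
naive-specific, in between shared, with ties at exactly 3-fold assigned
to the specific group ("at least 3-fold"). The absolute values mean a
*decrease* on activation counts like an increase; the formula is
implemented as printed, and in the universe this is applied to (silent
at rest in both subsets, induced above 5 in at least one) decreases are
essentially impossible. Isoform FPKMs sharing a TSS are **summed**
("combined" read as additive transcript mass); isoforms of one gene
with distinct TSSs stay separate entries. For the promoter-consequence
heatmap, FPKM below 1 is floored to 1 before log2 so fold changes among
barely-expressed genes do not explode.

## Island calling

A deliberately simple, fully specified substitute for a local-model
peak caller: non-overlapping 200 bp windows, tag assignment by
fragment midpoint, Poisson upper tail against the genome-wide mean
tags-per-window λ, eligibility p < 1e−5, eligible windows merged across
gaps ≤ 400 bp, islands trimmed to their outermost eligible windows.
The genome-wide λ (rather than a local λ) is appropriate for the
simulator's uniform background; on real data with copy-number or
mappability structure a local-background caller would be preferable —
a known limitation. The caller is verified against exhaustive window
enumeration with explicit Poisson pmf partial sums.

## Differential islands (M-A normalization)

Islands from the two samples are merged into union regions; regions
overlapping a called island in *both* samples are "common" — assumed
mostly unchanged biology, differing only by depth and intensity-
dependent bias. On common regions an ordinary least-squares line of
M = log2(a/b) against A = ½·log2(a·b) is fitted (the classic M-A
normalization; robust regression is a flag, not the default) and
subtracted from every region's M, including sample-unique regions
(zero counts replaced by pseudocount 0.5 so M is finite).

Significance: the raw total a+b is redistributed according to
M_adjusted and tested against Binomial(n, ½) — the exact conditional
form of the equal-means Poisson comparison; it is closed-form and
oracle-checkable, unlike the original Bayesian formulation, and
symmetric under sample swap. A region is differential when p < 0.01,
|M_adjusted| > 1 (i.e. adjusted fold change > 2, the log2 reading) and
max(raw a, raw b) ≥ 15 reads. The 15-read floor is applied to raw,
pre-normalization counts, per replicate (a pooled mode exists).

## Gene association

The association window is [TSS − 20 kb, TSS + 1 kb] in transcription
orientation by default (the directionality is a genuine open choice;
genomic orientation is a flag and both are tested). A gene is
gained/lost when ≥ 1 passing island of that direction overlaps the
window by ≥ 1 bp; presence/absence only — no per-gene p-value
combination and no weighting by island count. The induction-group
summary uses the deeper replicate-1 comparison; the promoter analysis
(TSS ± 1 kb) demands a passing island of consistent direction in both
replicate comparisons and drops direction conflicts. Expression
consequences compare the gene's class between naive and TEM
(silent→expressed = increased expression, silent→inducible = increased
inducibility, and mirror images). Heatmap row ordering uses
average-linkage hierarchical clustering on correlation distance —
cosmetic only.

## Synthetic data generator

The generator emulates the *structure* of the study, not its sequence
content. Defaults (chosen once as a realistic desk-scale study):

| parameter | default | meaning |
|---|---|---|
| chromosomes | 2 autosomes + chrX, 4 Mb each | small genome, sex-chromosome path exercised |
| n_genes | 200 | TSSs ≥ 50 kb apart so association windows never collide |
| class fractions | const .30 / poised_TEM .20 / poised_naive .10 / poised_both .10 / silent .30 | deterministic largest-remainder allocation (multinomial behind a flag) |
| background_rate | 0.05 tags/bp | 50 expected background tags per kb |
| island_enrichment | 10× | fold over background inside planted 1 kb promoter islands |
| replicate depths | 3:1 | forces the normalization to do real work |
| fpkm_high / fpkm_low | 20 / 0.5 | bracket the 5/2 thresholds comfortably |
| fpkm_noise_sd | 0.3 | lognormal sigma; misclassification ≪ 5% |

Tags are 36 bp reads drawn from a uniform-background + per-island
mixture; fragment midpoints are uniform in the source region and the 5′
end is placed so that extension to the fragment length reproduces the
midpoint; strand is ± with equal probability; the total count is
Poisson around the requested depth. Islands are planted centered on the
TSS, so they overlap both the 21 kb association window and the ±1 kb
promoter window. `poised_island_fraction` < 1 leaves some poised genes
without an island (induction without chromatin gain);
`decoy_gain_fraction` > 0 gives some silent genes a TEM-only island
(gain without consequence). Both knobs use deterministic within-class
allocation so planted rates are exact.

What the simulator does **not** model: sequence-level effects (no
FASTQ, no mappability or GC bias), input/IgG background structure,
copy-number variation, broad domains, enhancer–promoter looping, and
population heterogeneity (a partially-marked cell population is
represented only implicitly through the enrichment fold). Passing
recovery tests therefore demonstrates the correctness of the
computational chain under idealized noise, not performance on real
libraries — on real data the island caller's global background is the
main simplification to revisit.

## Determinism and numerics

All randomness flows from one integer seed through fixed per-purpose
`numpy` SeedSequence streams (genome, tags per cell type × replicate,
expression), so identical configs give byte-identical outputs; report
JSON is written with sorted keys. bedGraph values are rounded to 4
decimals, zero runs suppressed, and round-trip exactly at that
precision. Degenerate inputs: zero tags → no islands; < 10 common
islands → a hard error recommending deeper data rather than a silent
bad fit; empty induction group → fractions reported as NA; all-equal A
on common islands → slope 0, intercept = mean M.

## Problem sizes used in the test-suite

Oracle-equivalence tests run on toy chromosomes (≤ 100 kb, ≤ ~5,000
tags) where brute-force enumeration is exact and fast. End-to-end
recovery and null-comparison tests use the full default conditions
above (200 genes, ~12 Mb genome, ~0.6–0.9 M tags per deep replicate)
over ten seeds; the acceptance script uses three seeds per metric. At
these sizes the recovery of planted poised_TEM genes as
TEM-specific-with-gain is complete (≥ 90% required), spurious gains
among non-poised genes are ≤ 5%, and a 35% planted gain rate is
recovered within 5 points.
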