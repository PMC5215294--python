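# poisedchrom

Analysis pipeline for **promoter poising** in resting T-cell subsets:
linking gain or loss of activating histone-modification islands (H3K4me3
and friends, profiled by ChIP-Seq) to differential gene inducibility
(FPKM tables from RNA-Seq time courses) between naive and memory CD4
T cells. It is written for computational biologists who want the whole
chain — from aligned tags to the per-group "fraction of genes with
gained islands" bar-graph numbers — as a tested, scriptable library, and
it ships a synthetic-data generator with full ground truth so every
stage can be validated without downloading any external dataset.

## What it computes

Given BED6 aligned tags per cell type (Naive, TCM, TEM) and an FPKM
table over timepoints (rest R, 40 min, 150 min, 15 h of anti-CD3/CD28
activation):

1. **Coverage** — tags are extended to the estimated fragment length
   *L* and accumulated as fragments per million mapped tags (FPM);
   tracks are written as bedGraph.
2. **TSS metaprofiles** — average tag density ±2 kb around TSSs of a
   gene set, each read shifted by *L*/2 in its own direction, X/Y tags
   counted twice, normalized per million tags and per gene, smoothed
   with a 100 bp window.
3. **Expression classes** — per cell type: *expressed* (FPKM > 5 at
   rest), *silent* (< 2 at rest, < 5 activated), *inducible* (< 2 at
   rest, > 5 activated). Genes silent at rest in both cell types and
   induced in either are ranked by relative induction

   ratio = (|FPKM_TEM,150 − FPKM_TEM,R| + 0.1) / (|FPKM_Naive,150 − FPKM_Naive,R| + 0.1)

   and split at 3-fold into naive-specific / TEM-specific / shared
   groups.
4. **Islands** — a fixed-width scanning-window Poisson caller (200 bp
   windows, genome-wide expected rate λ, upper-tail p < 1e−5, merge gap
   400 bp).
5. **Differential islands** — M-A normalization on islands common to
   both samples (OLS of M = log2 a/b on A = ½ log2 ab, subtracted from
   every region), then a conditional binomial exact test; a region is
   differential when p < 0.01, |M_adjusted| > 1 (adjusted fold change
   > 2) and ≥ 15 raw reads in at least one condition.
6. **Association** — differential islands are linked to genes through
   the [TSS − 20 kb, TSS + 1 kb] window (transcription-oriented), and
   the per-induction-group fractions of gained/lost genes are
   tabulated. A stricter promoter analysis (TSS ± 1 kb, consistent
   direction in both replicates) feeds an expression-consequence
   classification (increased expression / increased inducibility /
   no change / lost inducibility / lost expression).

The synthetic generator plants all of this structure — per-cell-type
promoter islands at 10× background, poised genes silent at rest and
induced only in the island-carrying cell type, replicates at a 3:1
depth ratio — and records the ground truth, so recovery is measurable.

## Worked example

```bash
cat > pipe.yaml <<EOF
seed: 3
outdir: pipe_out
simulate:
  n_genes: 30
  chrom_length: 800000
  background_rate: 0.02
EOF
poisedchrom run --config pipe.yaml
```

prints (and writes to `pipe_out/summary.txt`):

```
poisedchrom pipeline summary
============================

induction groups: {'naive_specific': 3, 'tem_specific': 6, 'shared': 3}
   naive_specific: n=   3  gained=0.0%  lost=100.0%
     tem_specific: n=   6  gained=100.0%  lost=0.0%
           shared: n=   3  gained=0.0%  lost=0.0%
promoter H3K4me3 (both replicates): gained=6 lost=3
consequence categories: {'increased_expression': 0, 'increased_inducibility': 6, 'no_change': 0, 'lost_inducibility': 3, 'lost_expression': 0}
```

Reading this: of the 30 simulated genes, 12 enter the induction
universe; all 6 TEM-specific induced genes have a gained H3K4me3 island
in their association window ("gained=100.0%"), the naive-specific genes
show the mirror-image loss, and the shared group shows neither — i.e.
differential inducibility is fully explained by differential chromatin
in this planted dataset. The promoter analysis finds the same 6 gains
and 3 losses consistently in both replicates, and every promoter gain
comes with increased inducibility. `pipe_out/report.json` holds the
same numbers machine-readably, `pipe_out/data/` the simulated inputs
and ground truth, and `pipe_out/profile_*.tsv` the TSS metaprofiles per
expression class. Sub-commands (`simulate`, `coverage`, `profile`,
`classify`, `diff`) expose the individual stages.

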