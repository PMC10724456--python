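# Methods

This note documents the models and procedures implemented in
`placenta_enhancers`, the choices made where the underlying recipes were
open, and what the synthetic validation does and does not demonstrate.

## Scientific setting

Active enhancers produce short, unstable enhancer RNAs (eRNAs), and
nascent-transcription assays (PRO-seq analysed by the dREG classifier)
locate them as transcribed regulatory elements (TREs). In a
cross-sectional placental study spanning gestation, per-sample TRE calls,
histone-mark ChIP (H3K27ac, H3K4me1), RNA-seq expression, TF motif hits,
and a GWAS SNP catalog can be integrated to ask: which enhancers are
active when, which genes do they plausibly regulate, which transcription
factors drive them in early versus late pregnancy, and whether
disease-associated variation concentrates in them. This package
implements that analysis layer; it does not align reads, call peaks, run
dREG, or discover motifs — those upstream products are its inputs.

## Coordinate and data conventions

All intervals are 0-based half-open (BED). GTF input (1-based inclusive)
and GWAS catalog positions (1-based) are converted at the parser
boundary. SNPs are length-1 intervals. Chromosome names are compared by
exact string match; inputs sharing zero chromosome names trigger a
warning, not silent emptiness. Signal matrices (features x samples) must
be complete and nonnegative — there is no missing-data rule anywhere in
the pipeline, so adapters must impute upstream. The sample sheet is the
ordering authority: matrices are reindexed to it on load and absent
samples are errors.

## Enhancer universe

Per-sample TRE calls are merged into a non-redundant union; overlapping
and bookended (gap-0) intervals merge, a 1-bp gap separates runs (the
default behaviour of the standard merge utility). The distal filter
retains an element only when the gap to *every* gene span is strictly
greater than `distal_min_gap_bp` (default 5000); the gap is the number of
bases strictly between the nearest edges, zero for any overlap, and the
test is strand-agnostic. A TSS-only variant (`mode="tss"`) is available
because distal filtering is sometimes phrased against TSSs rather than
gene bodies; the gene-span rule is the default. Transcription is
quantified as RPKM, `counts / ((len/1e3)(lib/1e6))`, with total mapped
reads as the library size. The expressed universe keeps elements with
RPKM >= 2.0 (inclusive) in at least 1 sample. Raising the threshold can
only shrink the universe (tested monotonicity).

## Expression dynamics

*Size factors* follow the median-of-ratios estimator: each library's
factor is the median over all-positive feature rows of the count divided
by the row's geometric mean. Note this estimator is invariant to a common
rescaling of all libraries (the geometric-mean pseudo-reference rescales
with them); only relative depths are identified.

*Age correlation*: per gene, Pearson r of expression against gestational
age in weeks; two-sided p from t = r sqrt((n-2)/(1-r^2)) with n-2 df
(equivalent to the simple-regression slope test); classification as
increasing/decreasing requires |r| > 0.7 and p below alpha/m, where m
counts only testable (non-constant) genes — constant genes are flagged
and excluded from the denominator. At alpha = 0.05 and m = 23 000 the
cutoff is 2.17e-6.

*Differential tests*: two-sided two-sample t-tests, Student
pooled-variance by default (Welch optional), BH step-up q-values, a
pseudocount of 0.1 RPKM in fold changes to avoid division by zero, and a
call requires both |log2FC| >= log2(2) and q < 0.05. Identical constant
groups produce t = 0, p = 1 rather than NaN.

*Epoch trends*: per-gene z-scores across samples, samples partitioned
into five age-ordered bins of near-equal size with earlier bins taking
the remainder (36 samples -> 8,7,7,7,7); age ties break by sample id.
*Signature scores* are unweighted means of a gene set's expression per
sample, compared between trimesters with the same differential
machinery. The ddCt utility returns 2^-((Ct_t,B - Ct_r,B) - (Ct_t,A -
Ct_r,A)).

## Enhancer-gene linking

Nearest-gene assignment minimizes the gap between the enhancer interval
and the gene TSS (regulatory targeting concerns promoters; a
gene-body-edge mode exists). Ties break to the lexicographically
smallest gene id; enhancers on gene-free chromosomes stay unlinked.
List-overlap significance is the upper-tail hypergeometric P(X >= k)
(enrichment only), with the annotation size as the default universe.
Enhancer-gene co-expression is plain Pearson r across shared samples;
constant vectors are flagged undefined rather than silently zero.

## TFSEE

The Total Functional Score of Enhancer Elements integrates four inputs
over the enhancer universe. With N() the per-feature min-max across
samples (zero-range slices map to zero):

    A = N(eRNA) * (N(K27ac) + N(K4me1)) / 2          (samples x enhancers)
    M(e,t): top-20 motif hits per enhancer by -log10 p, reduced per TF
            by max, min-max scaled per TF across enhancers
    S_raw = (A @ M) * N_TF(expression)
    S     = per-TF min-max of S_raw                   (samples x TFs, [0,1])

Choices worth flagging: eRNA is the defining activity signal — zero
normalized eRNA forces zero activity regardless of marks — and the two
marks are averaged rather than multiplied so that one locally flat mark
cannot annihilate activity (a full three-way product is a config
option). Normalization axes are per-feature everywhere, which makes
features comparable across samples, the property sample clustering
needs; the upstream method descriptions leave the axis unstated, so it is
explicit and switchable here. Motif reduction over multiple kept sites of
the same TF is max (strongest site; sum optional).

Samples are clustered on d = 1 - Pearson(r) between score vectors with
average linkage (UPGMA); the 2-clade partition is the root cut.
Differential TF ranking is Delta = mean(S, late) - mean(S, early) with a
pooled t-test; the table is ordered ascending in Delta, so the most
early-active TFs head the list and the most term-active close it.

## SNP enrichment

Density is SNPs per Mb of a (pre-merged, non-overlapping) region set;
containment is half-open (pos == end is outside). The baseline divides
the whole catalog by the supplied total genome size — genome size is a
required input, not inferred, and no gap-exclusion is applied. Densities
are additive over disjoint region sets.

## Synthetic study generator

The generator emulates the study design: 36 samples, 12 per trimester,
ages uniform in 6-13 wk (I) and 14-27 wk (II) and a term cluster fixed at
39 wk (III); 2000 genes and 500 candidate enhancers laid out in blocks
(one gene per block, enhancer mid-block, always > 5 kb from every gene
span); per-sample TRE calls containing each sample's active enhancers
plus 40 random promoter-proximal decoys (entirely within 5 kb of a gene,
so the distal filter must remove every one). Enhancers are 30%
early-active, 30% late-active, 40% constitutive; "early" means mean eRNA
scaled by 2^effect (default effect_size_log2 = 2, i.e. 4-fold) in
trimester I/II samples relative to III, and symmetrically for "late".

All sequencing-derived counts are negative binomial with var = mu +
0.1 mu^2 (a typical bulk overdispersion); eRNA base means are 2^U(4,6)
counts (about 2-9 RPKM at the 2e7-read default depth, so every planted
enhancer clears the expression threshold while decoy background, 0.5-2
counts, does not matter after the distal filter). Histone matrices are
monotone noisy transforms of the eRNA means (K27ac proportional, K4me1
compressed via a square root), giving marks that are correlated with
transcription by construction but not identical — the real coupling is
qualitative in the source data, so no quantitative coupling is claimed.
Gene expression has three planted classes: genes hosting an early/late
enhancer follow that enhancer's 4-fold trimester step (these are the
planted enhancer targets and are counted among the age-down/age-up truth
sets, since their expression genuinely tracks gestation); a further 20%
of free genes are linear in age (base 50, |slope| U(0.8, 1.2) per week,
Gaussian sd 7 — population |r| about 0.85, comfortably above the 0.7
classification threshold but not trivially so); the rest are flat.
Early/late TFs have 4-fold elevated expression in their window and
motifs planted (p ~ log-uniform 1e-12..1e-6) in 80% of their class's
enhancers; 50 decoy TFs have flat expression and background motifs
(1e-4..1e-2) scattered everywhere. SNPs are uniform over the genome plus
a Poisson surplus inside enhancers sized to a 3x density ratio, with a
20 000-SNP catalog so the per-seed Poisson error on the enhancer count is
a few percent.

One root seed drives everything through child streams spawned in fixed
order, so identical configurations reproduce byte-identical files.

What passing recovery tests shows — and does not. The generator plants
clean, block-separated effects with known classes; real placental data
have correlated confounders (sex, cellular composition shifts across
gestation, batch), overlapping gene structures, unmodelled promoter
transcription, and much larger and messier TRE sets. Recovery of planted
TFs, clades, genes, and densities therefore validates the
implementation's correctness and calibration, not the biological power of
the method on real tissue.

## Problem sizes and numerics

The validation suite runs the full pipeline at the default design (36
samples, 500 enhancers, 2000 genes, 60 TFs) over 20 seeds — small enough
to complete in seconds per seed yet large enough for the planted effects
to be estimated rather than memorized. Result files render floats at 6
significant digits with fixed row/column order; the run manifest records
configuration, input checksums, and stage status but no wall-clock
times, so reruns are byte-identical. Degenerate inputs have explicit
rules throughout: constant slices min-max to zero, constant genes are
excluded from testing denominators, constant correlation vectors are
flagged undefined, and ties break lexicographically everywhere ordering
matters.

## Known limitations

- RPKM library sizes are total mapped reads; reads-in-TREs is a
  plausible alternative the interface does not currently expose.
- The hypergeometric overlap test is enrichment-only.
- No LD expansion of GWAS lead SNPs and no gap-excluded genome
  background.
- The generator does not simulate sequence, reads, or the TRE caller
  itself; TRE boundary noise is limited to decoy placement, so merge
  stress mostly comes from decoys, not planted enhancers.
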