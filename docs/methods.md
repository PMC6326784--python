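# Methods

## Scope and data model

The pipeline starts from per-sample Bismark-style coverage files (chrom,
1-based position, position, methylation %, methylated count, unmethylated
count). The percentage column is treated as advisory and recomputed from
the counts, which guards against rounding in third-party files. CpG
positions stay 1-based internally; every interval (tiles, gene flanks,
ICRs, BED/genePred input) is 0-based half-open, converted once at the file
boundary. CpG dyads are used as the extractor reports them; an optional
`destrand` step merges (pos, pos+1) pairs by summing counts, but it is off
by default because site-resolution extractor output is the unit of
analysis.

## Differential testing

Counts are modelled as binomial with a logit-linear group effect. The
replicate-aware test is a likelihood-ratio test of the group coefficient
against χ² with 1 df. Because the only covariate is the binary group
label, the maximum-likelihood fit is closed-form — each group's fitted
proportion is its coverage-pooled methylation fraction, and the
within-group replicate likelihoods sum to the pooled-count likelihood — so
no iterative solver is involved and the statistic is computed vectorized
over all units. This is the same model class the standard count-based DM
packages use for replicated designs, without an overdispersion
correction: biological replicates enter through their pooled coverage
weights. Comparisons with a single sample per group use the two-sided
Fisher exact test (hypergeometric-tail definition) instead, since the
logistic LRT is asymptotic.

Multiple testing is Benjamini–Hochberg step-up, applied over qualified
units only and per comparison. BH was chosen over permutation- or
SLIM-style q-values because it is deterministic, assumption-light, and
exactly testable against a brute-force min-over-suffix computation; the
q ≤ 0.01 calling threshold is applied identically either way. Group
methylation percentages are coverage-pooled (Σm/Σ(m+u)), not means of
per-sample percentages, to stay consistent with the count-based test.

Calling boundaries are inclusive: hypo requires Δ ≤ −25 points and
q ≤ 0.01, hyper the mirror image. Methylation-state boundaries put
exactly 20% in the partial class and exactly 80% in the high class,
resolving the overlap between a "20–80%" partial band and a "≥80%" high
band in favour of the explicit ≥.

## Tiling

Tiles are fixed, ungapped, non-overlapping 500-bp windows anchored at
0-based multiples of the width from each chromosome origin; the phase is a
convention (the window grid could in principle be shifted) and is recorded
here as a reproducibility caveat. A tile qualifies when at least three of
its member CpGs have ≥ 10× coverage in *every* sample of both groups —
the per-site-in-all-samples reading, which is the only one that makes a
tile's tested unit comparable across samples. Tile counts are per-sample
sums over member sites; a site missing from one sample contributes zero
there. Note that pooled tile counts make the tile percentage a
coverage-weighted average of member-site levels, so tiles whose members
have very different levels show extra between-sample variance; the
generator's block-level methylation structure (below) mirrors the local
homogeneity that keeps this effect small in real data.

## Annotation

Gene flanks are strand-oriented, half-open windows: promoter
[TSS−1000, TSS+500), upstream [TSS−5000, TSS−1000), TES window
[TES−500, TES+1000), downstream [TES+1000, TES+5000), mirrored through the
anchor on the minus strand and clipped at position 0. Exons come from the
gene model; introns are the gaps between consecutive exons. Categories
from all overlapping genes are pooled before resolution, and a single
location is chosen by the fixed priority promoter > upstream > TES >
downstream > exon > intron > intergenic, so gene order can never change
the answer. Tiles match on any-base overlap (an alternative midpoint rule
would assign slightly fewer promoter tiles; any-overlap was chosen and is
flagged here).

## ICR analysis and refinement

ICR summaries pool counts over qualified CpGs inside each region, per
group, and report regions with no qualified CpG as missing rather than 0.
Boundary refinement applies two data-driven edits: same-stem split ICRs
(e.g. `ZAC1_1`/`ZAC1_2`) merge into one region when their gap is at most
`icr_merge_max_gap` (default 500 bp) and contains at least one
hypomethylated CpG; a boundary extends outward to the farthest
hypomethylated CpG within `icr_extend_max` (default 600 bp). The defaults
cover the two edit magnitudes the analysis is designed around (a 346-bp
gap merge and a 549-bp extension) with headroom. Both passes iterate to a
fixed point, which makes the operation idempotent even when newly covered
CpGs bring further CpGs within reach of the moving boundary.

## Concordance

Group A (hypomethylated: Δ ≤ −25, q ≤ 0.01, inclusive) and Group B
(stringently unchanged: |Δ| < 5 and q > 0.1, strict — deliberately
excluding 5–25-point losses) are extracted from a source comparison,
restricted to units testable in every other comparison, and scored for
the same behaviour there. For Group B the published-style bar could mean
either "meets the full unchanged criteria" or merely "not significant";
the full criteria are used for the reported fraction and the
not-significant count is emitted alongside. Reported percentages round
half-up to integers ("~88%"); exact fractions are kept in the output.

## Targeted quantification

Clone-based bisulfite summaries pool every non-missing call across all
clones and CpGs of an amplicon (missing calls leave the denominator), so
clones are weighted by what they report rather than averaged as
percentages. Conversion QC treats non-CpG cytosines as unmethylated, so
the retained-C fraction estimates conversion failure; libraries should
exceed 99%. Protein half-life is estimated by ordinary least squares of
log intensity on chase time — with ~4 time points and multiplicative
densitometry noise, log-linear OLS is the standard, exactly testable
estimator — reporting t½ = ln2/(−slope) and R², with a no-decay sentinel
when the slope is non-negative (a negative half-life would be
meaningless; the protein simply did not measurably decay over the chase).

## Synthetic data

The generator's defaults define the study conditions the tests run under:

* **Genome**: two chromosomes totalling 2.5 Mb; CpGs at mean 120-bp
  spacing (exponential gaps, minimum 2 bp), ~4× denser inside ICRs to
  mimic their CpG-island character; 40 multi-exon genes; 8 ICRs of
  2–4 kb; 5% of non-ICR CpG-bearing tiles designated DNMT3A targets.
* **Methylation levels**: one draw per 750-bp block from a
  0.35/0.15/0.50 mixture of Beta(1,19), Uniform(0.2,0.8) and Beta(19,1),
  shared by the block's CpGs. The block structure reproduces the strong
  local autocorrelation of real methylomes (neighbouring CpGs agree);
  without it, tiles mixing fully methylated and unmethylated sites show
  coverage-composition variance far beyond anything biological. The
  mixture makes >75% of sites fall below 20% or above 80% — the observed
  bimodality.
* **ICRs** carry an explicit allele pair (1, 0) and reads are sampled
  allele-first (coverage split Binomial(cov, ½) between alleles), so
  observed ICR methylation is genuinely binomial around 50% rather than a
  flat per-read coin — matching the monoallelic mechanism.
* **Targets** draw their WT level from the methylated Beta(19,1)
  component: a planted loss is only observable where methylation exists,
  and with the default Δ = 0.30 the subtraction never floors at zero, so
  target tiles lose ~30 points on average. The zygotic-KO effect size is
  a modelling choice (the underlying biology is only characterized as
  "moderate" loss) and is exposed in `StudyConfig.effect_delta`.
* **Genotype effects**: mKO zeroes both ICR alleles and nothing else; KO
  subtracts Δ at target sites and leaves ICRs untouched; mzKO applies
  both.
* **Counts**: coverage is shifted negative binomial (mean 30, dispersion
  5, minimum 1) per site and replicate — at these settings roughly 19% of
  sites clear the 20×-in-all-six-samples filter, which still leaves >130
  qualified ICR CpGs; methylated counts are binomial at the
  conversion-adjusted level `ℓ(1−ε_over) + (1−ℓ)·ε_fail` with a 0.5%
  failure rate and no over-conversion by default. Each replicate also
  emits ~2000 non-CpG cytosine positions (~60k calls) carrying the same
  failure rate for conversion QC.
* Everything is a pure function of (config, seed); identical inputs give
  byte-identical files.

What passing tests on this generator do *not* show: the generator has no
fragment-level RRBS library structure (MspI sites, read ends), no
sequencing error beyond conversion failure, no biological
replicate-to-replicate variance in methylation levels (replicates differ
only by sampling), and no CpG-density covariates. Power and false-call
rates measured here therefore reflect sampling noise only; real data with
between-replicate biological variance would need the overdispersion
corrections this package deliberately omits.

## Problem sizes and numerics

The default synthetic study (~21k CpGs, 12 samples) runs the full
pipeline — three site-level and three tile-level comparisons plus
annotation, ICR analysis, and concordance — in a few seconds; the test
suite completes in well under a minute. Degenerate inputs are handled
explicitly: zero-margin 2×2 tables give p = 1 with a warning, zero-
coverage groups are untestable (p = 1 in the vectorized path, an error in
the scalar API), empty qualified sets produce empty tables with a
warning, and BH on an empty vector returns an empty vector. Ties in p are
handled by stable sorting; all boundary comparisons (≥ 20×, ≥ 25 points,
≤ 0.01, < 5, > 0.1, < 20%, ≥ 80%) follow the inclusive/strict conventions
listed above.
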