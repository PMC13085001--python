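# Methods

## Overview

`gltdseq` quantifies a global length-dependent signature in two-group
bulk RNA-seq comparisons. The pipeline is: library-size normalization →
expression filtering → per-gene differential expression (internal
negative-binomial Wald test, or an externally produced DE table) →
length binning and up-ratio regression → π-value-ranked permutation GSEA
→ cross-cohort reproducibility metrics. Every stage is also exercised
against a synthetic data generator whose ground truth is known, so the
statistical behaviour of the whole stack (recovery, calibration, power)
is testable without any external dataset.

## The synthetic data generator

The generator emulates a small-cohort mouse hippocampus RNA-seq study:

* **Gene universe.** Genomic lengths are log₁₀-normal, mean 4.3, sd 0.6,
  clipped to [10^2.5, 10^6.5] bp — mimicking mouse protein-coding genomic
  spans (median ≈ 20 kb). Expression base means are log₁₀-normal (mean
  2.0, sd 0.7 → median ≈ 100 normalized counts), independent of length by
  default; a `length_abundance_corr` knob couples them when a negative
  length–abundance correlation is wanted. NB dispersions follow
  Gamma(2, 0.025) (mean 0.05), typical of bulk RNA-seq with a handful of
  biological replicates.
* **True effects.** Each gene is differential with probability
  `de_fraction` (default 0.3). Differential genes get
  P(up | L) = logistic(−β · (log₁₀L − mean log₁₀L)) with β =
  `gltd_slope` (default 1.0) and |log₂FC| ~ Exponential(mean
  `effect_scale` = 0.2); null genes are exactly zero. The bias enters
  only the *sign*, keeping |log₂FC| length-independent so magnitude and
  direction effects are separable in tests.
* **Counts.** NB(mean = sⱼ · μ_g · 2^(Δ_g·xⱼ), α_g) with library factors
  sⱼ log-normal (sd 0.15 on the natural-log scale) and xⱼ the group
  indicator; α → 0 falls back to Poisson. Samples default to 6 vs 6.
* **Gene sets.** Known-enriched sets sample members with weight
  ∝ exp(bias · Δ_g); null sets sample uniformly.

Why `de_fraction` = 0.3 with effect scale 0.2: the empirical phenomenon
this models is a *dense* genome-wide direction pattern (per-bin
up-ratios drifting from ≈ 0.6 at short lengths to ≈ 0.4 at long lengths)
accompanied by only a handful of genome-wide-significant genes. Effects
of mean 0.2 log₂ units at n = 6 are mostly undetectable individually, so
a substantial minority of weakly shifted genes is exactly the regime that
produces a strong bin-level trend with few DEGs. With these defaults one
simulated cohort yields ~10,000–10,500 expressed genes (mirroring the
"TMM > 1, > 10,000 genes" universe), tens of significant DEGs, and a
fitted slope of ≈ −0.035 per log₁₀ bp.

What the generator does **not** emulate: litter/batch structure,
length–abundance coupling (off by default), splicing and exon structure,
outlier samples, and correlated genes (counts are independent across
genes given the design). Passing tests therefore demonstrate statistical
correctness of the methods under a clean NB world, not robustness to
every artefact of real data.

All randomness flows from one integer seed through fixed per-stage
`SeedSequence` substreams (`gltdseq._rng`), so each stage reproduces
byte-for-byte in isolation.

## Normalization and filtering

* **Median-of-ratios.** Pseudo-reference = per-gene geometric mean over
  samples, restricted to genes with no zeros; size factor = median over
  those genes of count/reference (plain-ratio median, so the per-sample
  median ratio of normalized counts to the pseudo-reference is exactly 1).
* **TMM.** Published trimmed-mean-of-M definition: reference sample =
  upper quartile closest to the mean upper quartile (`reference="auto"`),
  symmetric trimming of 30 % of M values and 5 % of A values, weighted by
  inverse delta-method variances, factors rescaled to geometric mean 1.
* **Expression filter.** A gene is kept when at least one group has
  ≥ `min_replicates` samples with normalized counts strictly > 20
  (strict inequality deliberately). The default `min_replicates` is half
  the smallest group size, rounded up.
* **Length-trend universe.** Genes with mean TMM-normalized CPM > 1
  across samples. "TMM-normalized abundance > 1" is read as CPM on
  TMM-adjusted effective library sizes, the conventional interpretation;
  both threshold and aggregation (`mean` vs `all`) are configurable.

## Differential expression

The internal caller is an intentionally transparent NB Wald surrogate,
not a DESeq2 re-implementation: per-gene group means on the normalized
scale; pooled within-group method-of-moments dispersion
α̂ = Σ(nᵍ−1)·α̂ᵍ / (n₁+n₂−2), floored at 1e-8; log₂FC =
log₂((m_t + ½)/(m_c + ½)) with a configurable pseudo-count; delta-method
standard error from NB variances v = m + α̂m². There is no dispersion
shrinkage across genes, no outlier replacement and no independent
filtering — externally produced DE tables are first-class inputs for
users who want DESeq2 itself.

**Calibration choice.** The Wald statistic's variance is estimated from
only n₁+n₂−2 residual degrees of freedom; against a normal reference the
empirical null type-I rate at 6 vs 6 is ≈ 0.08. The p-value therefore
uses a t reference with df = n₁+n₂−2, which calibrates the null rate to
≈ 0.05 (the statistic itself is unchanged and is asymptotically standard
normal in the large-count Poisson limit). The interaction contrast
(Δ = log₂FC₂ − log₂FC₁, se_Δ = √(se₁²+se₂²)) likewise uses a t reference
with the summed df when the inputs carry one, and a normal reference for
external tables without df. Significance flags always derive from
BH-adjusted p at α = 0.05, never from raw p. Meta-analysis across
cohorts is fixed-effect only (inverse-variance and equal-weight).

## The length trend

* Bins are anchored at the **long** end: genes sorted by descending
  length (ties broken by ascending gene id for reproducibility), complete
  bins of 500 taken from the top, the incomplete shortest bin discarded.
* Direction is called from the sign of each gene's fold change for *all*
  binned genes by default (`mode="all_genes"`). Rationale: with only
  tens of significant DEGs and > 20 bins, a DEG-only ratio would leave
  nearly every bin empty; the dense per-bin pattern necessarily comes
  from nominal fold-change signs. `mode="deg_only"` is available.
* The ratio is the bounded proportion n↑/(n↑+n↓); genes with fold change
  exactly 0 count in neither direction, and bins with an empty
  denominator are dropped from the regression (never imputed). An
  up/down odds variant exists behind `ratio="odds"`.
* The regression is unweighted OLS of up-ratio on log₁₀(mean bin
  length); bins are equal-sized so weights would be nearly uniform
  anyway. At least 3 usable bins and nonzero variance in both axes are
  required; constant ratios raise an error rather than reporting r = 0.
* Cohort comparison: F test by ANOVA of
  `up_ratio ~ log10L * cohort` against `up_ratio ~ log10L + cohort`; the
  reduced model's common slope and cohort main effect are reported as the
  pooled fixed-effects summary. A random-intercept variant is out of
  scope.
* DEG length shift: Mann-Whitney U on genomic lengths of up- vs
  down-regulated significant genes; exact null when both groups ≤ 8,
  tie-corrected normal approximation otherwise.

## Enrichment

Genes are ranked by π = log₂FC × −log₁₀(padj), descending, ties broken
by gene id; adjusted p of exactly 0 (common in exported DE tables) is
clamped to 1e-300 rather than rejected. The enrichment score is the
weighted Kolmogorov–Smirnov running sum with weight exponent 1 (the
cited implementation's default, exposed as a flag): hits add
|π|^w / Σ_hits|π|^w, misses subtract 1/(N−N_hits); ES is the signed
extremum, with exact ties between the positive and negative extremum
broken toward the positive deviation (tolerance 1e-12, applied
identically in the full-profile and hit-position-only code paths so
observed and permuted scores are comparable).

The null is **gene-label permutation** — ES of uniformly drawn same-size
subsets — because the pipeline may only possess a DE table, not
per-sample data. p = (1 + #{same-sign null with |ES| ≥ |ES_obs|}) /
(1 + #{same-sign null}) (never 0 by construction); NES = ES / mean |same-
sign null ES|; BH across sets whose intersection with the ranked universe
lies in [min_size, max_size] = [1, 5000]; the leading edge is the hits at
or before the ES extremum. Defaults: 10,000 permutations, deterministic
for a fixed seed (null distributions are cached per set size).

## Reproducibility metrics

Profile correlations are Pearson on log₂(normalized + 1), with
median-of-ratios factors computed per cohort and genes restricted to the
intersection of the cohorts' universes; all within- and between-cohort
sample pairs are summarized as mean ± sd, plus the percentage difference
of the pooled within mean over the between mean and the shared variance
r². Directionality consistency is the fraction of selected genes (the
reference cohort's DEGs by default, or all shared genes) whose fold-change
signs agree, zeros excluded and counted, with an exact two-sided binomial
test against 0.5. Overlap analysis enumerates every region of the
inclusion–exclusion partition of named DEG sets and can list genes "lost
by pooling".

## Numerical and design notes

* Problem sizes in the test-suite calibration checks: 100 replicate
  datasets for slope recovery, 200 for null calibration, ≥ 20,000 null
  gene-tests for the type-I rate, 50,000 genes for the Poisson-limit
  normality check — sizes at which the binomial/KS tolerances used are
  meaningful.
* `scripts/acceptance.py` uses 50 seeds per rate; every quantity it
  reports is recomputed from scratch at run time from `--seed`.
* Scaling one sample of a count matrix by λ rescales the median-of-ratios
  pseudo-reference by λ^(1/m), so the scaling identity holds on factor
  *ratios* (sample k's factor relative to any other gains exactly λ);
  tests check the ratio form.
* GTF coordinates are treated as 1-based inclusive throughout; gene
  length defaults to the genomic span (end − start + 1) of the gene
  feature, with merged-exon length as an option, since annotation
  pipelines differ in which "gene length" they export. Gene identifiers
  match exactly (case-sensitive, version suffix kept); `strip_versions`
  is off by default.
* Pipeline manifests echo the configuration (minus the output directory)
  and input SHA-256 digests but no timestamps, so two runs with the same
  config and seed are byte-identical.

## Known limitations

* The NB Wald surrogate is anti-conservative when counts are very low
  (< ~5 per group mean) and has no moderation across genes; use an
  external DE table for production differential expression.
* The permutation GSEA is O(n_perm × set sizes); no multilevel or
  adaptive speedups are implemented.
* The cohort comparison treats bins as independent observations, as the
  binning construction intends; spatial autocorrelation between adjacent
  bins (shared genes are none, but shared biology possibly) is not
  modelled.
* `mode="deg_only"` with few DEGs leaves most bins undefined; the
  regression then errors below 3 usable bins rather than guessing.
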