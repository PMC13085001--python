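# gltdseq

Tools for detecting **gene-length-dependent transcriptional decline (GLTD)**
in bulk RNA-seq experiments, together with the surrounding analysis a
multi-cohort stress/aging transcriptomics study needs: normalization,
differential expression, π-value-ranked permutation gene-set enrichment,
and cross-cohort reproducibility metrics. A negative-binomial count
simulator with a programmable length-dependent direction bias provides a
ground-truth test bed for every stage.

## Who this is for

Transcriptomics researchers who observe that individual differentially
expressed genes fail to replicate across cohorts, and want to ask whether
a reproducible *global* signature exists instead — in particular the
aging-like pattern in which short genes are preferentially upregulated
and long genes preferentially downregulated after a stressor.

## The core statistic

Take the analyzed gene universe (conventionally: genes with mean
TMM-normalized CPM > 1), sort by genomic length, and group into
consecutive bins of 500 genes anchored so the bin of *longest* genes is
complete (the incomplete shortest bin is discarded). Per bin *i* with
mean length L̄ᵢ, count genes whose fold change is positive (n↑) or
negative (n↓) and form the up-ratio

    rᵢ = n↑ / (n↑ + n↓)

The GLTD trend is the OLS fit

    rᵢ = α + β · log₁₀(L̄ᵢ) + εᵢ

reported with slope β, Pearson r, t = r·√(df / (1 − r²)) at df = n_bins − 2,
and the two-sided p. β < 0 is the GLTD signature. Cohorts are compared by
ANOVA of the model with and without a length × cohort interaction term.
Supporting statistics: a Mann-Whitney U test comparing lengths of up- vs
down-regulated DEGs, π-value ranking (log₂FC × −log₁₀ padj) for
permutation GSEA against aging signature gene sets (GMT), fixed-effect
(inverse-variance and equal-weight) meta-analysis across cohorts, and
within/between-cohort expression-profile correlations.

## Worked example

Simulate one cohort at the default study conditions (12,000 genes, 6 vs 6
samples, a length-dependent direction bias of 1.0 on the log-odds of
upregulation per log₁₀ bp), call differential expression, and fit the
length trend on the TMM > 1 universe:

```python
from gltdseq import SimulationConfig, NBWaldModel, GeneLengthTrendModel
from gltdseq.simulate import simulate_two_group_experiment
from gltdseq.normalize import tmm_factors, tmm_abundance_filter

cfg = SimulationConfig(seed=7)
universe, effects, counts = simulate_two_group_experiment(cfg)

de = NBWaldModel(counts).fit()
print(de.summary())

tmm = tmm_factors(counts)
kept = tmm_abundance_filter(counts, tmm, threshold=1.0)
trend = GeneLengthTrendModel(
    de.table[de.table["gene_id"].isin(kept)],
    universe.loc[kept, "length_bp"],
).fit()
print(trend.summary())
```

Output:

```
NB Wald differential expression
  contrast: ELS vs control
  genes tested: 12000
  significant (padj < 0.05): 93 (57 up, 36 down)
  mean |log2FC| of significant genes: 0.867

Gene-length trend (up-ratio vs log10 length)
  bins used: 23 x 500 genes (210 shortest discarded)
  direction mode: all_genes
  slope: -0.0453 per log10(bp)   intercept: 0.6946
  Pearson r = -0.862, t(21) = -7.80, p = 1.23e-07
```

Few individual genes reach significance (93 of 12,000, with most true
effects far below the detection limit), yet the global trend is
unambiguous: the up-ratio falls by ≈ 0.045 per decade of gene length
(r = −0.86, p ≈ 1e-7), recovering the programmed bias. `trend.plot()`
draws the per-bin ratios with the fitted line.

The same stages are available from the shell:

```sh
gltdseq simulate --n-genes 12000 --seed 7 --outdir sim/
gltdseq de --counts sim/counts.tsv --meta sim/samples.tsv --out de.tsv
gltdseq gltd --de de.tsv --annotation sim/annotation.tsv --out fit.json
gltdseq gsea --de de.tsv --gmt sim/sets.gmt --out gsea.tsv
gltdseq run --config pipeline.yaml     # full pipeline from YAML
```

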