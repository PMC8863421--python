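# stressmwas

A tested, reusable implementation of a methylome-wide association (MWAS)
workflow for studying early-life environments and adult mental health in a
family-based cohort — together with a synthetic family-structured cohort
generator that makes every stage testable without access-restricted data.

## Who this is for

Epigenetic epidemiologists running EWAS/MWAS on array methylation data from
related individuals (family cohorts), and methodologists who want a small,
fully-tested reference implementation of the moving parts: phenotype
construction, mixed-model correction of M-values, two association engines,
inflation diagnostics, probe-bias-corrected gene-set enrichment, methylation
profile scores, kinship GLMMs and mediation.

## What it computes

- **Early-life phenotypes** from raw birth records: preterm birth
  (gestation < 37 weeks), low birth weight (below a sex- and
  gestation-adjusted centile threshold), birth month (April–October), a
  continuous seasonal birth-date score
  `y = −cos(2π(date + 10)/365)` running from −1 at the winter solstice to +1
  at the summer solstice, young parent (< 21 years), lone parent, urban
  birth region and population density; plus a psychological-resilience score
  (first unrotated principal component of six Likert items, with iterative
  tree-ensemble imputation of sparse missingness).
- **Methylome preprocessing**: detection/beadcount/sex-mismatch QC with the
  standard boundary conventions, M-values as `log2(meth/unmeth)`, then a
  two-stage per-CpG mixed-model correction — (1) plate and blood-draw date
  as crossed random intercepts with technical fixed effects, (2) the five
  pedigree covariance structures (G: common genetic, K: kinship, F: nuclear
  family, C: couple, S: sibling) as random effects with sex, age and
  estimated cell proportions as fixed effects.
- **Engine 1 (probewise)**: per-CpG OLS of M-values on the phenotype with
  shared covariates (Set, smoking, 20 methylome PCs) and empirical-Bayes
  moderated t-statistics — posterior variance
  `(d0·s0² + d·s²)/(d0 + d)`, prior df by trigamma inversion.
- **Engine 2 (multi-component mixed model)**: an initial scan with the
  phenotype as dependent variable groups probes by association P; each
  group's methylome relationship matrix `Z_g Z_gᵀ/p_g` (excluding the target
  probe and a ±50 kb window) enters as a random effect, blood-cell counts as
  fixed effects, and the target's effect is Wald-tested under REML.
- **Diagnostics and downstream**: genomic inflation λ (median observed χ²
  over the null median 0.455), Bonferroni thresholds (0.05/713 522 =
  7.01 × 10⁻⁸ at methylome scale; 0.05/8 across phenotypes), QQ/Miami data
  exports, location-based gene annotation, Wallenius noncentral
  hypergeometric gene-set enrichment correcting for probes-per-gene bias,
  profile scores (effect-weighted M-value sums at seven P thresholds with
  Nagelkerke/adjusted R² evaluation), kinship GLMMs and
  product-of-coefficients mediation with percentile bootstrap.

## Worked example

`examples/run_association.py` simulates 300 related individuals × 400 CpGs
with one planted causal CpG, corrects the methylome, and runs both engines:

```
planted causal CpG: cg000370
engine 1 (probewise): effect -0.3154 (se 0.0316), P = 1.62e-20, lambda = 1.007
engine 2 (mixed model): effect -0.8364 (se 0.0812), P = 2.45e-21, lambda = 1.048
Bonferroni threshold at alpha 0.05 over 400 CpGs: 1.25e-04
```

Both engines flag the planted site far below the Bonferroni threshold with
concordant sign (engine 1 reports M-value change per phenotype SD; engine 2
reports the phenotype change per M-value unit, hence the different scales),
and λ ≈ 1 shows the null bulk of probes is calibrated. The other scripts in
`examples/` demonstrate cohort simulation, phenotype construction, profile
scores across the two cohort Sets, enrichment/inflation diagnostics and
mediation, each printing a short annotated result.

A thin CLI mirrors the library for shell use:
`stressmwas {simulate, mwas1, mwas2, post, score, mediate, run}`.

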