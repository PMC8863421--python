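# Methods

This note records the models implemented, the estimation choices, what the
synthetic cohorts emulate, and the limitations a user should know about.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic family cohorts

The generator (`stressmwas.synth`) emulates a family-based methylation
cohort at desk scale. Individuals are organised into independent nuclear
families — two unrelated founders plus 0–3 offspring, the mix controlled by
`family_distribution` — which induces the five covariance structures used by
the correction model: K (expected relatedness: parent–offspring and full
sibs 0.5), F (whole-family indicator), C (couple), S (sibship), and G
defaulting to K (`separate_g` gives G an independent draw; with pedigree
data only, common-genetic and kinship components coincide). Whole families
are assigned to one of two Sets so the Sets share no relatives, matching the
discovery/target split used for profile scores.

Each CpG's M-values are a sum of component draws (Cholesky factors of the
relationship matrices scaled by `variance_fractions`), plate and
blood-draw-date random intercepts, an optional cell-composition term, iid
noise, and a per-CpG baseline level. Default variance fractions
(K 0.20, F 0.10, C 0.05, S 0.05, plate 0.10, date 0.05, residual 0.45) are
plausible placeholders: published estimates of these methylome variance
shares in family cohorts are scarce, so the defaults are chosen to give
every component a testable footprint, not to estimate any real dataset.
Binary phenotypes arise from a
liability threshold: liability = Σ(slope × M over causal CpGs) + a
kinship-correlated familial term + iid residual, standardised and cut at the
normal quantile of the configured prevalence (defaults 3.5% "preterm", 13%
"MDD", typical population rates for these traits). Continuous phenotypes
are the
standardised liability, so a planted slope β appears downstream attenuated
by the liability SD √(β²·var(M) + 1); recovery tests compare against that
induced value.

Blood-cell compositions are Dirichlet draws (lymphocyte subsets + monocyte
+ granulocyte) with small measurement noise so the six proportions do not
sum exactly to one, as with reference-based deconvolution estimates.
`seasonal_cell_shift` moves lymphocyte-lineage proportions up and
neutrophils down in proportion to the birth-date score, and
`cell_meth_fraction`/`cell_affected_prop` let a subset of CpGs load on the
cell factor — together these create the seasonal confounding scenario in
which an engine without cell adjustment inflates. Haematology-style count
columns (basophil…neutrophil) carry the same factor with small noise,
reflecting the precision of analyser counts.

What the generator does **not** emulate: raw array intensities, bimodal
beta-value distributions, co-methylation blocks beyond an optional AR(1)
residual correlation, genotype data, ascertainment, or age/sex effects on
methylation. Passing tests therefore demonstrate correctness of the
estimators under the stated covariance model, not robustness to every
feature of real arrays.

All randomness flows from one integer seed; each stage (pedigree, methylome,
phenotypes) uses a `SeedSequence` substream keyed by stage index, so any
stage regenerates bit-identically.

## Variance-component estimation

All mixed models reduce to REML estimation of
`V = Σ_c σ²_c A_c + σ²_e I` (`stressmwas.reml`). The estimator is
average-information (AI) REML initialised by Haseman–Elston regression, with
per-component tolerance 10⁻⁶ on the scaled score and at most 50 iterations.
Updates are guarded: components are clamped individually at a small floor
(a component headed negative must not strangle the global step), steps along
flat directions are removed by a pseudo-inverse of the AI matrix, and wild
overshoots are capped.

Three structure-exploiting paths give exact results (they solve the same
score equations) at a fraction of the dense cost, verified against the
dense path and against `statsmodels.MixedLM` in the tests:

- **Low-rank (Woodbury)** for crossed random intercepts given as incidence
  factors (plate, draw date): O(n·q) per iteration with q total levels.
- **Block-diagonal** for pedigree matrices over independent families:
  batched per-family inversion, O(Σ b²) per iteration.
- **Eigen + small-Woodbury** for the single-methylome-component association
  model: the full-probe relationship matrix is eigendecomposed once and the
  per-target exclusion handled as a k-rank downdate, O(n·(k + p)) per
  iteration.

**Degenerate splits.** On purely nuclear pedigrees the structures are
exactly collinear (K − I = ½(F − I) − ½(C − I), and G = K), so the
five-way variance split — though not V itself — is unidentified. The flat
directions of the component Gram matrix are resolved deterministically by
attributing ambiguous variance to the residual (a small linear program).
This makes the all-identity edge case collapse exactly to OLS and keeps
corrected matrices reproducible. Fraction-recovery tests use the
identifiable subset {K, F, S} with C generated at zero.

**Correction residuals.** Both correction stages return the mixed-model
(BLUP) residual `σ²_e V⁻¹(y − Xβ̂)`, which is exactly orthogonal to the
fixed design. Note that BLUP residuals of relatives carry the small
*negative* correlation of the off-diagonal of V⁻¹ (≈ −0.12 for siblings at
a kinship share of 0.35) — the positive familial correlation is fully
removed, but whitened residuals are not independent; tests assert the exact
expectation.

## Engine 1: probewise moderated linear model

Per CpG, OLS of (corrected) M-values on the phenotype plus shared fixed
effects; continuous phenotypes standardised so effects are per SD; binary
phenotypes coded 0/1; complete-case per phenotype. Methylome principal
components (default 20, computed from the corrected matrix — a flag allows
raw) join the covariates. Residual variances are shrunk by moment matching
of log-variances to a scaled-F prior: the prior df solve
`trigamma(d0/2) = var(log s²) − trigamma(d/2)` by monotone bisection
(tolerance 10⁻⁸), the prior variance from the mean. Degenerate inputs: no
excess scatter → d0 = ∞ with the prior at the common variance; d0 = 0
reproduces ordinary OLS t-tests exactly. The moderated t uses d + d0
degrees of freedom. The implementation is cross-checked against the
reference R implementation of the moderated t in the test suite.

## Engine 2: multi-component mixed model excluding the target

The scan regresses the phenotype on each probe (Frisch–Waugh residualised,
so the t equals the joint fit's). Probes are binned by scan P (default two
groups split at 0.05). For each target, group relationship matrices are
built from standardised probes excluding the target and any probe within
50 kb (same chromosome), maintained by rank-1 downdates of precomputed
full-group matrices. The phenotype is then regressed on the target with the
group matrices as random effects and the five cell-count columns as fixed
effects; the Wald t of the target uses n − p df. Binary phenotypes are
analysed on the 0/1 scale in the linear mixed model. Exact mode re-estimates
variance components per target (warm-started from the previous target); an
approximation mode freezes them from a target-free fit and is flagged in the
output.

**Small-cohort guard.** A lead group selected on the scan statistics that
contains fewer probes than samples is low-rank, and REML credits it with the
phenotype's chance alignment, deflating every test — at a few thousand
probes this is severe, while at biobank scale the 5% lead group exceeds the
sample count many-fold and the issue vanishes. Groups smaller than
`min_component_probes` (default: the sample count) are therefore merged
into their neighbour. Calibration tests exercise this guarded default.

**Inflation estimates.** λ computed from a single phenotype's probes has
substantial sampling noise (the median estimator plus a shared-phenotype
scale factor, SD ≈ 0.07 at 2000 probes), so calibration checks pool
P-values across five independent null phenotypes simulated on the same
cohort.

## Post-association

λ = median(χ²₁ quantiles of P) / 0.45494 (library inverse-CDF, no tables).
QQ expected values use rank/(n+1) with pointwise beta(i, n−i+1) bands.
Miami export writes signed −log10 columns (engine 1 negative), genome
ordered, with missing probes kept as null cells. Gene-set enrichment draws
genes with weights proportional to raw probe counts: the null is Wallenius'
noncentral hypergeometric with odds the ratio of mean probe counts inside
vs outside the set; equal counts reduce exactly to the central
hypergeometric. Unadjusted P is the headline decision value with a BH-FDR
column alongside.

## Profile scores, GLMM, mediation

Scores are Σ(discovery effect × target M-value) over CpGs below each of the
seven thresholds 10⁻⁷…10⁻¹; nested thresholds give monotone site counts; a
shared sample between discovery and target is a hard error. Binary outcomes
are evaluated by the Nagelkerke R² increment of the score over the
covariate-only logistic model, `(1 − exp((2/n)(ℓ₀ − ℓ₁)))/(1 − exp((2/n)ℓ₀))`
with likelihood-ratio P; continuous outcomes by the adjusted-R² increment
with an F-test. All seven thresholds are reported with the best-R² row
flagged; the selection-aware null test documents the optimism this induces;
significance is gated at α/8.

The phenotype-level GLMM fits outcome ~ exposure + sex with a
kinship-structured random effect: exact eigen-REML for gaussian outcomes;
penalised quasi-likelihood with fixed unit dispersion for binomial-logit
(working response iterated with per-iteration eigen-REML of the whitened
kinship). PQL fixed effects are mildly biased toward zero at low prevalence
— recovery tests document the operating range; the bias caveat applies to
rare outcomes.

Mediation uses the product-of-coefficients decomposition: a from the
mediator regression, b and c′ from the outcome model (Newton logistic for
binary outcomes), indirect = a·b on the outcome model's linear-predictor
scale, total from the outcome model without the mediator
(total = direct + indirect exactly in the linear case). Percentile bootstrap
over individuals (default 2000 draws, fixed seed) supplies CIs and sign-test
P-values; the quasi-Bayesian alternative was rejected in favour of this
transparent, oracle-checkable scheme.

## Problem sizes

Test and acceptance runs use desk-scale cohorts chosen to make each
statistical property measurable: 500 × 2000 for null calibration (five null
phenotypes pooled), 100 replicates of 500 × 300 for slope recovery, 300 ×
1000 for the seasonal confounding contrast, 5000 probes for eBayes
hyperparameter recovery. These sizes are the package's reference conditions;
all scale linearly in probes and near-cubically in samples only through the
dense REML paths.

## Known limitations

- The five-component correction cannot attribute variance between exactly
  collinear structures on nuclear-family pedigrees (see above); only the
  fitted V is meaningful there.
- Engine 2's finite-sample behaviour below ~2 probes per sample relies on
  the lead-group guard; ungated two-group fits at that scale are
  conservative by construction.
- PQL binomial GLMMs underestimate kinship variance at low prevalence.
- The generator's M-values are Gaussian; heavy-tailed or bimodal
  methylation distributions are not represented, so moderation hyperprior
  estimates on real arrays will differ from the simulated recovery setting.
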