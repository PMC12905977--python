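# Methods

## Model

The trait for individual *i* is modelled, after removal of fixed effects,
as

    y = Z_m β_m + Z_g β_g + e,        e ~ N(0, σ²_e I)

where `Z_m` (n × p_m) holds covariate-adjusted, column-standardized CpG
probe values and `Z_g` (n × p_g) column-standardized allele dosages.
Every marker effect follows a finite spike-plus-mixture prior per marker
set *s*:

    β_{s,j} ~ π_{s,0} δ₀ + Σ_{k=1..K} π_{s,k} N(0, c_k σ²_P)

with component variances `c_k` that are **fixed fractions of the
phenotypic variance** — default (10⁻⁴, 10⁻³, 10⁻²), i.e. classes of
markers capturing 0.01%, 0.1% and 1% of σ²_P.  Several mixture-regression
programs instead scale components by a sampled per-set genetic variance;
the fixed-fraction parameterization is declared canonical here because it
keeps class membership directly interpretable ("a large-class marker
captures about 1% of trait variance") and makes the per-class
architecture comparable across marker sets.  Mixture proportions carry a
symmetric Dirichlet(α), default α = 1 per component including the spike;
the residual variance a scaled-inverse-χ²(ν₀ = 4, s₀² = 0.5·Var(y))
prior.  The trait is standardized internally; all reported fractions are
invariant to that scaling.

### Gibbs sampler

One sweep visits every marker in a fresh random permutation (drawn from a
dedicated RNG stream so that update order is independent of storage
order), computes the marker's residual association with the current
residual vector, evaluates the log marginal density of the data under
each component, samples the component indicator, and — if non-spike —
samples the effect from its conjugate normal.  After each sweep the
per-set mixture proportions are drawn from their Dirichlet posterior and
σ²_e from its scaled-inverse-χ² posterior.  The numerical core is a
numba-compiled kernel; all random numbers are generated outside it from a
`numpy.random.Generator` seeded per chain via `SeedSequence(seed,
spawn_key=(chain,))`, so runs are bit-reproducible.

Per retained draw the variance contribution of set *s* is the realized
`Var(Z_s β_s)` (robust to residual correlation among markers, unlike
Σβ²), and the reported fraction divides by `Σ_t Var(Z_t β_t) + σ²_e`.
Cross-set covariance is deliberately excluded from the denominator so
that set fractions plus the residual fraction sum to one in every draw;
with mQTL-coupled sets the excluded covariance is small (order of the
coupling share) and the convention is stated here once rather than ad
hoc per result.  Credible intervals are equal-tailed percentiles of the
retained draws pooled across chains.  PIP(j) is the fraction of retained
draws in which marker *j* is non-spike; per-marker class membership is
recorded as well, because the *expected class count* `E[#class k]`
includes an irreducible contribution from null markers (the expected
Bayes factor under the null is 1), so single-marker questions should be
asked of the membership matrix, not the counts.

Defaults: n_iter = 10 000, burn-in = 5 000, thin = 5, 2 chains — a
conservative spec exposed in `McmcSpec`.  The test-suite and the
acceptance script use shorter chains (700–1600 sweeps, 1 chain) and
desk-scale cohorts (n ≤ 3000, p_m ≤ 2000, p_g ≤ 3000); at those sizes
between-chain agreement of the set fractions is < 0.01, which is why the
shorter spec is adequate there.

### Divergence and validation guards

Inputs must be column-standardized (|var − 1| ≤ 10⁻³) — fractions are
otherwise meaningless; a residual-variance draw exceeding 10·Var(y)
aborts the chain.  The single-marker conjugate case (exact normal
posterior and two-component Bayes factor) is the gating unit test for any
sampler change.

## OREML

The sensitivity estimator replaces the mixture with the infinitesimal
model `y ~ N(Xb, Σ_k σ²_k K_k + σ²_e I)`, with `K = (1/p) Z Zᵀ` on the
standardized (probe) or allele-frequency-standardized (SNP) markers.  The
restricted likelihood is maximized by average-information (AI) Newton
steps; the first two iterations use EM, and whenever an AI step proposes
a negative component that component is pinned at the boundary while the
AI move is kept for the rest (a pure EM fallback only crawls toward the
boundary).  Convergence at |Δ logL| < 10⁻⁸ or relative parameter change
< 10⁻⁶, at most 100 iterations; non-convergence raises rather than
returning partial estimates.  Fractions of phenotypic variance get
delta-method standard errors from the inverse AI matrix and symmetric
±1.96·SE confidence intervals.  A kernel numerically proportional to the
identity raises an identifiability error (its component would be aliased
with σ²_e).  The eigen-rotation identity — REML on (K, y) equals REML on
(Λ, Uᵀy) — is kept as an exact internal oracle.

### Bivariate cross-group decomposition

To ask whether probe effects are shared between groups (the sexes), the
trait in each group is treated as a separate trait observed on disjoint
individuals; the covariance model places `r·σ₁·σ₂·K₁₂` on the cross
block.  Five parameters (two marker variances, two residual variances,
atanh r) are optimized by Nelder–Mead from two starts (r₀ = ±0.5); the SE
of r comes from the delta method on a central-difference Hessian, falling
back to profile-likelihood curvature in r when the z-scale Hessian
degenerates (which it does whenever r̂ approaches ±1).  The test of r = 1
is a likelihood-ratio test against the boundary mixture ½χ²₀ + ½χ²₁.

A caution that shapes the test design: the estimator recovers the
*realized* correlation of the two effect vectors.  Under a sparse
architecture dominated by a few large effects the realized correlation
scatters around the planted value with SD ≈ 1/√(effective marker count),
so planted-truth recovery is only a meaningful check under a dense
single-class architecture (all probes causal), which is what the tests
use.

## Synthetic cohorts

`simulate_cohort` emulates the statistical structure of a population
cohort with array methylation and genotypes:

* genotypes: per-SNP MAF ~ U(0.05, 0.5), dosages Binomial(2, maf);
* methylation: additive on the logit scale and squashed by the logistic
  function — per-probe level μ_j ~ U(−1.5, 1.5), individual noise
  sd 0.35, and for a fraction `mqtl_frac` (default 0.3) of probes one
  cis-driver SNP explaining `mqtl_r2` (default 0.2) of the latent
  variance;
* confounding: batch offsets (4 batches, sd 0.08), a neutrophil-fraction
  loading (sd 0.15) on Dirichlet cell proportions, and slide labels
  perturb the **measured** beta values only.  Trait effects act on the
  confounder-free probe signal: this is the generative counterpart of
  adjusting probes for technical covariates before analysis, and it keeps
  the planted estimand identical to what the adjusted probes carry.  (If
  effects are instead placed on the raw measured probes, a chance
  alignment between the effect vector and the cell-loading vector puts a
  seed-dependent slice — up to ~20% — of the trait's probe component
  inside the covariate span, where residualization deletes it; the
  planted fractions are then not recoverable by any estimator.)
* effects: four classes {null, small, medium, large} with variance ratio
  1 : 10 : 100, then one multiplicative rescale per set so the realized
  `Var(Z β)` hits the target fraction of σ²_P exactly.  Default class
  probabilities put the probe variance mostly in the medium class and the
  SNP variance mostly in the small class, mirroring the architecture a
  large cohort analysis reports for height; the realized (not target)
  fractions are recorded in the truth block.
* phenotype: intercept 162 cm, sex effect +14 cm (the male–female gap),
  age slope −0.05 cm/yr, plus the two marker contributions and a Gaussian
  residual; the fixed-effect-adjusted SD is 6.5 cm (a within-sex adult
  height SD).  A noisy polygenic-score proxy anchored to the true genetic
  value (R² default 0.6) is emitted as a covariate column.
* `cross_sex_corr` switches on sex-specific probe-effect vectors with the
  given correlation.

A single `numpy.random.Generator` keyed by `seed` drives every draw in a
fixed order (genotypes, covariates, methylation, effects, residual), so
identical configs reproduce cohorts bitwise.

What the generator does **not** emulate: probe–probe correlation beyond
shared drivers, non-Gaussian effect-size tails, age-varying methylation,
population structure/relatedness (all simulated individuals are
unrelated; the relatedness filter is exercised on constructed matrices),
and missingness.  Passing tests therefore demonstrate estimator
correctness under the stated generative model, not robustness to every
feature of real array data.

## Preprocessing conventions

Phenotype: OLS residuals on intercept, age, age², sex, plus optional
extra fixed effects (a polygenic score for the PGS-adjusted variants —
equivalent to a fixed-effect block in the regression likelihood, and kept
out of the sampler for simplicity).  Probes: residualized on age, sex,
batch, slide, cell proportions (one simplex column dropped against the
intercept) and smoking score, **then** standardized; genotypes are
standardized only.  Zero-variance columns are dropped and recorded,
never imputed (a mean-imputation helper exists for real-data ingestion
and is off by default).  Relationship matrices are (1/p)·Z·Zᵀ with
chunked accumulation over marker blocks; the dosage-based GRM uses the
standard 2p̂ centering and √(2p̂(1−p̂)) scaling.  Relatedness filtering is
greedy by above-threshold degree with a deterministic tie-break (the
highest-index individual among the most-connected is removed).  The CLI
raises the threshold to the GRM sampling-noise floor 6/√p when the
configured value sits below it — with few SNPs a 0.05 threshold is below
the noise of the GRM itself and would discard unrelated individuals.

## Scoring and PheWAS choices

The cm-rescaling of a profile score z-scores it in the target sample and
re-anchors to the **training** phenotype mean/SD (target-sample anchors
available by flag); only the affine class matters for correlations and
R².  Decile contrasts use empirical quantile ranks with stable tie
order and a Welch t-test.  Incremental adjusted R² is the adjusted-R²
difference of nested OLS fits, with the score's Wald p-value; a score
collinear with the base model is flagged and contributes zero increment.
PheWAS regresses the score on each standardized phenotype with
standardized age/sex adjustment (score as outcome, following the
discovery convention), complete-case per phenotype, Bonferroni threshold
α divided by the number of phenotypes in the panel; a parallel block runs
measured height as the outcome for comparison.

## Problem sizes and numerical notes

The packaged tests and `scripts/acceptance.py` run at desk scale: main
cohorts n = 2000 with p_m = 2000, p_g = 3000; discovery at n = 3000;
bivariate fits at n = 500; ten replicates where replicate counts matter.
These sizes were chosen so the whole suite runs on one CPU in minutes
while keeping the Monte-Carlo error of each check well below its
tolerance.  Paper-scale dimensions (n ≈ 7600, p_m ≈ 750k, p_g ≈ 500k)
are reachable through the same API — the sampler is O(n) per marker per
sweep and the relationship matrices accumulate in column blocks — but
need memory planning for the marker matrices (a float64 750k-probe matrix
at n = 7600 is ~45 GB; block-wise residualization and an out-of-core
matrix store would be the first additions).

Degenerate inputs are rejected rather than repaired: non-standardized
marker sets, all-null class configurations with a positive target
fraction, single-sex bivariate inputs, thresholds outside their domains,
ragged or out-of-range data files.
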