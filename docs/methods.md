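# Methods

## The synthetic cohort generator

The generator is the package's substitute for a restricted-access twin
registry: it produces wide per-individual tables with exactly the covariance
structure the downstream models assume, plus configurable violations
(attrition, trajectory subgroups) for robustness checks.

Latent factors are drawn jointly per family from the Kronecker covariance
`pair-relatedness ⊗ cross-wave correlation` — for A the pair matrix has
off-diagonal 1.0 (MZ) or 0.5 (DZ), for C it is 1.0 for all pairs, for E it is
0 — so the within- and between-twin covariances hold exactly by construction,
not asymptotically. Phenotypes combine the standardized factors with per-wave
path weights √a², √c², √e²; the population variance is 1 per measure-wave
before mean structure, and mean structure (wave shifts, sex effects) never
alters variance. Matrix square roots are taken by eigendecomposition with
eigenvalues below `1e-12·λmax` set to exactly zero, so degenerate
specifications (e.g. unit factor correlations) give exactly identical, not
numerically-nearly-identical, latent scores.

Default parameters are the average conditions of the study design the
package reproduces, and are not tuned per analysis:

| parameter | default | meaning |
|---|---|---|
| `n_mz_pairs`, `n_dz_pairs` | 1501, 2380 | complete pairs per zygosity |
| `n_waves` | 5 | baseline + four follow-ups |
| `ace_components` | (0.33, 0.07, 0.60) | standardized variance proportions per wave |
| `corr_A` | CS(0.95) | cross-wave genetic correlation |
| `corr_C` | CS(0.90) | cross-wave shared-environment correlation |
| `corr_E` | CS(0.41) | cross-wave nonshared-environment correlation |
| `sex_effect` | 0 | male−female mean gap, s.d. units (±half per sex) |
| `age_range` | 22–26 y | uniform; co-twins share age |
| `skew` | 0 (off) | optional exponential transform; analyses use untransformed scores by default |

CS(ρ) denotes a compound-symmetric correlation matrix. The shared-environment
stability 0.90 is a design choice: no average value is reported for it in the
study this emulates, and with c² = 0.07 the downstream estimates are
insensitive to it; 0.90 encodes the usual finding that family-level
environment is highly stable over a few years. MZ pairs are forced same-sex;
DZ pairs are same-sex with probability 0.5 and are not modelled separately by
sex composition (no sex-limitation model). Generation truth (latent baseline
A scores, profile class labels) lives in a sidecar table that the analysis
CSV never contains, so recovery tests cannot leak it.

Attrition is per individual-wave (a non-responding individual loses all
measures at that wave), never at baseline. MCAR drops with probability
1−retention; MAR lowers the retention odds with the individual's mean
baseline z-score, `logit p − slope·z` (default slope 0.5), so high scorers
drop out more — the direction that makes retained samples look healthier.
Both mechanisms are provided; neither is asserted to match any real
registry's attrition.

Polygenic scores are generated as `ρ·A₁ + √(1−ρ²)·G` with G an independent
genetic-type factor, giving MZ-identical, DZ-0.5-correlated scores whose
correlation with the baseline genetic factor is exactly ρ. No genotypes, LD
or GWAS machinery are simulated — scores are continuous columns only.

What the generator does *not* emulate: item-level measurement, floor/ceiling
effects and ordinal scales, assortative mating, sibling interaction,
age-moderated heritability, non-normal tails (unless `skew` is enabled), and
realistic attrition processes. Passing recovery tests therefore shows the
estimators are correct under the stated model, not that real questionnaire
data satisfy that model.

## Pre-analysis transformations

Each measure-wave is residualized on sex and age by a single pooled OLS fit
(not per zygosity group) on rows with both phenotype and covariates observed;
residuals are standardized to mean 0, s.d. 1 in the estimation sample, which
makes the transformation idempotent. Rows with missing covariates but an
observed phenotype receive predictions with covariates filled at the sample
mean, maximizing wave coverage. Standardization uses the full observed sample
per wave, not the subsample retained at later waves. Co-twins are identical
in age and MZ co-twins in sex, so skipping this correction would inflate
shared-environment estimates.

## The FIML engine

All covariance-structure models (ACE, correlated factors, Cholesky, growth
curves) route through one multigroup engine. A model maps a named, box-
bounded parameter vector to an implied mean vector and covariance matrix per
group; the objective is the FIML deviance, −2·Σᵢ log φ(xᵢ; μ(θ), Σ(θ))
restricted to each row's observed variables. Rows are grouped by missingness
pattern and reduced to (count, mean, scatter), so one deviance evaluation
costs one Cholesky factorization per pattern regardless of n.

Numerical choices:

- Non-positive-definite implied covariances return a penalty that grows with
  the most negative eigenvalue, steering the optimizer back rather than
  raising.
- Optimization is L-BFGS-B (`ftol` 1e-10, `gtol` 1e-6, max 2000 iterations)
  from a documented start vector plus up to four seeded jittered restarts
  (jitter s.d. 0.2·(1+|start|), clipped to bounds). L-BFGS-B occasionally
  stops on a failed line search while reporting success, so solutions are
  polished by re-minimizing from the stopping point until the *projected*
  gradient (components pushing into an active bound are zeroed) is small
  relative to the deviance; only then is a solution marked converged.
  Restarting stops early once two independent starts agree to 1e-6.
- Non-convergence is flagged on the result, never silent.
- Confidence intervals are profile-likelihood: the bound is where the profile
  deviance (inner re-optimization warm-started at the solution) rises by the
  χ²(1) quantile, located by doubling-bracket plus Brent root finding. A
  bound that reaches a box constraint is reported at the constraint
  (boundary-censored); this is the documented behaviour for components near
  0 or correlations near ±1, where the χ² calibration is itself conservative.
- Likelihood-ratio tests reject a negative deviance difference beyond
  1e-4·(1+|deviance|) as a fit failure rather than truncating it silently.

## Twin models

The univariate ACE model is parameterized as (μ, V, a², c²) with a², c² in
[0,1] — proportions are estimated directly so profile CIs apply to the
reported quantities, and e² < 0 is excluded automatically because it makes
the implied MZ matrix non-PD. The e² interval comes from a refit with (e²,
c²) as free proportions. Falconer moment estimates (a² = 2(rMZ−rDZ),
c² = 2rDZ−rMZ, e² = 1−rMZ) are reported unconstrained, negative values
flagged; the SEM estimates are authoritative. e² includes measurement error
by construction.

The multivariate model exists in two likelihood-equivalent parameterizations:
correlated factors (per-wave scales plus factor correlations bounded in
[−1, 1], PSD enforced through the likelihood penalty) and Cholesky
(lower-triangular paths with non-negative diagonal). The correlated-factors
form makes rG/rC/rE direct parameters (hence profilable); the Cholesky form
yields per-wave innovation proportions, the wave-specific share of each
factor's variance. Their deviances agree on any dataset, which the test suite
exploits as an internal consistency oracle. Genetic correlations default to
the joint model over the requested waves; means are equated across twins and
groups (analyses run on residualized scores).

Intraclass correlations use double-entered pairs; Fisher-z CIs use the number
of complete pairs, not the doubled record count.

## Latent profiles

Longitudinal LPA is a Gaussian mixture over the waves with diagonal
covariance and per-wave variances equated across classes ("variances equated,
covariances fixed to 0"); the equating is across classes, wave-specific —
the conventional reading for longitudinal indicators. Missing waves are
completed once by single imputation — a conditional draw from an EM-estimated
multivariate normal — before any k is fitted, so all class counts see the
same completed data. EM runs to a relative log-likelihood change below 1e-8
or 500 iterations, best of 20 seeded k-means-initialized restarts (plain
Lloyd's algorithm, written in-package because the mixture constraint has no
off-the-shelf equivalent and the initializer must stay dependency-free);
restarts that collapse a class below one expected member are discarded.
Selection is by BIC with p = k·w + w + (k−1) parameters, ties broken toward
smaller k; classes are reported sorted by mean trajectory (wave 1 first) for
stable identification. Entropy is the normalized posterior entropy,
1 − (−Σ p log p)/(n log k).

## Growth curves

Latent growth curves fix factor loadings to time codes — defaults
(0, 2.0, 2.25, 2.5, 2.92) years since baseline for assessments in 2018,
April/July/October 2020 and March 2021, since the waves are unevenly spaced —
with free growth-factor means, a Cholesky-parameterized random-effect
covariance, and residual variances free per wave (the abrupt context change
at wave 2 makes homoscedasticity implausible; a homoscedastic switch exists
and is what the lme4 cross-check uses). Piecewise trends are out of scope:
with a single pre-disruption wave the pre-segment slope is not estimable.
The slope-variance test compares against a random-intercept-only model; with
variance components on the boundary the χ² reference is conservative, which
the null-calibration test reflects (rejection rate ≤ nominal). Residual
variances estimated at the zero bound are flagged as Heywood cases.

## Association analyses

The p-factor is the first principal component of the column-standardized
complete-case matrix, sign-fixed so the mean loading is positive; scores are
standardized. The genomic p-factor convention excludes educational-attainment
and cross-disorder scores from the input set so the composite indexes
psychiatric liability only. GPS effects are incremental R² between
covariates-only and covariates+score OLS fits (equal to squared partial
correlation times 1−R²_cov), with an optional permutation p-value. Extreme
groups are the strict ±1 s.d. tails of the internally standardized score —
boundary values fall in the excluded middle. Extreme-group trajectory
contrasts report per-wave two-sample Cohen's d (observed samples, pooled
s.d. — under attrition the wave samples are only partially overlapping, so a
paired form is not generally available) plus the same contrast-score MANOVA
used for time×sex, with group as the between factor.

The extremes sample generator calibrates the latent-factor weight at each
post-baseline wave from truncated-normal moments so that the *expected*
pipeline output (standardized high-vs-low gap after PCA and ±1 s.d.
grouping) equals the requested gap: with h = 2φ(t)/Φ(−t), v = Var(Z|Z>t) and
r the component-score/factor correlation, d = δrh/√(1−(1−v)r²δ²) is inverted
for δ.

## Problem sizes

Recovery experiments use the cohort sizes of the emulated design (1,500 MZ +
2,380 DZ pairs) with 20 replicates per quantity, n = 4,000 individuals for
effect-size, profile and extremes experiments and n = 3,000 for correlation
stability — sizes at which Monte-Carlo error is comfortably below the
reporting precision while the whole acceptance run stays around a minute.

## Known limitations

- No ordinal/threshold likelihoods; questionnaire data are treated as
  Gaussian.
- No sex-limitation, gene–environment interaction, common-pathway or
  direction-of-causation models.
- Profile CIs for derived multivariate quantities (e.g. standardized per-wave
  components of the joint model) are not provided; CIs cover direct
  parameters only.
- The BIC default for LPA class selection is known to be conservative
  relative to other indices; with many weakly separated classes, selected k
  may differ from what other criteria (or software defaults) report.
- FIML assumes missing-at-random given the observed variables; the MAR
  attrition the generator produces satisfies this only because selection acts
  on the always-observed baseline.
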