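# Methods

## The estimand and the residualization procedure

The quantity of interest is the non-genetic component of adult height: the
part of sex-standardized height not explained by the fixed-effects
prediction of a mixed model whose fixed part contains the height polygenic
score (PGS), sex and the top five genetic PCs (model 1), optionally plus age
and age² (model 2), and whose random part contains three variance
components — genome-wide relatedness (GRM), household, and census block —
plus iid error. Two conventions matter and are deliberate:

- **Fixed-effects-only residuals.** `height_rez = z − Xβ̂`. Random-effect
  BLUPs are not subtracted: household and neighbourhood effects are part of
  the environmental signal the residual is meant to capture, and the random
  effects exist only so that β̂ is the GLS estimate under the correct
  covariance (and so relatives do not distort it). The defining property,
  `Xᵀ V̂⁻¹ (z − Xβ̂) = 0`, holds at convergence to machine precision.
- **Unweighted standardization.** The within-sex means/SDs that define the
  height Z-score are plain sample statistics; a survey-weighted variant
  exists behind a flag (`standardize_height(..., weights=)`), since the
  convention is not dictated by the estimand.

Age enters model 2 raw (uncentered); residuals are invariant to centering.
Residuals are not re-standardized at extraction; association models divide
the exposure by its sample SD so that reported betas are per 1 SD of
`height_rez_age` — rescaling the residual upstream provably does not change
the reported coefficient.

## REML

Variance components maximize the restricted likelihood of
`y ~ N(Xβ, Σ_k σ²_k K_k + σ²_e I)` by Average-Information (AI) updates.
Numerical policy:

- Initial values: equal split of the OLS residual variance across
  components. Convergence: successive restricted log-likelihoods within
  1e-6 (configurable); max 200 iterations, failure raises with the full
  trajectory attached.
- An AI proposal that would push a component negative falls back to the EM
  update for that component; when EM also points downhill the component is
  projected to the boundary directly, because the EM decay near zero is
  geometric and stalls (observed, and the reason a boundary projection is
  the default rather than repeated EM). A step-halving line search guards
  every step; if no step along the proposal improves the likelihood the
  current point is the optimum and iteration stops.
- Components ending at the floor are reported as exact zeros, and the final
  GLS pass for β̂ and its covariance uses that same zeroed V, keeping
  `varcomp` and `beta` mutually consistent (the GLS-orthogonality identity
  would otherwise be violated at the size of the floor).
- Kernels that are linearly dependent (e.g. a GRM equal to I aliasing the
  error term) are detected by a rank screen on the kernel Gram matrix and
  produce a non-identifiability warning; only identifiable combinations
  (such as the total) are then meaningful.

For the single-kernel model an eigen-rotation path decomposes the GRM once
and profiles the restricted likelihood over the heritability ratio on
[0, 1) with a bounded scalar optimizer; it reaches the same maximum as the
generic path (agreement ~1e-7 in practice, tested at 1e-5) and is the
default there. The AI matrix at the optimum supplies the component
covariance; heritability CIs use the delta method on σ²_g over the chosen
denominator. The denominator default is `all_components` (household and
block in the total); `grm_plus_error` is available because the convention
differs across tools and the right choice depends on what "phenotypic
variance" should include — both are exposed and recorded in fit output.
Haseman–Elston regression (pairwise phenotype cross-products on GRM
entries) is implemented as an independent moment-based estimator and used
to cross-check REML in tests; its naive OLS standard error ignores pair
dependence and is used only for agreement bands, never for inference.

Variance explained by the PGS is an incremental least-squares R²
(unweighted by default; weighted behind a flag). Whether the original
survey weights belong in that computation is genuinely undetermined, so it
is a flag, not a guess.

## Polygenic scoring

A SNP from the weight table is scored only if its {effect, other} allele
set equals the genotype metadata's {allele1, allele2}; the dosage is
flipped (2 − d) when the effect allele is allele2. Non-available and
allele-mismatched SNPs are excluded and reported separately, never
fatally. Strand-ambiguous A/T and C/G SNPs are kept by default (the
synthetic data has no strand issues); `drop_ambiguous=True` exists for real
data. Missing dosages contribute twice the effect-allele frequency (mean
imputation from the genotype matrix), matching common scoring-tool
defaults. No weight centering or score standardization happens inside the
scoring module.

## Survey estimation

Design-based weighted means and weighted least squares with
Taylor-linearized variance: linearized scores are totalled per PSU, and
between-PSU variability within strata (with-replacement first-stage
approximation, no finite-population correction) estimates the variance.
Design df = #PSUs − #strata; CIs use t on those df. Point estimates depend
on weights only through relative weights. Missing data follow domain
(subpopulation) semantics: incomplete units contribute zero score but keep
their stratum/PSU membership, so item missingness does not silently
collapse variance strata. A stratum contributing a single PSU is an error
(no silent collapse rule); stratified analyses are subset refits rather
than domain estimation, with the interaction p-value taken from the pooled
model's joint Wald test. Single-coefficient Wald tests square the t
statistic exactly.

## Scoring rubrics

The cardiovascular-health rubric (eight components, 0–100, higher = better)
is externalized JSON validated at load: numeric bands must tile the real
line contiguously and all points lie in [0, 100]. The shipped default
transcribes the adult (≥20y) Life's Essential 8 point scale: BMI bands;
non-HDL bands with a −20 lipid-medication penalty; blood pressure as the
minimum of the systolic and diastolic band scores with a −20 treatment
penalty; glucose with a diabetes-status rule first (medication or
diagnostic FBG/HbA1c), then HbA1c control bands, then FBG — a treated
diabetic without HbA1c is missing rather than guessed. Diet consumes an
upstream DASH 0–80 adherence score through fixed cutpoints placed at the
25/50/75/95th percentiles of the generator's DASH distribution; physical
activity, nicotine and sleep use the standard band/category scales. The
health-domain score is the mean of the four health factors, missing under
any factor missingness. Participants aged 18–19 are scored with the adult
rubric (the separate under-20 scale is out of scope for an 18–74 cohort).

Cognition: five tests are z-standardized (ddof = 1) within the eligible
subsample (age ≥ 45); global cognition is the mean of the four non-SIS
z-scores (complete cases), re-standardized in the same subsample. Younger
participants carry missing cognition values by construction.

## The synthetic cohort generator

The generator emulates the features the analysis relies on, on a
unit-variance latent height scale per sex:

| component | default | rationale |
|---|---|---|
| additive genetic share `h2_true` | 0.53 | the heritability the analysis is designed to recover |
| household / block shares | 0.05 / 0.05 | plausible placeholders; no external estimate exists for these shares |
| SEP effect | 0.04 SD per ordinal unit | yields ≈0.12 SD between extreme parental-education groups, the order of magnitude reported for such gradients |
| secular trend | 0.15 SD/decade (≈1 cm/decade) | the widely reported 20th-century trend in Latin American populations |
| height loss after 60 | 0.1 cm/year | literature range 0.1–0.2 |
| sex height mean (SD) | F 156.6 (6.5), M 169.7 (7.0) cm | the target population's distributions |
| environment→cognition coupling | 0.15 z per SD | moderate, detectable at desk-scale n |

Families are founder pairs with full sibs only (expected GRM relatedness
0.5), all SNPs causal with iid effects on the standardized-dosage scale —
the simplest structure that exercises the GRM random effect. Genetic,
household and block draws are empirically rescaled to their exact target
variance shares, and the noise share is the remainder after the
SEP/trend/age-loss variance, so in-sample decomposition matches the
parameters exactly and recovery tests are sharp. SEP covariates (parental
education, migration age, hardship, utilities) are ordinal/binary cuts of a
family-level latent with category frequencies matching the target
population's margins, making category means monotone in the realized
environment without asserting unverifiable effect sizes. Ages are uniform
18–74 with `birth_year = reference_year − age` (default 2009); the survey
design assigns census blocks to strata and PSUs geographically, with
weights uniform on a range and optionally tilted by the block effect to
mimic informative sampling. A missingness injector (MCAR, rate-
parameterized, default off) supports complete-case tests.

What the generator does **not** emulate: linkage disequilibrium, imputation
uncertainty, realistic allele-frequency spectra, weight calibration to
census margins, non-linear or interactive SEP effects, and informative
missingness. Passing recovery tests therefore demonstrates correctness of
the estimators under the assumed data-generating process, not robustness of
the substantive findings to real-data complications.

## Problem sizes and other choices

Recovery and direction checks in the acceptance script use n = 1500 (30
replicates at the 0.53 truth, 10 at 0.2/0.8) and n = 1000 (30 replicates
for the directional findings); the test suite uses n = 800–1000 with fewer
replicates. These sizes put Monte-Carlo SEs near 0.4 percentage points of
heritability while keeping runs desk-scale. Birth cohorts use closed
printed-endpoint intervals (1949 → 1930–1949, 1950 → the 1950s); age 65+ is
unbounded. No multiple-testing adjustment is applied anywhere — per-model
CIs only, mirroring standard reporting for this kind of descriptive
epidemiology. The under-60 sensitivity analysis refits everything
(standardization, REML, residuals, scoring, associations) on the restricted
sample rather than reusing main-analysis residuals.

## Known limitations

- The AI-REML implementation is dense (O(n³) per iteration) and intended
  for cohorts up to a few thousand; it does not implement the sparse or
  streaming strategies needed at biobank scale.
- Survey features are limited to Taylor linearization: no replicate
  weights, calibration/raking, or survey GLMs.
- The HE standard error is naive (see above); heritability CIs rely on the
  asymptotic normality of REML estimates and can be optimistic near the
  h² boundary.
- The rubric ships one default transcription; jurisdictions of the
  underlying scale differ in minor details (e.g. secondhand-smoke
  penalties) that are not modelled.
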