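# Methods

This note documents the statistical model behind `tractlink`, the design
choices that were genuinely open, the synthetic-cohort calibration, and the
limits of what the test suite demonstrates.

## Analysis model

**Inputs.** One row per infant: gestational age at birth (GA, weeks),
postmenstrual age at scan (PMA, weeks), sex (1 = female), socioeconomic
deprivation index (IMD convention: higher = more deprived), global
white-matter volume (mm³), median FA of six tracts (left/right arcuate
fasciculus, cortico-spinal tract, superior longitudinal fasciculus), and
BSID-III composite language and cognitive scores at ~2 years. FA values
must lie strictly in (0, 1); missing values are hard errors — the pipeline
models complete cohorts and performs no imputation.

**Confound removal.** PMA is residualized out of all FA features and the
socioeconomic score out of the outcome scores, by per-column OLS with
intercept. By default the residualizer is fitted once on the full sample,
before cross-validation — mirroring a confound-removal step performed prior
to the analysis; `residualize_within_fold=True` gives the strictly
leakage-free variant (refit inside every training fold, held-out row
transformed with training coefficients). GA, sex and WM volume are *not*
residualized here; they enter only the sensitivity analyses below. The
pipeline order is fixed: residualize, then standardize. Standardization
(zero mean, unit variance with the population divisor n — a documented
convention choice) is always fold-wise: parameters estimated on the n − 1
training rows and applied unchanged to the held-out row.

**PLS core.** `fit_pls` is NIPALS in mode A with canonical deflation (both
blocks deflated by their own scores), deterministic initialization (`u` =
maximal-variance Y column), tolerance 1e-12 on the change in `w`, at most
500 iterations, and a deterministic sign convention (each component flipped,
both blocks together, so its X-weights sum ≥ 0; the first non-zero entry
breaks exact ties). Per-component variance explained is the Frobenius-norm
drop of the deflated block over the original block norm; with K = min(p, q)
components the cumulative value reaches 1 (tested). K defaults to 1: the
analysis targets a single mode of covariation. "Loadings of involvement"
reported by the pipeline are the unit-norm *weights* of component 1 — the
printed values this emulates (≈ 0.66/0.78 for two FA columns, 0.71/0.71 for
two outcome columns) have unit Euclidean norm, which identifies them as
normalized weight vectors rather than regression loadings `p = Xᵀt/(tᵀt)`;
the loadings are also computed and serialized for anyone wanting the other
convention.

**Cross-validated link.** Leave-one-out only (no k-fold variants): per
fold, preprocess on n − 1 rows, fit the model, project the held-out row's
FA block onto the training X-weights and its outcome block onto the
training Y-weights. `r_cv` is the Pearson correlation (Spearman by option)
of the n out-of-sample score pairs. For the OLS/Ridge comparators the
x-score is the prediction of the standardized first outcome and the y-score
its observed standardized value, making the three methods' statistics
directly comparable. Ridge uses λ = 1.0 on standardized features by default
(the penalty the emulated analysis used is unknown; λ = 0 reproduces OLS
exactly, which is tested).

**Sign convention in cross-validation.** A PLS component is only defined up
to a joint sign flip, and a correlation over score pairs pooled from 43
separately-fitted folds is meaningless unless all folds share one
orientation. Three candidate rules were evaluated on simulated null
cohorts:

* *align each fold to the full-sample fit* — lets the held-out subject
  influence its own fold's orientation; measurably biases r_cv upward
  under the global null (+0.02 mean over 300 null cohorts);
* *let NIPALS tie the Y sign to the training cross-covariance* (the raw
  algorithm's behavior) — makes the null statistic behave like |r|,
  inflating the right tail and wasting power for a directional test;
* *orient each block independently by its training-only canonical sign*
  (sum of weights ≥ 0) — chosen. Every fold and every permutation
  replicate then shares a fixed directional convention ("higher FA with
  better outcome" is positive), the null distribution of r_cv is centered
  slightly **below** zero (the classic cross-validation pessimism, mean
  ≈ −0.01 at n = 43), and no held-out information enters the orientation.

Fold-wise weight stability (the mean ± SD table) uses the same orientation.

**Permutation inference.** The link test permutes the subject rows of the
residualized outcome block, keeps the FA block fixed, and re-runs the full
LOOCV pipeline per permutation; one-sided (positive) by default, matching
the directional hypothesis, with a two-sided flag. GLM contrasts use
Freedman–Lane: residuals of the reduced nuisance-only model are permuted,
the nuisance fit re-added, and the full-model t recomputed (with an empty
nuisance set this reduces exactly to simple permutation — tested).
P-values use the add-one convention p = (1 + #{null ≥ obs})/(B + 1), valid
at any finite B and never zero. Familywise error is controlled single-step
with the max-statistic over seed-aligned families: the three tract sets
within one method (the method-comparison table), the six FA outcomes
within one contrast (the developmental table), and the four predictors of
the independent-contribution GLM. Family composition is recorded in the
run log. B defaults to 10,000; calibration tests use B = 199 and the
acceptance script B = 9,999.

**Sensitivity and asymmetry analyses.** The partial correlation between
the out-of-sample PLS FA and language scores adjusting for GA, WM volume
and sex (OLS residuals of both scores on the covariates, Freedman–Lane
inference); a joint GLM of SES-residualized language on [PLS FA score, GA,
sex, WM volume] with one contrast per predictor under one family; the
lateralization index (L − R)/(L + R) with positive- and negative-contrast
GLMs against language; and a Wilcoxon signed-rank comparison of left vs
right FA (continuity-corrected normal approximation, zeros dropped,
mid-ranks for ties — the approximation is within 0.02 of the exact 2¹²
enumeration at n = 12, tested).

## Synthetic cohort generator

The generator is first-class, tested code: it defines the study conditions
under which the pipeline's statistical behavior is demonstrated.

* **GA** ~ scaled Beta(4, 2) on [24, 33] weeks: median ≈ 30 with a left
  tail, as in a preterm cohort (population mean 30.0, SD 1.60).
* **PMA** is centered on 42 weeks and jointly Gaussian with GA such that
  postnatal age D = PMA − GA satisfies corr(D, PMA) = 0.79 and
  corr(D, GA) = −0.90. These two targets identify the joint law in closed
  form: σ_PMA/σ_GA = √((1−0.9²)/(1−0.79²)) ≈ 0.711 and
  corr(PMA, GA) ≈ −0.44 (solved inside the config, so changing the targets
  re-derives the geometry).
* **Tract FA** per hemisphere: base level (0.24 arcuate / 0.32 CST / 0.22
  SLF — free parameters at plausible neonatal levels) + 0.028·(PMA − 42)
  maturation + [arcuate only] 0.004·(GA − 30) prematurity dose +
  z_loading·z with z ~ N(0,1) the subject latent (z_loading = 0.030,
  symmetric across hemispheres) + residual noise (SD 0.0223 per side). The
  left/right residual correlation is solved analytically so the *raw*
  within-pair FA correlation hits 0.58. Because the maturation component is
  strongly hemisphere-shared, that target forces the residual noise to be
  negatively correlated (≈ −0.92 for the arcuate at defaults) — i.e. most
  residual variance is individual *lateralization* variance rather than
  bilateral measurement noise. Infeasible combinations raise a
  configuration error rather than silently missing the target. FA is
  clipped to (0.01, 0.99) with a logged count; at defaults clipping is
  rare (< 0.1%, tested).
* **Outcomes.** An outcome latent mixes the brain latent with weight
  `effect` (= corr(z, outcome latent), the planted association dial, in
  [0, 1)) and independent variation. Language loads 0.93 and cognition
  0.79/0.93 ≈ 0.85 on the shared latent — product 0.79, their mutual
  correlation — so language, the primary outcome, tracks the latent most
  closely while keeping independent noise. Language adds −0.28 standardized
  SES units and is scaled to 90 ± 16.2; cognition to 92 ± 11.85.
* **Defaults as study conditions.** beta_pma was set so the developmental
  GLM produces t ≈ 5–6 at n = 43 (the p ≈ 10⁻⁴–10⁻³ regime of the emulated
  results); `effect` defaults to 0.55, at which the arcuate link is
  reliably detectable and the arcuate-significant / controls-null
  specificity pattern reproduces in ≈ 86% of replicate analyses. The
  measured transmission from the planted latent correlation to the
  observable score-pair correlation is ≈ 0.91 at defaults, so a planted
  effect of ≈ 0.41 corresponds to an observable link of ≈ 0.36 — the
  borderline-detectable regime; one config field moves between the two.
  All of these values were frozen from a single design study before the
  statistical tests were written.
* `null_variant` zeroes `effect` only: tracts and outcomes decouple while
  every confound relationship survives — the global null used for
  calibration.

**What the generator does not emulate.** Linear-Gaussian structure only: no
FA floor/ceiling nonlinearity, no outcome skew or floor effects in BSID-III
scores, no missing follow-up, no site or scanner effects, no spatial
structure within tracts (the unit is the per-tract median FA), and no
birth-weight/ventilation covariates (nothing downstream uses them). Passing
tests therefore demonstrate the pipeline's *statistical* correctness —
calibration, FWE control, power monotonicity, specificity — under idealized
conditions, not robustness to the messiness of real cohorts.

## Numerical conventions and performance

Exact tie handling in p-values (`≥` comparisons on identically-computed
floats); seeds below 2³¹ derived from a master seed per stage; the cohort
TSV writer uses 17-significant-digit floats so write → read → write is
byte-identical. The LOOCV engine has two code paths that agree to 1e-9
(tested): a general per-fold loop through the public API (any K, optional
within-fold residualization) and a fold-batched path for the default
configuration that runs the same NIPALS sweep on all folds simultaneously
(~1 ms per 43-fold LOOCV), which is what makes 10⁴-permutation inference
interactive. When a fold's cross-covariance has nearly equal singular
values — routine in permutation nulls with a two-column outcome block — the
NIPALS direction converges only at the ratio of those values; the batched
path accepts the subspace-converged iterate after 2,000 sweeps, since any
direction in the leading subspace carries the same covariance. `fit_pls`
itself keeps the strict convergence contract (error with the last delta).

Simulation sizes in the test suite (200 null cohorts at B = 199 for
calibration; 100–150 cohorts per effect level for power; 50 replicate
analyses at B = 999 for the specificity pattern) were chosen to bound
Monte-Carlo error on the assessed rates at roughly ±3 percentage points
while keeping the full suite around five minutes.

## Known limitations

* The cross-validated score-pair statistic pays a power cost relative to an
  ideal correlation test (~0.08 absolute near observable r ≈ 0.4, n = 43);
  it buys out-of-sample validity, not efficiency.
* Full-sample residualization (the default, matching the emulated order of
  operations) leaks a small amount of held-out information through the
  confound fit; the effect at n = 43 is far below the CV noise floor, and
  the leakage-free variant is one flag away.
* The permutation scheme assumes exchangeable subjects under the null; no
  exchangeability blocks are implemented.
* Ridge's penalty is not tuned (no nested CV); it exists as a comparator,
  not a production predictor.
* With a one-column outcome block the Y-side of the PLS is trivial (the
  score is the standardized outcome itself); the machinery only becomes
  genuinely multivariate with cognition included.
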