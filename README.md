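# tractlink

Cross-validated partial-least-squares (PLS) brain–behavior link analysis for
tract-level diffusion MRI, with permutation-based familywise-error (FWE)
inference and a calibrated synthetic cohort generator.

## The problem

In preterm-born infants, does white-matter microstructure at term-equivalent
age — summarized as the median fractional anisotropy (FA) of specific tracts
— carry information about language and cognitive outcome at two years?
Answering this in a small cohort (n ≈ 43) raises three statistical problems
this package solves as a reusable pipeline:

1. **Collinearity.** Left and right tract FA are strongly correlated
   (r ≈ 0.6), so ordinary least squares is ill-conditioned. The pipeline's
   core is a from-scratch NIPALS PLS in **mode A with canonical deflation**:
   per component, initialize `u` as the maximal-variance Y column, iterate
   `w = Xᵀu/‖Xᵀu‖`, `t = Xw`, `c = Yᵀt/‖Yᵀt‖`, `u = Yc` to convergence;
   loadings `p = Xᵀt/(tᵀt)`, `q = Yᵀu/(uᵀu)`; deflate each block by its own
   scores (`X ← X − tpᵀ`, `Y ← Y − uqᵀ`). For one component, `(w, c)` equal
   the leading singular pair of `XᵀY` — tested against an SVD oracle.
   Cross-validated OLS and Ridge comparators are included.
2. **Overfitting at small n.** The link is assessed by leave-one-out
   cross-validation: each subject's "PLS FA score" and "PLS language score"
   are projections of their held-out rows onto weights trained on the other
   n − 1 subjects (confounds residualized, features standardized with
   training-fold parameters only). The statistic `r_cv` is the Pearson
   correlation over the n out-of-sample score pairs.
3. **Valid small-sample inference.** Significance comes from permutation
   tests (outcome rows permuted after confound residualization; the full
   LOOCV pipeline re-run per permutation), with single-step max-statistic
   FWE correction across each test family. GLM contrasts with nuisance
   covariates (developmental effects of postmenstrual age and gestational
   age; independent-contribution analyses) use Freedman–Lane permutation.
   Lateralization is quantified by the index (L − R)/(L + R) and a Wilcoxon
   signed-rank test.

Because no subject-level data are distributable, the package includes a
**synthetic cohort generator** whose defaults emulate the published cohort
structure: GA median 30 (24–33) weeks, PMA at scan median 42 (39–46) weeks,
postnatal age correlating r = 0.79 with PMA and r = −0.90 with GA,
socioeconomic index 17.43 ± 8.08, BSID-III language/cognition 90 ± 16.2 /
92 ± 11.85 with r = 0.79, left–right arcuate FA correlation 0.58, an
SES→language correlation of −0.28, and a tunable latent brain–behavior
association planted in the arcuate fasciculus only.

## Worked example

```bash
tractlink run --simulate --seed 42 --b-perms 1999 --out demo_report
```

prints (exact output of this command):

```
  ols arcuate: r_cv=+0.266 p=0.0470 p_fwe=0.1395
  ols     cst: r_cv=-0.028 p=0.4330 p_fwe=0.8215
  ols     slf: r_cv=+0.134 p=0.1845 p_fwe=0.4390
ridge arcuate: r_cv=+0.267 p=0.0465 p_fwe=0.1375
ridge     cst: r_cv=-0.029 p=0.4345 p_fwe=0.8250
ridge     slf: r_cv=+0.132 p=0.1855 p_fwe=0.4415
  pls arcuate: r_cv=+0.330 p=0.0215 p_fwe=0.0890
  pls     cst: r_cv=+0.054 p=0.3955 p_fwe=0.7770
  pls     slf: r_cv=+0.142 p=0.2490 p_fwe=0.5370
report bundle: demo_report
```

Reading it: each row is one regression method applied to one tract set
(arcuate fasciculus; cortico-spinal tract and superior longitudinal
fasciculus as specificity controls). `r_cv` is the out-of-sample score-pair
correlation, `p` its one-sided permutation p-value, and `p_fwe` the
max-statistic correction across the three tract sets. In this simulated
cohort the association is planted only in the arcuate: PLS finds it
(r_cv = 0.33) while both control tracts stay at noise level, and PLS beats
OLS/Ridge, which dilute the bilateral signal across collinear coefficients.
The bundle directory contains the cohort snapshot, the developmental GLM
table, the method-comparison table, PLS loading means ± SDs across folds,
partial-correlation and independent-contribution sensitivity tables, the
asymmetry analysis, and a run log with every seed and family definition.

The same pipeline runs on a real cohort table via `--input cohort.tsv`
(one row per subject; see `tractlink.cohort.COLUMNS` for the schema).

## Library use

```python
import tractlink as tl

cohort = tl.generate_cohort(tl.SyntheticConfig(seed=1))
cv = tl.loocv_link(cohort, tl.TRACT_SETS["arcuate"], ("lang",))
print(cv.r_cv, cv.loadings_x_mean, cv.varexp_x_mean)

fam = tl.tract_link_family(cohort, ("lang",), "pls", B=1999, seed=2)
print({t: (f.observed, f.p_fwe) for t, f in fam.items()})
```

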