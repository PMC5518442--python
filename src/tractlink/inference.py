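"""Permutation-based significance machinery.

All significance statements in the pipeline are nonparametric:

* the cross-validated link statistic is tested by permuting the subject
  rows of the (confound-residualized) outcome block while the FA block
  stays fixed, re-running the *full* LOOCV pipeline per permutation;
* GLM contrasts with nuisance covariates use the Freedman–Lane scheme
  (permute residuals of the reduced nuisance-only model, re-add the
  nuisance fit, recompute the statistic);
* familywise error (FWE) is controlled single-step with the max-statistic
  (Westfall–Young) construction over a family of tests that share
  seed-aligned permutation indices.

P-values use the add-one convention p = (1 + #{null ≥ observed})/(B + 1),
which is exactly valid at finite B and can never be zero.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from . import preprocess
from .cohort import TRACT_SETS
from .crossval import (
    DEFAULT_X_CONFOUNDS,
    DEFAULT_Y_CONFOUNDS,
    _corr,
    _loocv_general,
    loocv_scores,
)
from .errors import SingularMatrixError, TractlinkError

__all__ = [
    "PermutationTest",
    "GlmContrastTest",
    "make_permutations",
    "perm_test_cv_link",
    "tract_link_family",
    "fwe_correct",
    "glm_contrast_perm",
    "prematurity_glm_grid",
    "independent_contribution_glm",
    "partial_corr_perm",
    "asymmetry_index",
    "paired_signed_rank",
]


@dataclass
class PermutationTest:
    """An observed statistic with its permutation null."""

    observed: float
    B: int
    null_draws: np.ndarray
    p_uncorrected: float
    p_fwe: float | None
    family_id: str
    seed: int | None
    sided: str  # "greater" | "less" | "two"

    def to_dict(self, include_null: bool = False) -> dict:
        d = {
            "observed": self.observed,
            "B": self.B,
            "p_uncorrected": self.p_uncorrected,
            "p_fwe": self.p_fwe,
            "family_id": self.family_id,
            "seed": self.seed,
            "sided": self.sided,
        }
        if include_null:
            d["null_draws"] = self.null_draws.tolist()
        return d


@dataclass
class GlmContrastTest:
    """A GLM contrast with its Freedman–Lane permutation test."""

    outcome: str
    design_cols: tuple[str, ...]
    contrast: np.ndarray
    t_statistic: float
    perm: PermutationTest


def _oriented(values: np.ndarray | float, sided: str):
    if sided == "greater":
        return values
    if sided == "less":
        return -values if np.ndim(values) else -values
    if sided == "two":
        return np.abs(values)
    raise TractlinkError(f"unknown sidedness {sided!r}")


def _add_one_p(observed: float, null: np.ndarray, sided: str) -> float:
    obs = _oriented(observed, sided)
    nul = _oriented(null, sided)
    return float((1 + int((nul >= obs).sum())) / (null.shape[0] + 1))


def make_permutations(n: int, B: int, seed: int) -> np.ndarray:
    """B row permutations of 0..n−1, deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    return np.array([rng.permutation(n) for _ in range(B)])


# ---------------------------------------------------------------------------
# cross-validated link
# ---------------------------------------------------------------------------


def perm_test_cv_link(
    cohort,
    x_cols: Sequence[str],
    y_cols: Sequence[str],
    method: str = "pls",
    *,
    x_confounds: Sequence[str] = DEFAULT_X_CONFOUNDS,
    y_confounds: Sequence[str] = DEFAULT_Y_CONFOUNDS,
    B: int = 10_000,
    seed: int = 0,
    sided: str = "greater",
    ridge_lambda: float = 1.0,
    corr_method: str = "pearson",
    residualize_within_fold: bool = False,
    K: int = 1,
    perm_indices: np.ndarray | None = None,
    family_id: str = "cv_link",
) -> PermutationTest:
    """Permutation test of the LOOCV link statistic.

    The null is generated by permuting the subject rows of the outcome
    block *after* its confound residualization, keeping the FA block fixed,
    and re-running the complete LOOCV pipeline (fold-wise standardization,
    model fit, held-out projection, correlation) for every permutation.
    One-sided in the positive direction by default — the directional
    hypothesis that higher FA goes with better outcomes.

    With ``residualize_within_fold=True`` the outcome rows are permuted
    jointly with their confound rows and the per-fold residualization is
    re-run inside every permutation (slower, leakage-free variant).
    """
    if B < 99:
        raise TractlinkError("B must be ≥ 99 for a meaningful permutation test")
    n = len(cohort)
    X = cohort[list(x_cols)].to_numpy(dtype=float)
    Y = cohort[list(y_cols)].to_numpy(dtype=float)
    Cx = cohort[list(x_confounds)].to_numpy(dtype=float) if x_confounds else None
    Cy = cohort[list(y_confounds)].to_numpy(dtype=float) if y_confounds else None

    if not residualize_within_fold:
        if Cx is not None:
            rx = preprocess.fit_residualizer(X, Cx, tuple(x_confounds))
            X = preprocess.apply_residualizer(rx, X, Cx)
        if Cy is not None:
            ry = preprocess.fit_residualizer(Y, Cy, tuple(y_confounds))
            Y = preprocess.apply_residualizer(ry, Y, Cy)

    if perm_indices is None:
        perm_indices = make_permutations(n, B, seed)
    elif perm_indices.shape != (B, n):
        raise TractlinkError("perm_indices must have shape (B, n)")

    def _stat(Yb: np.ndarray, Cyb: np.ndarray | None) -> float:
        if residualize_within_fold:
            xs, ys, _ = _loocv_general(
                X, Yb, Cx, Cyb, method, K, ridge_lambda, True, False
            )
        else:
            xs, ys = loocv_scores(X, Yb, method, ridge_lambda=ridge_lambda)
        return _corr(xs, ys, corr_method)

    observed = _stat(Y, Cy)
    if not np.isfinite(observed):
        raise TractlinkError("degenerate (constant) link statistic")

    null = np.empty(B)
    for b in range(B):
        pi = perm_indices[b]
        null[b] = _stat(Y[pi], Cy[pi] if (residualize_within_fold and Cy is not None) else Cy)

    return PermutationTest(
        observed=observed,
        B=B,
        null_draws=null,
        p_uncorrected=_add_one_p(observed, null, sided),
        p_fwe=None,
        family_id=family_id,
        seed=seed,
        sided=sided,
    )


def fwe_correct(tests: Sequence[PermutationTest]) -> list[PermutationTest]:
    """Single-step max-statistic FWE correction over a family.

    All members must carry identical permutation counts, seeds and
    sidedness (i.e. seed-aligned permutations on a comparable statistic
    scale). Returns new test objects with ``p_fwe`` filled in.
    """
    if not tests:
        return []
    B = tests[0].B
    seed = tests[0].seed
    sided = tests[0].sided
    for t in tests:
        if t.B != B or t.seed != seed or t.sided != sided:
            raise TractlinkError(
                "family members must share permutation count, seed and sidedness"
            )
    null_mat = np.vstack([_oriented(t.null_draws, sided) for t in tests])
    max_null = null_mat.max(axis=0)
    out = []
    for t in tests:
        obs = _oriented(t.observed, sided)
        p_fwe = float((1 + int((max_null >= obs).sum())) / (B + 1))
        out.append(dataclasses.replace(t, p_fwe=p_fwe))
    return out


def tract_link_family(
    cohort,
    y_cols: Sequence[str],
    method: str = "pls",
    *,
    tract_sets: Mapping[str, Sequence[str]] | None = None,
    B: int = 10_000,
    seed: int = 0,
    sided: str = "greater",
    ridge_lambda: float = 1.0,
    corr_method: str = "pearson",
    residualize_within_fold: bool = False,
) -> dict[str, PermutationTest]:
    """FWE-corrected link tests for each tract set within one method.

    The family (default: arcuate, cortico-spinal, superior longitudinal)
    shares one set of permutation indices so the max-statistic correction
    is exact.
    """
    tract_sets = dict(tract_sets or TRACT_SETS)
    perms = make_permutations(len(cohort), B, seed)
    tests = [
        perm_test_cv_link(
            cohort,
            cols,
            y_cols,
            method,
            B=B,
            seed=seed,
            sided=sided,
            ridge_lambda=ridge_lambda,
            corr_method=corr_method,
            residualize_within_fold=residualize_within_fold,
            perm_indices=perms,
            family_id=f"link:{method}",
        )
        for cols in tract_sets.values()
    ]
    tests = fwe_correct(tests)
    return dict(zip(tract_sets.keys(), tests))


# ---------------------------------------------------------------------------
# GLM contrasts (Freedman–Lane)
# ---------------------------------------------------------------------------


def _glm_t(D: np.ndarray, y: np.ndarray, c: np.ndarray, xtx_inv_c: float) -> float:
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    df = D.shape[0] - D.shape[1]
    sigma2 = float(resid @ resid) / df
    return float(c @ beta) / np.sqrt(sigma2 * xtx_inv_c)


def glm_contrast_perm(
    outcome: np.ndarray,
    design: np.ndarray,
    contrast: Sequence[float],
    *,
    design_cols: Sequence[str] | None = None,
    outcome_name: str = "y",
    B: int = 10_000,
    seed: int = 0,
    sided: str = "two",
    perm_indices: np.ndarray | None = None,
    family_id: str = "glm",
) -> GlmContrastTest:
    """Freedman–Lane permutation test of a single GLM contrast.

    ``design`` must include its intercept column. The reduced model keeps
    the columns with zero contrast weight (the nuisance set); its residuals
    are permuted, the nuisance fit re-added, and the full-model t-statistic
    recomputed per permutation. With an empty nuisance set this reduces to
    a plain permutation of the outcome.
    """
    y = np.asarray(outcome, dtype=float).ravel()
    D = np.asarray(design, dtype=float)
    c = np.asarray(contrast, dtype=float).ravel()
    n, p = D.shape
    if c.shape[0] != p:
        raise TractlinkError(f"contrast length {c.shape[0]} != design width {p}")
    if not np.any(c):
        raise TractlinkError("contrast vector is all zeros")
    if np.linalg.matrix_rank(D) < p:
        raise SingularMatrixError("GLM design is rank deficient")

    xtx_inv = np.linalg.inv(D.T @ D)
    xtx_inv_c = float(c @ xtx_inv @ c)
    t_obs = _glm_t(D, y, c, xtx_inv_c)

    if perm_indices is None:
        perm_indices = make_permutations(n, B, seed)
    elif perm_indices.shape != (B, n):
        raise TractlinkError("perm_indices must have shape (B, n)")

    nuisance = D[:, c == 0]
    if nuisance.shape[1]:
        gamma, *_ = np.linalg.lstsq(nuisance, y, rcond=None)
        fitted = nuisance @ gamma
    else:
        fitted = np.zeros(n)
    eps = y - fitted

    # vectorized over permutations: Y* (n × B), then batched least squares
    Ystar = fitted[:, None] + eps[perm_indices].T
    pinv = np.linalg.pinv(D)
    beta_all = pinv @ Ystar  # p × B
    resid_all = Ystar - D @ beta_all
    df = n - p
    sigma2 = (resid_all * resid_all).sum(axis=0) / df
    t_null = (c @ beta_all) / np.sqrt(sigma2 * xtx_inv_c)

    perm = PermutationTest(
        observed=t_obs,
        B=B,
        null_draws=t_null,
        p_uncorrected=_add_one_p(t_obs, t_null, sided),
        p_fwe=None,
        family_id=family_id,
        seed=seed,
        sided=sided,
    )
    names = tuple(design_cols) if design_cols else tuple(f"x{i}" for i in range(p))
    return GlmContrastTest(
        outcome=outcome_name,
        design_cols=names,
        contrast=c,
        t_statistic=t_obs,
        perm=perm,
    )


def prematurity_glm_grid(
    cohort,
    *,
    fa_cols: Sequence[str] | None = None,
    B: int = 10_000,
    seed: int = 0,
    sided: str = "two",
) -> dict[str, dict[str, GlmContrastTest]]:
    """Developmental-effect GLM grid: six FA outcomes × two contrasts.

    For every tract FA column, tests (1) the PMA-at-scan effect covaried
    for GA at birth and (2) the GA-at-birth effect covaried for PMA. Each
    contrast's six outcome tests form one max-statistic FWE family.
    """
    fa_cols = tuple(fa_cols or (c for pair in TRACT_SETS.values() for c in pair))
    D = np.column_stack(
        [
            np.ones(len(cohort)),
            cohort["pma_scan"].to_numpy(dtype=float),
            cohort["ga_birth"].to_numpy(dtype=float),
        ]
    )
    names = ("intercept", "pma_scan", "ga_birth")
    contrasts = {"pma_adj_ga": (0.0, 1.0, 0.0), "ga_adj_pma": (0.0, 0.0, 1.0)}
    perms = make_permutations(len(cohort), B, seed)

    out: dict[str, dict[str, GlmContrastTest]] = {}
    for label, cvec in contrasts.items():
        tests = [
            glm_contrast_perm(
                cohort[col].to_numpy(dtype=float),
                D,
                cvec,
                design_cols=names,
                outcome_name=col,
                B=B,
                seed=seed,
                sided=sided,
                perm_indices=perms,
                family_id=f"glm:{label}",
            )
            for col in fa_cols
        ]
        corrected = fwe_correct([t.perm for t in tests])
        for t, cp in zip(tests, corrected):
            t.perm = cp
        out[label] = dict(zip(fa_cols, tests))
    return out


def independent_contribution_glm(
    cohort,
    fa_scores: np.ndarray,
    *,
    outcome_col: str = "lang",
    outcome_confounds: Sequence[str] = DEFAULT_Y_CONFOUNDS,
    B: int = 10_000,
    seed: int = 0,
    sided: str = "two",
) -> dict[str, GlmContrastTest]:
    """Joint GLM of the (SES-residualized) language score on
    [PLS FA score, GA at birth, sex, WM volume], one Freedman–Lane contrast
    per predictor under a single max-statistic family.
    """
    y = cohort[outcome_col].to_numpy(dtype=float)
    if outcome_confounds:
        C = cohort[list(outcome_confounds)].to_numpy(dtype=float)
        r = preprocess.fit_residualizer(y, C, tuple(outcome_confounds))
        y = preprocess.apply_residualizer(r, y, C)
    n = len(cohort)
    D = np.column_stack(
        [
            np.ones(n),
            np.asarray(fa_scores, dtype=float),
            cohort["ga_birth"].to_numpy(dtype=float),
            cohort["sex"].to_numpy(dtype=float),
            cohort["wm_volume"].to_numpy(dtype=float),
        ]
    )
    names = ("intercept", "pls_fa_score", "ga_birth", "sex", "wm_volume")
    perms = make_permutations(n, B, seed)
    tests = []
    for j in range(1, D.shape[1]):
        cvec = np.zeros(D.shape[1])
        cvec[j] = 1.0
        tests.append(
            glm_contrast_perm(
                y,
                D,
                cvec,
                design_cols=names,
                outcome_name=outcome_col,
                B=B,
                seed=seed,
                sided=sided,
                perm_indices=perms,
                family_id="glm:independent_contributions",
            )
        )
    corrected = fwe_correct([t.perm for t in tests])
    for t, cp in zip(tests, corrected):
        t.perm = cp
    return dict(zip(names[1:], tests))


# ---------------------------------------------------------------------------
# partial correlation
# ---------------------------------------------------------------------------


def partial_corr_perm(
    a: np.ndarray,
    b: np.ndarray,
    covariates: np.ndarray | None = None,
    *,
    B: int = 10_000,
    seed: int = 0,
    sided: str = "two",
    perm_indices: np.ndarray | None = None,
    family_id: str = "partial_corr",
) -> PermutationTest:
    """Partial Pearson correlation of ``a`` and ``b`` given covariates,
    with Freedman–Lane permutation inference.

    Both variables are OLS-residualized on [1, covariates]; per permutation
    the residuals of ``a`` are shuffled and re-residualized before
    correlating with the fixed residuals of ``b``. With no covariates this
    equals the plain correlation under simple permutation.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    n = a.shape[0]
    if b.shape[0] != n:
        raise TractlinkError("a and b must have equal length")
    if covariates is not None and np.size(covariates):
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        Z = np.column_stack([np.ones(n), C])
    else:
        Z = np.ones((n, 1))
    q = Z.shape[1] - 1
    if n <= q + 2:
        raise TractlinkError(f"need n > q + 2 (got n={n}, q={q})")
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise SingularMatrixError("covariate matrix is rank deficient")

    M = np.eye(n) - Z @ np.linalg.pinv(Z)  # residual-maker projection
    ra = M @ a
    rb = M @ b
    # a variable lying in the covariate span has (numerically) zero residual:
    # its partial correlation with anything is exactly 0
    tol_a = 1e-10 * max(float(np.linalg.norm(a)), 1.0)
    tol_b = 1e-10 * max(float(np.linalg.norm(b)), 1.0)
    if np.linalg.norm(ra) < tol_a or np.linalg.norm(rb) < tol_b:
        null = np.zeros(B if perm_indices is None else perm_indices.shape[0])
        return PermutationTest(
            observed=0.0,
            B=null.shape[0],
            null_draws=null,
            p_uncorrected=1.0,
            p_fwe=None,
            family_id=family_id,
            seed=seed,
            sided=sided,
        )
    denom_b = float(np.linalg.norm(rb))
    observed = float(ra @ rb / (np.linalg.norm(ra) * denom_b))

    if perm_indices is None:
        perm_indices = make_permutations(n, B, seed)
    elif perm_indices.shape != (B, n):
        raise TractlinkError("perm_indices must have shape (B, n)")

    Ra = ra[perm_indices] @ M.T  # (B, n) re-residualized permuted residuals
    norms = np.linalg.norm(Ra, axis=1)
    null = (Ra @ rb) / (norms * denom_b)

    return PermutationTest(
        observed=observed,
        B=B,
        null_draws=null,
        p_uncorrected=_add_one_p(observed, null, sided),
        p_fwe=None,
        family_id=family_id,
        seed=seed,
        sided=sided,
    )


# ---------------------------------------------------------------------------
# asymmetry and paired tests
# ---------------------------------------------------------------------------


def asymmetry_index(fa_left, fa_right):
    """Lateralization index (L − R)/(L + R) ∈ (−1, 1); positive = leftward."""
    left = np.asarray(fa_left, dtype=float)
    right = np.asarray(fa_right, dtype=float)
    denom = left + right
    if np.any(denom <= 0):
        raise TractlinkError("asymmetry index undefined for non-positive L + R")
    out = (left - right) / denom
    return float(out) if out.ndim == 0 else out


def paired_signed_rank(left: np.ndarray, right: np.ndarray) -> tuple[float, float]:
    """Wilcoxon signed-rank test of paired left/right values.

    Continuity-corrected normal approximation with zeros dropped and
    mid-ranks for ties; returns the (signed) z-value and the two-sided
    p-value.
    """
    left = np.asarray(left, dtype=float).ravel()
    right = np.asarray(right, dtype=float).ravel()
    if left.shape != right.shape:
        raise TractlinkError("left and right must have equal length")
    if left.shape[0] < 5:
        raise TractlinkError("paired test needs n ≥ 5")
    if np.all(left == right):
        raise TractlinkError(
            "signed-rank test undefined: all paired differences are zero"
        )
    try:
        res = stats.wilcoxon(
            left,
            right,
            zero_method="wilcox",
            correction=True,
            alternative="two-sided",
            method="approx",
        )
    except ValueError as exc:
        raise TractlinkError(f"signed-rank test failed: {exc}") from exc
    return float(res.zstatistic), float(res.pvalue)
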