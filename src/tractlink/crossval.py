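"""Leave-one-out cross-validated brain-behavior link.

For each fold the n−1 training rows are (optionally re-)residualized,
standardized (training parameters only), a model is fitted (PLS / OLS /
Ridge) and the held-out row is transformed with the training parameters and
projected:

* PLS: the held-out "FA score" and "language score" are the projections of
  the held-out X and Y rows onto the training x-weights and y-weights
  (component 1);
* OLS/Ridge: the x-score is the prediction of the standardized first
  outcome, the y-score is that outcome's observed standardized value.

The link statistic ``r_cv`` is the correlation (Pearson by default,
Spearman optionally) over the n out-of-sample score pairs. PLS components
carry a sign indeterminacy; here each block's fold weights are oriented
*independently* by the deterministic, training-only canonical sign (sum of
weights ≥ 0, first entry breaking ties). This gives every fold — and every
permutation replicate — the same directional convention, so a positive
r_cv always reads "higher FA goes with better outcome", the null
distribution can land on either side of zero (a one-sided test is
meaningful), and no information about the held-out subject enters its own
fold's orientation. Tying the Y-block sign to the X-block per fold (as raw
NIPALS does) would make the statistic behave like |r| under the null;
aligning folds to the full-sample fit would leak the held-out subject and
bias r_cv upward.

Two execution paths produce bit-comparable results (tested): a general
per-fold loop through the public preprocessing/model API, and a
fold-batched path for the default configuration (K = 1, full-sample
residualization) that runs the same NIPALS iteration on all folds at once.
The batched path is what makes permutation testing (which re-runs the full
LOOCV per permutation) affordable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import preprocess
from .errors import SingularMatrixError, TractlinkError
from .pls import fit_ols, fit_pls, fit_ridge, predict, project

__all__ = ["CvLinkResult", "loocv_link", "loading_stability"]

#: default confound assignment: PMA out of FA features, SES out of outcomes
DEFAULT_X_CONFOUNDS: tuple[str, ...] = ("pma_scan",)
DEFAULT_Y_CONFOUNDS: tuple[str, ...] = ("ses",)


@dataclass
class CvLinkResult:
    """Out-of-sample score pairs and fold-stability summaries."""

    method: str
    x_cols: tuple[str, ...]
    y_cols: tuple[str, ...]
    x_scores: np.ndarray  # n out-of-sample scores, component 1
    y_scores: np.ndarray
    r_cv: float
    corr_method: str
    loadings_x_mean: np.ndarray
    loadings_x_sd: np.ndarray
    loadings_y_mean: np.ndarray | None
    loadings_y_sd: np.ndarray | None
    varexp_x_mean: float | None
    varexp_y_mean: float | None

    @property
    def n(self) -> int:
        return self.x_scores.shape[0]

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "x_cols": list(self.x_cols),
            "y_cols": list(self.y_cols),
            "r_cv": self.r_cv,
            "corr_method": self.corr_method,
            "x_scores": self.x_scores.tolist(),
            "y_scores": self.y_scores.tolist(),
            "loadings_x_mean": self.loadings_x_mean.tolist(),
            "loadings_x_sd": self.loadings_x_sd.tolist(),
            "loadings_y_mean": (
                None if self.loadings_y_mean is None else self.loadings_y_mean.tolist()
            ),
            "loadings_y_sd": (
                None if self.loadings_y_sd is None else self.loadings_y_sd.tolist()
            ),
            "varexp_x_mean": self.varexp_x_mean,
            "varexp_y_mean": self.varexp_y_mean,
        }


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "pearson":
        return float(np.corrcoef(x, y)[0, 1])
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise TractlinkError(f"unknown correlation method {method!r}")


def loading_stability(fold_weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise mean and sample SD of (sign-aligned) per-fold weights."""
    fold_weights = np.asarray(fold_weights, dtype=float)
    if fold_weights.ndim != 2:
        raise TractlinkError("fold_weights must be a 2-D (folds × variables) array")
    return fold_weights.mean(axis=0), fold_weights.std(axis=0, ddof=1)


# ---------------------------------------------------------------------------
# fold-batched fast path (K = 1, residualization already applied)
# ---------------------------------------------------------------------------


def _block_signs(w: np.ndarray) -> np.ndarray:
    """Per-row canonical sign: flip so each row sums ≥ 0 (first entry breaks ties)."""
    s = w.sum(axis=1)
    return np.where(np.abs(s) > 1e-12, np.sign(s), np.where(w[:, 0] >= 0, 1.0, -1.0))


def _loo_standardize(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Leave-one-out training means/SDs and the masked standardized tensor.

    Returns (A, m, s): ``A[i]`` is the full data standardized with fold i's
    training parameters, with row i zeroed (so sums over rows only see the
    n−1 training rows); ``m``/``s`` are (n, p) fold-wise training means and
    population SDs.
    """
    n = M.shape[0]
    ssum = M.sum(axis=0)
    ssq = (M * M).sum(axis=0)
    m = (ssum - M) / (n - 1)
    v = (ssq - M * M) / (n - 1) - m * m
    v = np.maximum(v, 0.0)
    if np.any(v <= 0):
        fold = int(np.argwhere(v <= 0)[0][0])
        raise TractlinkError(f"constant column in training fold {fold}")
    s = np.sqrt(v)
    A = (M[None, :, :] - m[:, None, :]) / s[:, None, :]
    A[np.arange(n), np.arange(n), :] = 0.0
    return A, m, s


def _batched_nipals_k1(
    A: np.ndarray, B: np.ndarray, tol: float = 1e-12, max_iter: int = 2000
):
    """One NIPALS component on every fold simultaneously.

    ``A``/``B`` are masked standardized (n_folds, n, p/q) tensors from
    :func:`_loo_standardize`; the iteration is identical to the per-fold
    algorithm in :mod:`tractlink.pls`. When the two leading singular values
    of a fold's cross-covariance are almost equal (which happens routinely
    in permutation nulls with a multi-column Y) the direction converges
    only geometrically at their ratio; after ``max_iter`` sweeps the
    current iterate — already converged to the leading sub*space* — is
    accepted, since any direction in that subspace captures the same
    covariance.
    """
    nf = A.shape[0]
    # standardized training columns all have unit variance, so the
    # maximal-variance initialization deterministically picks column 0,
    # exactly as the scalar NIPALS does on standardized input
    u = B[:, :, 0].copy()
    w_old = np.zeros((nf, A.shape[2]))
    for _ in range(max_iter):
        w = np.einsum("fnp,fn->fp", A, u)
        w /= np.linalg.norm(w, axis=1, keepdims=True)
        t = np.einsum("fnp,fp->fn", A, w)
        c = np.einsum("fnq,fn->fq", B, t)
        c /= np.linalg.norm(c, axis=1, keepdims=True)
        u = np.einsum("fnq,fq->fn", B, c)
        if float(np.abs(w - w_old).max()) < tol:
            break
        w_old = w
    tt = np.einsum("fn,fn->f", t, t)
    uu = np.einsum("fn,fn->f", u, u)
    p_load = np.einsum("fnp,fn->fp", A, t) / tt[:, None]
    q_load = np.einsum("fnq,fn->fq", B, u) / uu[:, None]
    return w, c, t, u, p_load, q_load, tt, uu


def _loocv_fast(
    X: np.ndarray,
    Y: np.ndarray,
    method: str,
    ridge_lambda: float,
    details: bool,
):
    """Batched LOOCV for K = 1 on pre-residualized blocks."""
    n, p_dim = X.shape
    q_dim = Y.shape[1]
    A, mx, sx = _loo_standardize(X)
    B, my, sy = _loo_standardize(Y)
    x_held = (X - mx) / sx  # row i standardized with fold i's parameters
    y_held = (Y - my) / sy

    if method == "pls":
        w, c, _, _, p_load, q_load, tt, uu = _batched_nipals_k1(A, B)
        # each block oriented independently by its training-only canonical
        # sign, so a positive r_cv always means "higher FA goes with better
        # outcome" and the null can land on either side of zero
        w *= _block_signs(w)[:, None]
        c *= _block_signs(c)[:, None]
        xs = np.einsum("np,np->n", x_held, w)
        ys = np.einsum("nq,nq->n", y_held, c)
        if not details:
            return xs, ys, None
        # variance removed by canonical deflation of one component,
        # as a fraction of the standardized training block variance
        ssx = (n - 1) * p_dim
        ssy = (n - 1) * q_dim
        vex = tt * np.einsum("fp,fp->f", p_load, p_load) / ssx
        vey = uu * np.einsum("fq,fq->f", q_load, q_load) / ssy
        return xs, ys, {
            "wx": w,
            "wy": c,
            "varexp_x": vex,
            "varexp_y": vey,
        }

    if method in ("ols", "ridge"):
        lam = ridge_lambda if method == "ridge" else 0.0
        b_col = B[:, :, 0]
        G = np.einsum("fnp,fnq->fpq", A, A) + lam * np.eye(p_dim)
        g = np.einsum("fnp,fn->fp", A, b_col)
        if lam == 0.0 and np.linalg.matrix_rank(G[0]) < p_dim:
            raise SingularMatrixError(
                "XᵀX singular in LOOCV training fold; consider ridge or PLS"
            )
        beta = np.linalg.solve(G, g[..., None])[..., 0]
        xs = np.einsum("np,np->n", x_held, beta)
        ys = y_held[:, 0]
        if not details:
            return xs, ys, None
        return xs, ys, {"wx": beta, "wy": None, "varexp_x": None, "varexp_y": None}

    raise TractlinkError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# general per-fold loop (any K, optional within-fold residualization)
# ---------------------------------------------------------------------------


def _loocv_general(
    X: np.ndarray,
    Y: np.ndarray,
    Cx: np.ndarray | None,
    Cy: np.ndarray | None,
    method: str,
    K: int,
    ridge_lambda: float,
    residualize_within_fold: bool,
    details: bool,
):
    n = X.shape[0]
    xs = np.empty(n)
    ys = np.empty(n)
    wx_folds = []
    wy_folds = []
    vex_folds = []
    vey_folds = []
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        Xt, Yt = X[tr], Y[tr]
        xh, yh = X[i], Y[i]
        if residualize_within_fold:
            rx = preprocess.fit_residualizer(Xt, Cx[tr])
            ry = preprocess.fit_residualizer(Yt, Cy[tr])
            Xt = preprocess.apply_residualizer(rx, Xt, Cx[tr])
            Yt = preprocess.apply_residualizer(ry, Yt, Cy[tr])
            xh = preprocess.apply_residualizer(rx, xh[None, :], Cx[i][None, :])[0]
            yh = preprocess.apply_residualizer(ry, yh[None, :], Cy[i][None, :])[0]
        try:
            stx = preprocess.fit_standardizer(Xt)
            sty = preprocess.fit_standardizer(Yt)
        except TractlinkError as exc:
            raise TractlinkError(f"fold {i}: {exc}") from exc
        Xs = preprocess.apply_standardizer(stx, Xt)
        Ys = preprocess.apply_standardizer(sty, Yt)
        xh = preprocess.apply_standardizer(stx, xh[None, :])[0]
        yh = preprocess.apply_standardizer(sty, yh[None, :])[0]

        if method == "pls":
            try:
                model = fit_pls(Xs, Ys, K=K)
            except TractlinkError as exc:
                raise TractlinkError(f"fold {i}: {exc}") from exc
            # fit_pls orients components jointly (sum of x-weights ≥ 0);
            # re-orient the Y block by its own canonical sign so both
            # blocks carry the same directional convention as the fast path
            w1 = model.x_weights[:, 0]
            c1 = model.y_weights[:, 0].copy()
            cflip = float(_block_signs(c1[None, :])[0])
            c1 *= cflip
            sx_all, sy_all = project(model, xh, yh)
            xs[i] = float(np.atleast_1d(sx_all)[0])
            ys[i] = cflip * float(np.atleast_1d(sy_all)[0])
            if details:
                wx_folds.append(w1)
                wy_folds.append(c1)
                vex_folds.append(model.varexp_x[0])
                vey_folds.append(model.varexp_y[0])
        elif method in ("ols", "ridge"):
            y1 = Ys[:, 0]
            link = (
                fit_ols(Xs, y1)
                if method == "ols"
                else fit_ridge(Xs, y1, ridge_lambda)
            )
            xs[i] = float(predict(link, xh[None, :])[0])
            ys[i] = float(yh[0])
            if details:
                wx_folds.append(link.coef)
        else:
            raise TractlinkError(f"unknown method {method!r}")

    if not details:
        return xs, ys, None
    det = {
        "wx": np.array(wx_folds),
        "wy": np.array(wy_folds) if wy_folds else None,
        "varexp_x": np.array(vex_folds) if vex_folds else None,
        "varexp_y": np.array(vey_folds) if vey_folds else None,
    }
    return xs, ys, det


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------


def loocv_scores(
    X: np.ndarray,
    Y: np.ndarray,
    method: str = "pls",
    *,
    ridge_lambda: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Low-level LOOCV on pre-residualized blocks: the n score pairs only.

    This is the unit of work a permutation test repeats; it uses the
    fold-batched path.
    """
    return _loocv_fast(X, Y, method, ridge_lambda, details=False)[:2]


def loocv_link(
    cohort,
    x_cols,
    y_cols,
    method: str = "pls",
    *,
    x_confounds=DEFAULT_X_CONFOUNDS,
    y_confounds=DEFAULT_Y_CONFOUNDS,
    residualize_within_fold: bool = False,
    K: int = 1,
    ridge_lambda: float = 1.0,
    corr_method: str = "pearson",
) -> CvLinkResult:
    """Leave-one-out cross-validated link between an FA block and outcomes.

    Parameters
    ----------
    cohort
        Validated cohort DataFrame.
    x_cols, y_cols
        Feature (FA) and outcome column names.
    method
        ``pls`` (default), ``ols`` or ``ridge``.
    x_confounds, y_confounds
        Confound columns removed from each block (PMA from FA, SES from
        outcomes, by default). Empty tuples disable residualization.
    residualize_within_fold
        If False (default, matching an analysis-wide confound removal
        performed prior to cross-validation) the residualizer is fitted
        once on the full sample; if True it is refitted inside every
        training fold.
    """
    x_cols = tuple(x_cols)
    y_cols = tuple(y_cols)
    for col in x_cols + y_cols + tuple(x_confounds) + tuple(y_confounds):
        if col not in cohort.columns:
            raise TractlinkError(f"column {col!r} not in cohort")
    n = len(cohort)
    if n < 5:
        raise TractlinkError("LOOCV needs at least 5 subjects")

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

    if not residualize_within_fold and K == 1:
        xs, ys, det = _loocv_fast(X, Y, method, ridge_lambda, details=True)
    else:
        xs, ys, det = _loocv_general(
            X,
            Y,
            Cx,
            Cy,
            method,
            K,
            ridge_lambda,
            residualize_within_fold,
            details=True,
        )

    lx_mean, lx_sd = loading_stability(det["wx"])
    if det["wy"] is not None:
        ly_mean, ly_sd = loading_stability(det["wy"])
    else:
        ly_mean = ly_sd = None
    return CvLinkResult(
        method=method,
        x_cols=x_cols,
        y_cols=y_cols,
        x_scores=xs,
        y_scores=ys,
        r_cv=_corr(xs, ys, corr_method),
        corr_method=corr_method,
        loadings_x_mean=lx_mean,
        loadings_x_sd=lx_sd,
        loadings_y_mean=ly_mean,
        loadings_y_sd=ly_sd,
        varexp_x_mean=(
            float(det["varexp_x"].mean()) if det["varexp_x"] is not None else None
        ),
        varexp_y_mean=(
            float(det["varexp_y"].mean()) if det["varexp_y"] is not None else None
        ),
    )
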