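"""Partial least squares (NIPALS, mode A, canonical deflation) and linear comparators.

This is the analytic core of the package. ``fit_pls`` implements the
classical NIPALS algorithm for symmetric two-block covariation:

* inner loop (per component): initialize ``u`` as the Y column of maximal
  variance, then iterate ``w = Xᵀu/‖Xᵀu‖``, ``t = Xw``, ``c = Yᵀt/‖Yᵀt‖``,
  ``u = Yc`` until the change in ``w`` falls below ``tol``;
* mode-A loadings ``p = Xᵀt/(tᵀt)``, ``q = Yᵀu/(uᵀu)``;
* canonical deflation ``X ← X − t pᵀ``, ``Y ← Y − u qᵀ`` (both blocks are
  deflated by their *own* scores, modeling covariation rather than a
  regression of Y on X).

For a single component the converged ``(w, c)`` equal the leading
singular-vector pair of the cross-covariance ``XᵀY`` — a property the test
suite checks against an independent SVD oracle.

A deterministic sign convention (each component flipped so that the sum of
its X-weights is non-negative, both blocks together) makes fits
reproducible across runs and platforms.

``fit_ols`` / ``fit_ridge`` provide the cross-validated comparators: plain
least squares (which degrades when left/right FA are strongly collinear)
and its L2-regularized variant with an unpenalized intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConvergenceError, SingularMatrixError, TractlinkError

__all__ = [
    "PlsModel",
    "LinearLink",
    "fit_pls",
    "project",
    "variance_explained",
    "fit_ols",
    "fit_ridge",
    "predict",
]

_CENTER_TOL = 1e-8


@dataclass
class PlsModel:
    """A fitted K-component mode-A canonical PLS decomposition."""

    K: int
    x_weights: np.ndarray  # p × K, unit-norm columns
    y_weights: np.ndarray  # q × K, unit-norm columns
    x_scores: np.ndarray  # n × K (t)
    y_scores: np.ndarray  # n × K (u)
    x_loadings: np.ndarray  # p × K
    y_loadings: np.ndarray  # q × K
    varexp_x: np.ndarray  # K, fraction of X-block variance per component
    varexp_y: np.ndarray  # K
    n_iter: tuple[int, ...] = field(default=())

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "x_weights": self.x_weights.tolist(),
            "y_weights": self.y_weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "varexp_x": self.varexp_x.tolist(),
            "varexp_y": self.varexp_y.tolist(),
            "n_iter": list(self.n_iter),
        }


@dataclass
class LinearLink:
    """OLS or Ridge regression of a single outcome on the feature block."""

    method: str  # "ols" | "ridge"
    coef: np.ndarray
    intercept: float
    ridge_lambda: float = 0.0


def _canonical_sign(w: np.ndarray) -> float:
    """+1/−1 so that flipping makes sum(w) ≥ 0; first nonzero entry breaks ties."""
    s = float(w.sum())
    if abs(s) > 1e-12:
        return 1.0 if s >= 0 else -1.0
    nz = np.flatnonzero(np.abs(w) > 1e-12)
    if nz.size == 0:
        return 1.0
    return 1.0 if w[nz[0]] > 0 else -1.0


def _check_centered(M: np.ndarray, name: str) -> None:
    scale = max(1.0, float(np.abs(M).max(initial=0.0)))
    if np.abs(M.mean(axis=0)).max(initial=0.0) > _CENTER_TOL * scale:
        raise TractlinkError(f"{name} block is not column-centered")
    if np.any(M.std(axis=0) <= 0):
        raise TractlinkError(f"{name} block has a zero-variance column")


def _nipals(
    X: np.ndarray,
    Y: np.ndarray,
    K: int,
    tol: float,
    max_iter: int,
):
    """Inner NIPALS driver on pre-validated centered copies."""
    Xd = X.copy()
    Yd = Y.copy()
    ssx0 = float((X * X).sum())
    ssy0 = float((Y * Y).sum())
    p_dim, q_dim = X.shape[1], Y.shape[1]
    n = X.shape[0]

    W = np.empty((p_dim, K))
    C = np.empty((q_dim, K))
    T = np.empty((n, K))
    U = np.empty((n, K))
    P = np.empty((p_dim, K))
    Q = np.empty((q_dim, K))
    vex = np.empty(K)
    vey = np.empty(K)
    iters: list[int] = []

    for k in range(K):
        u = Yd[:, int(Yd.var(axis=0).argmax())].copy()
        w_old = np.zeros(p_dim)
        delta = np.inf
        for it in range(1, max_iter + 1):
            w = Xd.T @ u
            nw = np.linalg.norm(w)
            if nw < 1e-300:
                raise TractlinkError(
                    f"component {k + 1}: cross-covariance vanished (Xᵀu = 0)"
                )
            w /= nw
            t = Xd @ w
            c = Yd.T @ t
            nc = np.linalg.norm(c)
            if nc < 1e-300:
                raise TractlinkError(
                    f"component {k + 1}: cross-covariance vanished (Yᵀt = 0)"
                )
            c /= nc
            u = Yd @ c
            delta = float(np.linalg.norm(w - w_old))
            if delta < tol:
                break
            w_old = w
        else:
            raise ConvergenceError(
                f"NIPALS did not converge for component {k + 1} within "
                f"{max_iter} iterations (last delta {delta:.3e})",
                last_delta=delta,
            )
        iters.append(it)

        tt = float(t @ t)
        uu = float(u @ u)
        if tt <= 0 or uu <= 0:
            raise TractlinkError(f"component {k + 1}: degenerate scores")
        p_load = Xd.T @ t / tt
        q_load = Yd.T @ u / uu

        flip = _canonical_sign(w)
        w, t, p_load = flip * w, flip * t, flip * p_load
        c, u, q_load = flip * c, flip * u, flip * q_load

        ssx_before = float((Xd * Xd).sum())
        ssy_before = float((Yd * Yd).sum())
        Xd = Xd - np.outer(t, p_load)
        Yd = Yd - np.outer(u, q_load)
        vex[k] = (ssx_before - float((Xd * Xd).sum())) / ssx0
        vey[k] = (ssy_before - float((Yd * Yd).sum())) / ssy0

        W[:, k], C[:, k], T[:, k], U[:, k] = w, c, t, u
        P[:, k], Q[:, k] = p_load, q_load

    return W, C, T, U, P, Q, vex, vey, tuple(iters)


def fit_pls(
    X: np.ndarray,
    Y: np.ndarray,
    K: int = 1,
    tol: float = 1e-12,
    max_iter: int = 500,
) -> PlsModel:
    """Fit a K-component mode-A canonical PLS model to centered blocks.

    Parameters
    ----------
    X, Y
        Column-centered blocks of shape (n, p) and (n, q) with n ≥ 3.
        A one-dimensional Y is treated as a single column.
    K
        Number of components, 1 ≤ K ≤ min(p, q).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise TractlinkError("X and Y must be 2-D with matching row counts")
    if X.shape[0] < 3:
        raise TractlinkError("need at least 3 rows to fit PLS")
    if not 1 <= K <= min(X.shape[1], Y.shape[1]):
        raise TractlinkError(
            f"K={K} outside [1, min(p, q)={min(X.shape[1], Y.shape[1])}]"
        )
    _check_centered(X, "X")
    _check_centered(Y, "Y")

    W, C, T, U, P, Q, vex, vey, iters = _nipals(X, Y, K, tol, max_iter)
    return PlsModel(
        K=K,
        x_weights=W,
        y_weights=C,
        x_scores=T,
        y_scores=U,
        x_loadings=P,
        y_loadings=Q,
        varexp_x=vex,
        varexp_y=vey,
        n_iter=iters,
    )


def project(model: PlsModel, x_new: np.ndarray, y_new: np.ndarray):
    """Project new (already residualized + standardized) rows onto the weights.

    Returns the pair of score vectors ``(x_new @ x_weights, y_new @ y_weights)``;
    the first-component entries are the subject's "PLS FA score" and
    "PLS language score".
    """
    x_new = np.asarray(x_new, dtype=float)
    y_new = np.asarray(y_new, dtype=float)
    if x_new.shape[-1] != model.x_weights.shape[0]:
        raise TractlinkError(
            f"x dimension mismatch: expected {model.x_weights.shape[0]}, "
            f"got {x_new.shape[-1]}"
        )
    if y_new.ndim == 0 or (y_new.ndim == 1 and model.y_weights.shape[0] == 1):
        y_new = np.atleast_1d(y_new)
        if y_new.shape[-1] != 1 and model.y_weights.shape[0] == 1:
            y_new = y_new[..., None]
    if y_new.shape[-1] != model.y_weights.shape[0]:
        raise TractlinkError(
            f"y dimension mismatch: expected {model.y_weights.shape[0]}, "
            f"got {y_new.shape[-1]}"
        )
    return x_new @ model.x_weights, y_new @ model.y_weights


def variance_explained(model: PlsModel, block: str, k: int | None = None):
    """Fraction of block variance explained by component ``k`` (1-based).

    With ``k=None`` the full per-component vector is returned.
    """
    if block not in ("x", "y"):
        raise TractlinkError("block must be 'x' or 'y'")
    vec = model.varexp_x if block == "x" else model.varexp_y
    if k is None:
        return vec.copy()
    if not 1 <= k <= model.K:
        raise TractlinkError(f"component {k} outside [1, K={model.K}]")
    return float(vec[k - 1])


def _solve_ridge(X: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """Centered-normal-equations solve with unpenalized intercept."""
    xm = X.mean(axis=0)
    ym = float(y.mean())
    Xc = X - xm
    yc = y - ym
    G = Xc.T @ Xc + lam * np.eye(X.shape[1])
    if lam == 0.0:
        # plain OLS: refuse a singular system rather than pseudo-inverting
        if np.linalg.matrix_rank(Xc.T @ Xc) < X.shape[1]:
            raise SingularMatrixError(
                "XᵀX is singular (collinear predictors); OLS coefficients are "
                "not identified — consider ridge or PLS"
            )
    coef = np.linalg.solve(G, Xc.T @ yc)
    intercept = ym - float(xm @ coef)
    return coef, intercept


def fit_ols(X: np.ndarray, y: np.ndarray) -> LinearLink:
    """Ordinary least squares β = (XᵀX)⁻¹Xᵀy with intercept."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    coef, intercept = _solve_ridge(X, y, 0.0)
    return LinearLink(method="ols", coef=coef, intercept=intercept, ridge_lambda=0.0)


def fit_ridge(X: np.ndarray, y: np.ndarray, lam: float = 1.0) -> LinearLink:
    """Ridge regression with penalty ``lam`` ≥ 0 and unpenalized intercept."""
    if lam < 0:
        raise TractlinkError("ridge penalty must be ≥ 0")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    coef, intercept = _solve_ridge(X, y, lam)
    return LinearLink(method="ridge", coef=coef, intercept=intercept, ridge_lambda=lam)


def predict(link: LinearLink, X_new: np.ndarray) -> np.ndarray:
    """Linear prediction from a fitted OLS/Ridge link."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != link.coef.shape[0]:
        raise TractlinkError(
            f"feature mismatch: model has {link.coef.shape[0]}, data has "
            f"{X_new.shape[1]}"
        )
    return X_new @ link.coef + link.intercept
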