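"""Confound residualization and train-fold standardization.

Two deliberately small, serializable transforms:

* :class:`ResidualizationModel` — ordinary least-squares removal of confound
  variables from target columns (postmenstrual age at scan from the FA
  block; socioeconomic score from the outcome block). By default it is
  fitted once on the full sample before cross-validation; the leakage-free
  per-fold variant is available through the cross-validation options.
* :class:`Standardizer` — zero-mean / unit-variance scaling with the
  *population* (divisor n) variance convention, always fitted on the
  training fold and applied unchanged to held-out rows.

The pipeline order is fixed: residualize, then standardize. The two
operations do not commute in general (residualization changes column
scales), so the order is part of the contract and is covered by tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SingularMatrixError, TractlinkError

__all__ = [
    "ResidualizationModel",
    "Standardizer",
    "fit_residualizer",
    "apply_residualizer",
    "fit_standardizer",
    "apply_standardizer",
    "invert_standardizer",
]


def _design(confounds: np.ndarray) -> np.ndarray:
    """Prepend an intercept column."""
    confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
    if confounds.ndim != 2:
        raise TractlinkError("confounds must be a 2-D matrix (n × q)")
    return np.column_stack([np.ones(confounds.shape[0]), confounds])


@dataclass(frozen=True)
class ResidualizationModel:
    """OLS fit of each target column on [1, confounds].

    ``coefficients`` has shape (q + 1, p): row 0 is the intercept.
    """

    confound_names: tuple[str, ...]
    coefficients: np.ndarray

    def to_dict(self) -> dict:
        return {
            "confound_names": list(self.confound_names),
            "coefficients": self.coefficients.tolist(),
        }


@dataclass(frozen=True)
class Standardizer:
    """Per-feature location/scale learned on a training block (divisor n)."""

    means: np.ndarray
    sds: np.ndarray
    feature_names: tuple[str, ...] = field(default=())

    def to_dict(self) -> dict:
        return {"means": self.means.tolist(), "sds": self.sds.tolist()}


def fit_residualizer(
    targets: np.ndarray,
    confounds: np.ndarray,
    confound_names: tuple[str, ...] | None = None,
) -> ResidualizationModel:
    """Fit the confound-removal model by least squares.

    Requires n > q + 1 and a full-column-rank design after adding the
    intercept; a rank-deficient design raises :class:`SingularMatrixError`
    naming the collinear columns.
    """
    targets = np.asarray(targets, dtype=float)
    if targets.ndim == 1:
        targets = targets[:, None]
    X = _design(confounds)
    n, q1 = X.shape
    if n <= q1:
        raise TractlinkError(f"need n > q + 1 (got n={n}, q={q1 - 1})")
    if np.linalg.matrix_rank(X) < q1:
        names = confound_names or tuple(f"c{i}" for i in range(q1 - 1))
        raise SingularMatrixError(
            "confound design is rank deficient (collinear columns among: "
            + ", ".join(("intercept",) + tuple(names))
            + ")"
        )
    coef, *_ = np.linalg.lstsq(X, targets, rcond=None)
    names = confound_names or tuple(f"c{i}" for i in range(q1 - 1))
    return ResidualizationModel(confound_names=tuple(names), coefficients=coef)


def apply_residualizer(
    model: ResidualizationModel,
    targets: np.ndarray,
    confounds: np.ndarray,
    confound_names: tuple[str, ...] | None = None,
) -> np.ndarray:
    """Subtract the model-predicted confound contribution from ``targets``."""
    targets = np.asarray(targets, dtype=float)
    squeeze = targets.ndim == 1
    if squeeze:
        targets = targets[:, None]
    X = _design(confounds)
    if X.shape[1] != model.coefficients.shape[0]:
        raise TractlinkError(
            f"confound count mismatch: model expects "
            f"{model.coefficients.shape[0] - 1}, got {X.shape[1] - 1}"
        )
    if confound_names is not None and tuple(confound_names) != model.confound_names:
        raise TractlinkError(
            f"confound columns {tuple(confound_names)} do not match the model's "
            f"{model.confound_names}"
        )
    resid = targets - X @ model.coefficients
    return resid[:, 0] if squeeze else resid


def fit_standardizer(
    train: np.ndarray, feature_names: tuple[str, ...] = ()
) -> Standardizer:
    """Learn per-feature mean and population SD on a training block."""
    train = np.asarray(train, dtype=float)
    if train.ndim == 1:
        train = train[:, None]
    if train.shape[0] < 2:
        raise TractlinkError("standardizer needs at least 2 training rows")
    means = train.mean(axis=0)
    sds = train.std(axis=0, ddof=0)
    if np.any(sds <= 0) or not np.all(np.isfinite(sds)):
        bad = np.where(~(sds > 0))[0]
        labels = (
            [feature_names[i] for i in bad] if feature_names else bad.tolist()
        )
        raise TractlinkError(f"constant (zero-variance) feature(s): {labels}")
    return Standardizer(means=means, sds=sds, feature_names=tuple(feature_names))


def apply_standardizer(s: Standardizer, data: np.ndarray) -> np.ndarray:
    """Apply training location/scale to new data."""
    data = np.asarray(data, dtype=float)
    squeeze = data.ndim == 1
    if squeeze:
        data = data[:, None]
    if data.shape[1] != s.means.shape[0]:
        raise TractlinkError(
            f"feature count mismatch: standardizer has {s.means.shape[0]}, "
            f"data has {data.shape[1]}"
        )
    out = (data - s.means) / s.sds
    return out[:, 0] if squeeze else out


def invert_standardizer(s: Standardizer, data: np.ndarray) -> np.ndarray:
    """Undo :func:`apply_standardizer` (exact up to float rounding)."""
    data = np.asarray(data, dtype=float)
    squeeze = data.ndim == 1
    if squeeze:
        data = data[:, None]
    out = data * s.sds + s.means
    return out[:, 0] if squeeze else out
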