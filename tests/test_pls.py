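"""NIPALS PLS core against independent oracles (SVD, closed forms, sklearn)."""

import numpy as np
import pytest

import tractlink as tl
from tractlink.errors import SingularMatrixError, TractlinkError
from tractlink.pls import _canonical_sign

from conftest import centered


def svd_leading_pair(X, Y):
    """Independent oracle: leading singular vectors of the cross-covariance."""
    U, _, Vt = np.linalg.svd(X.T @ Y, full_matrices=False)
    w, c = U[:, 0], Vt[0, :]
    flip = _canonical_sign(w)
    return flip * w, flip * c


def canon(v):
    return _canonical_sign(v) * v


def test_identical_blocks_give_identical_components(rng):
    X = centered(rng, 25, 2)
    model = tl.fit_pls(X, X.copy(), K=1)
    np.testing.assert_allclose(model.x_weights, model.y_weights, atol=1e-10)
    np.testing.assert_allclose(model.x_scores, model.y_scores, atol=1e-10)
    r = np.corrcoef(model.x_scores[:, 0], model.y_scores[:, 0])[0, 1]
    assert r == pytest.approx(1.0, abs=1e-10)


def test_component_one_matches_svd_oracle(rng):
    X = centered(rng, 20, 2)
    Y = centered(rng, 20, 2)
    model = tl.fit_pls(X, Y, K=1)
    w, c = svd_leading_pair(X, Y)
    np.testing.assert_allclose(model.x_weights[:, 0], w, atol=1e-8)
    np.testing.assert_allclose(canon(model.y_weights[:, 0]), canon(c), atol=1e-8)


def test_full_decomposition_explains_all_variance(rng):
    X = centered(rng, 30, 2)
    Y = centered(rng, 30, 2)
    model = tl.fit_pls(X, Y, K=2)
    assert model.varexp_x.sum() == pytest.approx(1.0, abs=1e-8)
    assert model.varexp_y.sum() == pytest.approx(1.0, abs=1e-8)
    assert np.all(model.varexp_x >= 0) and model.varexp_x.sum() <= 1 + 1e-8


def test_duplicate_column_block_is_rank_one(rng):
    col = rng.standard_normal(20)
    col -= col.mean()
    X = np.column_stack([col, col])
    Y = centered(rng, 20, 2)
    model = tl.fit_pls(X, Y, K=1)
    assert model.varexp_x[0] == pytest.approx(1.0, abs=1e-8)


def test_orthogonal_noise_column_excluded_from_varexp(rng):
    """A pure-noise column orthogonal to the mode contributes ~0 to comp-1 varexp."""
    s = centered(rng, 400, 1)[:, 0]
    noise = centered(rng, 400, 1)[:, 0]
    noise -= noise @ s / (s @ s) * s  # exactly orthogonal to the signal
    X = np.column_stack([s, noise])
    X -= X.mean(axis=0)
    Y = (s + 0.01 * centered(rng, 400, 1)[:, 0]).reshape(-1, 1)
    Y -= Y.mean(axis=0)
    model = tl.fit_pls(X, Y, K=1)
    share_signal = (s @ s) / (X * X).sum()
    assert model.varexp_x[0] == pytest.approx(share_signal, abs=0.01)


def test_successive_scores_are_orthogonal(rng):
    X = centered(rng, 40, 5)
    Y = centered(rng, 40, 3)
    model = tl.fit_pls(X, Y, K=3)
    G = model.x_scores.T @ model.x_scores
    off = G - np.diag(np.diag(G))
    assert np.abs(off).max() < 1e-8


def test_sign_convention_and_reproducibility(rng):
    X = centered(rng, 30, 4)
    Y = centered(rng, 30, 2)
    m1 = tl.fit_pls(X, Y, K=2)
    m2 = tl.fit_pls(X.copy(), Y.copy(), K=2)
    for k in range(2):
        assert m1.x_weights[:, k].sum() >= -1e-12
        assert np.linalg.norm(m1.x_weights[:, k]) == pytest.approx(1.0, abs=1e-10)
        assert np.linalg.norm(m1.y_weights[:, k]) == pytest.approx(1.0, abs=1e-10)
    np.testing.assert_array_equal(m1.x_weights, m2.x_weights)


def test_global_sign_flip_equivariance(rng):
    X = centered(rng, 25, 3)
    Y = centered(rng, 25, 2)
    m = tl.fit_pls(X, Y, K=1)
    m_flip = tl.fit_pls(-X, Y, K=1)
    r = abs(np.corrcoef(m.x_scores[:, 0], m.y_scores[:, 0])[0, 1])
    r_flip = abs(np.corrcoef(m_flip.x_scores[:, 0], m_flip.y_scores[:, 0])[0, 1])
    assert r == pytest.approx(r_flip, abs=1e-10)
    np.testing.assert_allclose(np.abs(m_flip.x_weights), np.abs(m.x_weights), atol=1e-8)


def test_agrees_with_sklearn_canonical_pls(rng):
    sklearn_pls = pytest.importorskip("sklearn.cross_decomposition").PLSCanonical
    X = centered(rng, 30, 3)
    Y = centered(rng, 30, 2)
    ours = tl.fit_pls(X, Y, K=2)
    ref = sklearn_pls(n_components=2, scale=False, algorithm="nipals", tol=1e-10).fit(X, Y)
    for k in range(2):
        a = ours.x_weights[:, k]
        b = ref.x_weights_[:, k]
        b = b * np.sign(a @ b)
        np.testing.assert_allclose(a, b, atol=1e-6)


def test_project_matches_training_scores_for_k1(rng):
    X = centered(rng, 15, 3)
    Y = centered(rng, 15, 2)
    model = tl.fit_pls(X, Y, K=1)
    xs, ys = tl.project(model, X, Y)
    np.testing.assert_allclose(xs, model.x_scores, atol=1e-10)
    np.testing.assert_allclose(ys, model.y_scores, atol=1e-10)
    xz, yz = tl.project(model, np.zeros(3), np.zeros(2))
    assert float(xz[0]) == 0.0 and float(yz[0]) == 0.0


def test_project_held_out_equals_manual_dot_product(rng):
    X = centered(rng, 5, 2)
    Y = centered(rng, 5, 1)
    model = tl.fit_pls(X, Y, K=1)
    x_new = np.array([0.3, -0.2])
    y_new = np.array([0.7])
    xs, ys = tl.project(model, x_new, y_new)
    manual_x = x_new[0] * model.x_weights[0, 0] + x_new[1] * model.x_weights[1, 0]
    manual_y = y_new[0] * model.y_weights[0, 0]
    assert float(xs[0]) == pytest.approx(manual_x, abs=1e-10)
    assert float(ys[0]) == pytest.approx(manual_y, abs=1e-10)


def test_variance_explained_accessor(rng):
    X = centered(rng, 20, 3)
    Y = centered(rng, 20, 2)
    model = tl.fit_pls(X, Y, K=2)
    assert tl.variance_explained(model, "x", 1) == pytest.approx(model.varexp_x[0])
    with pytest.raises(TractlinkError):
        tl.variance_explained(model, "x", 3)
    with pytest.raises(TractlinkError):
        tl.variance_explained(model, "z", 1)


@pytest.mark.parametrize(
    "bad_call",
    [
        lambda rng: tl.fit_pls(np.ones((10, 2)), centered(rng, 10, 2)),  # not centered
        lambda rng: tl.fit_pls(
            np.column_stack([centered(rng, 10, 1), np.zeros(10)]), centered(rng, 10, 2)
        ),  # zero-variance column
        lambda rng: tl.fit_pls(centered(rng, 10, 2), centered(rng, 10, 2), K=3),
        lambda rng: tl.fit_pls(centered(rng, 2, 2), centered(rng, 2, 2)),  # n < 3
    ],
)
def test_fit_pls_input_validation(rng, bad_call):
    with pytest.raises(TractlinkError):
        bad_call(rng)


def test_project_dimension_mismatch(rng):
    model = tl.fit_pls(centered(rng, 10, 2), centered(rng, 10, 2), K=1)
    with pytest.raises(TractlinkError, match="mismatch"):
        tl.project(model, np.zeros(3), np.zeros(2))


# ---------------------------------------------------------------------------
# OLS / Ridge comparators
# ---------------------------------------------------------------------------


def test_ridge_zero_penalty_equals_ols(rng):
    X = rng.standard_normal((20, 3))
    y = rng.standard_normal(20)
    ols = tl.fit_ols(X, y)
    ridge = tl.fit_ridge(X, y, 0.0)
    np.testing.assert_allclose(ols.coef, ridge.coef, atol=1e-10)
    assert ols.intercept == pytest.approx(ridge.intercept, abs=1e-10)


def test_ridge_coefficients_shrink_monotonically(rng):
    X = rng.standard_normal((30, 4))
    y = X @ np.array([1.0, -2.0, 0.5, 3.0]) + rng.standard_normal(30)
    norms = [
        np.linalg.norm(tl.fit_ridge(X, y, lam).coef)
        for lam in (0.0, 1.0, 10.0, 100.0, 1e4, 1e8)
    ]
    assert all(a > b for a, b in zip(norms, norms[1:]))
    assert norms[-1] < 1e-3


def test_ols_matches_normal_equations_oracle():
    X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0], [2.0, -1.0]])
    y = np.array([1.0, 2.0, 2.5, 0.5])
    D = np.column_stack([np.ones(4), X])
    beta = np.linalg.inv(D.T @ D) @ D.T @ y  # independent closed form
    link = tl.fit_ols(X, y)
    assert link.intercept == pytest.approx(beta[0], abs=1e-10)
    np.testing.assert_allclose(link.coef, beta[1:], atol=1e-10)
    np.testing.assert_allclose(tl.predict(link, X), D @ beta, atol=1e-10)


def test_singular_ols_suggests_alternatives():
    x = np.arange(6.0)
    X = np.column_stack([x, 2 * x])  # perfectly collinear
    with pytest.raises(SingularMatrixError, match="ridge or PLS"):
        tl.fit_ols(X, np.ones(6))
    tl.fit_ridge(X, np.ones(6), 1.0)  # the regularized variant is fine


def test_negative_penalty_rejected(rng):
    with pytest.raises(TractlinkError):
        tl.fit_ridge(rng.standard_normal((6, 2)), np.ones(6), -1.0)
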