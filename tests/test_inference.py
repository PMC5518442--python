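"""Permutation machinery: exact p-value formulas, FWE properties, calibration."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

import tractlink as tl
from tractlink import inference
from tractlink.errors import SingularMatrixError, TractlinkError
from tractlink.inference import PermutationTest, _add_one_p


def make_test(observed, null, seed=0, sided="greater", family="f"):
    null = np.asarray(null, dtype=float)
    return PermutationTest(
        observed=float(observed),
        B=null.shape[0],
        null_draws=null,
        p_uncorrected=_add_one_p(observed, null, sided),
        p_fwe=None,
        family_id=family,
        seed=seed,
        sided=sided,
    )


def test_add_one_formula_exact_values():
    null = np.linspace(-1, 0.5, 99)
    assert _add_one_p(0.9, null, "greater") == (1 + 0) / 100  # 0.01 exactly
    assert _add_one_p(np.median(null), null, "greater") == pytest.approx(0.5, abs=0.02)
    assert _add_one_p(-2.0, null, "greater") == 1.0
    # two-sided orientation uses magnitudes
    assert _add_one_p(-0.9, null, "two") < _add_one_p(-0.9, null, "greater")


def test_p_values_never_zero():
    null = np.zeros(199)
    p = _add_one_p(10.0, null, "greater")
    assert p == 1 / 200


def test_single_member_family_fwe_equals_uncorrected(rng):
    t = make_test(1.2, rng.standard_normal(499))
    (corrected,) = tl.fwe_correct([t])
    assert corrected.p_fwe == corrected.p_uncorrected


def test_duplicated_statistic_family_fwe_equals_uncorrected(rng):
    null = rng.standard_normal(499)
    t1 = make_test(1.2, null)
    t2 = make_test(1.2, null.copy())
    c1, c2 = tl.fwe_correct([t1, t2])
    assert c1.p_fwe == c1.p_uncorrected
    assert c2.p_fwe == c2.p_uncorrected


def test_independent_family_matches_sidak_limit(rng):
    """For two independent statistics p_fwe ≈ 1 − (1 − p)²."""
    B = 4000
    n1, n2 = rng.standard_normal(B), rng.standard_normal(B)
    obs = float(np.quantile(n1, 0.9))
    t1, t2 = make_test(obs, n1), make_test(obs, n2)
    c1, _ = tl.fwe_correct([t1, t2])
    p = c1.p_uncorrected
    assert c1.p_fwe == pytest.approx(1 - (1 - p) ** 2, abs=0.03)


def test_fwe_monotone_in_family_size(rng):
    tests = [make_test(0.5 + 0.1 * k, rng.standard_normal(999)) for k in range(4)]
    small = tl.fwe_correct(tests[:2])
    large = tl.fwe_correct(tests)
    for s, l in zip(small, large[:2]):
        assert l.p_fwe >= s.p_fwe
    for t in large:
        assert t.p_fwe >= t.p_uncorrected
        assert t.p_fwe >= 1 / 1000


def test_fwe_requires_aligned_families(rng):
    t1 = make_test(1.0, rng.standard_normal(99), seed=0)
    t2 = make_test(1.0, rng.standard_normal(99), seed=1)
    with pytest.raises(TractlinkError, match="share"):
        tl.fwe_correct([t1, t2])


def test_cv_link_test_seed_determinism(cohort43):
    a = tl.perm_test_cv_link(cohort43, tl.TRACT_SETS["arcuate"], ("lang",), B=99, seed=5)
    b = tl.perm_test_cv_link(cohort43, tl.TRACT_SETS["arcuate"], ("lang",), B=99, seed=5)
    assert np.array_equal(a.null_draws, b.null_draws)
    assert a.p_uncorrected == b.p_uncorrected
    c = tl.perm_test_cv_link(cohort43, tl.TRACT_SETS["arcuate"], ("lang",), B=99, seed=6)
    assert not np.array_equal(a.null_draws, c.null_draws)


def test_cv_link_detects_planted_association(cohort43):
    test = tl.perm_test_cv_link(
        cohort43, tl.TRACT_SETS["arcuate"], ("lang",), B=199, seed=5
    )
    assert test.observed > 0.2
    assert test.p_uncorrected <= 0.05


def test_cv_link_rejects_tiny_b(cohort43):
    with pytest.raises(TractlinkError, match="99"):
        tl.perm_test_cv_link(cohort43, tl.TRACT_SETS["arcuate"], ("lang",), B=50)


# ---------------------------------------------------------------------------
# GLM contrasts
# ---------------------------------------------------------------------------


def test_glm_zero_contrast_and_rank_deficiency(rng):
    y = rng.standard_normal(20)
    D = np.column_stack([np.ones(20), rng.standard_normal(20)])
    with pytest.raises(TractlinkError, match="zero"):
        tl.glm_contrast_perm(y, D, (0.0, 0.0), B=99)
    D_bad = np.column_stack([np.ones(20), np.ones(20)])
    with pytest.raises(SingularMatrixError):
        tl.glm_contrast_perm(y, D_bad, (0.0, 1.0), B=99)


def test_glm_t_statistic_matches_ols_theory(rng):
    """Observed t equals the classical OLS t for the same coefficient."""
    n = 40
    x = rng.standard_normal(n)
    z = rng.standard_normal(n)
    y = 0.5 * x + 0.3 * z + rng.standard_normal(n)
    D = np.column_stack([np.ones(n), x, z])
    got = tl.glm_contrast_perm(y, D, (0, 1, 0), B=99, seed=0)
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    sigma2 = resid @ resid / (n - 3)
    se = np.sqrt(sigma2 * np.linalg.inv(D.T @ D)[1, 1])
    assert got.t_statistic == pytest.approx(beta[1] / se, abs=1e-10)


def test_freedman_lane_type_one_error_calibrated(default_config):
    """A zero-slope covariate is rejected at the nominal 5% rate."""
    rng = np.random.default_rng(31)
    rejections = 0
    reps = 200
    for _ in range(reps):
        cohort = tl.generate_cohort(
            dataclasses.replace(default_config, seed=int(rng.integers(2**31)))
        )
        # language is generated independently of PMA at scan
        D = np.column_stack(
            [np.ones(len(cohort)), cohort["pma_scan"], cohort["ga_birth"]]
        )
        t = tl.glm_contrast_perm(
            cohort["lang"].to_numpy(), D, (0, 1, 0), B=199,
            seed=int(rng.integers(2**31)),
        )
        rejections += t.perm.p_uncorrected <= 0.05
    lo, hi = stats.binom.interval(0.95, reps, 0.05)
    assert lo <= rejections <= hi


def test_developmental_glm_grid_detects_maturation(default_config):
    """The planted positive PMA slope survives max-stat FWE in ≥90% of cohorts."""
    rng = np.random.default_rng(41)
    reps = 100
    all_six = 0
    for _ in range(reps):
        cohort = tl.generate_cohort(
            dataclasses.replace(default_config, seed=int(rng.integers(2**31)))
        )
        grid = tl.prematurity_glm_grid(cohort, B=199, seed=int(rng.integers(2**31)))
        pma = grid["pma_adj_ga"]
        all_six += all(t.perm.p_fwe <= 0.05 for t in pma.values())
    assert all_six / reps >= 0.90


def test_glm_grid_shapes_and_family_labels(cohort43):
    grid = tl.prematurity_glm_grid(cohort43, B=99, seed=3)
    assert set(grid) == {"pma_adj_ga", "ga_adj_pma"}
    for tests in grid.values():
        assert len(tests) == 6
        for t in tests.values():
            assert t.perm.p_fwe >= t.perm.p_uncorrected


def test_independent_contribution_glm_flags_fa_scores(cohort43):
    cv = tl.loocv_link(cohort43, tl.TRACT_SETS["arcuate"], ("lang",))
    contrib = tl.independent_contribution_glm(cohort43, cv.x_scores, B=199, seed=9)
    assert set(contrib) == {"pls_fa_score", "ga_birth", "sex", "wm_volume"}
    assert contrib["pls_fa_score"].perm.p_fwe <= 0.2  # planted link dominates


# ---------------------------------------------------------------------------
# partial correlation
# ---------------------------------------------------------------------------


def test_partial_corr_without_covariates_is_plain_correlation(rng):
    a, b = rng.standard_normal(30), rng.standard_normal(30)
    t = tl.partial_corr_perm(a, b, None, B=99, seed=0)
    assert t.observed == pytest.approx(np.corrcoef(a, b)[0, 1], abs=1e-12)


def test_partial_corr_empty_nuisance_reduces_to_simple_permutation(rng):
    """Freedman–Lane with no covariates equals plain permutation of one block."""
    a, b = rng.standard_normal(25), rng.standard_normal(25)
    B, seed = 199, 7
    t = tl.partial_corr_perm(a, b, None, B=B, seed=seed)
    perms = inference.make_permutations(25, B, seed)
    manual = np.array([np.corrcoef(a[p], b)[0, 1] for p in perms])
    np.testing.assert_allclose(np.sort(t.null_draws), np.sort(manual), atol=1e-12)
    np.testing.assert_allclose(t.null_draws, manual, atol=1e-12)


def test_partial_corr_with_covariate_equal_to_b(rng):
    a = rng.standard_normal(40)
    c = rng.standard_normal(40)
    t = tl.partial_corr_perm(a, c, c[:, None], B=99, seed=0)
    assert abs(t.observed) < 1e-10


def test_partial_corr_recovers_known_value(rng):
    """Trivariate normal with true partial correlation 0.4."""
    n = 1000
    c = rng.standard_normal(n)
    L = np.linalg.cholesky(np.array([[1.0, 0.4], [0.4, 1.0]]))
    E = rng.standard_normal((n, 2)) @ L.T
    a = 0.8 * c + E[:, 0]
    b = -0.5 * c + E[:, 1]
    t = tl.partial_corr_perm(a, b, c[:, None], B=99, seed=0)
    assert t.observed == pytest.approx(0.4, abs=0.06)


def test_partial_corr_needs_enough_subjects(rng):
    with pytest.raises(TractlinkError, match="n > q"):
        tl.partial_corr_perm(
            rng.standard_normal(4), rng.standard_normal(4),
            rng.standard_normal((4, 2)), B=99,
        )


# ---------------------------------------------------------------------------
# asymmetry and paired tests
# ---------------------------------------------------------------------------


def test_asymmetry_index_values():
    assert tl.asymmetry_index(0.2, 0.2) == 0.0
    assert tl.asymmetry_index(0.3, 0.1) == pytest.approx(0.5, abs=1e-12)
    with pytest.raises(TractlinkError):
        tl.asymmetry_index(0.1, -0.1)


def test_asymmetry_index_antisymmetry(rng):
    l = rng.uniform(0.05, 0.6, 100)
    r = rng.uniform(0.05, 0.6, 100)
    np.testing.assert_allclose(
        tl.asymmetry_index(l, r), -tl.asymmetry_index(r, l), atol=1e-15
    )
    assert np.all(np.abs(tl.asymmetry_index(l, r)) < 1)


def test_signed_rank_error_paths(rng):
    x = rng.standard_normal(10)
    with pytest.raises(TractlinkError):
        tl.paired_signed_rank(x, x)  # all differences zero
    with pytest.raises(TractlinkError, match="n ≥ 5"):
        tl.paired_signed_rank(x[:3], x[:3])


def test_signed_rank_detects_constant_shift(rng):
    x = rng.standard_normal(20)
    z, p = tl.paired_signed_rank(x + 5.0, x)
    assert abs(z) > 3 and p < 1e-3


def test_signed_rank_matches_exact_enumeration(rng):
    """Normal-approximation p within 0.02 of the exact 2^n sign-flip null."""
    n = 12
    d = rng.standard_normal(n)
    left = rng.standard_normal(n)
    right = left - d
    _, p_approx = tl.paired_signed_rank(left, right)

    ranks = stats.rankdata(np.abs(d))
    t_obs = ranks[d > 0].sum()
    signs = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
    t_all = signs @ ranks
    p_lo = np.mean(t_all <= t_obs)
    p_hi = np.mean(t_all >= t_obs)
    p_exact = min(1.0, 2 * min(p_lo, p_hi))
    assert p_approx == pytest.approx(p_exact, abs=0.02)
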