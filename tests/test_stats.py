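import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gradpain.errors import DataError, NumericalError
from gradpain.stats import (
    partial_r2,
    per_coefficient_association,
    permutation_test,
    quintile_gradient_curves,
    sex_comparison,
)


def _cohort(rng, n=40, p=4, q=2):
    X = rng.standard_normal((n, p))
    Z = rng.standard_normal((n, q))
    return X, Z


# --- partial R² --------------------------------------------------------------


def test_partial_r2_zero_when_outcome_orthogonal_to_predictors(rng):
    X, Z = _cohort(rng)
    n = X.shape[0]
    # residualize a random y against (1, Z, X) so nothing is left to explain
    D = np.column_stack([np.ones(n), Z, X])
    y = rng.standard_normal(n)
    y = y - D @ np.linalg.lstsq(D, y, rcond=None)[0]
    y_for_x = y + np.column_stack([np.ones(n), Z]) @ rng.standard_normal(3)
    assert partial_r2(y_for_x, X, Z) <= 1e-10


def test_partial_r2_matches_two_explicit_ols_fits(rng):
    X, Z = _cohort(rng)
    n = X.shape[0]
    y = X @ rng.standard_normal(4) + Z @ rng.standard_normal(2) + rng.standard_normal(n)
    red = np.column_stack([np.ones(n), Z])
    full = np.column_stack([red, X])
    rss = lambda D: np.sum((y - D @ np.linalg.lstsq(D, y, rcond=None)[0]) ** 2)
    expected = (rss(red) - rss(full)) / rss(red)
    assert partial_r2(y, X, Z) == pytest.approx(expected, abs=1e-10)


def test_partial_r2_zero_when_nuisance_contains_predictors(rng):
    X, _ = _cohort(rng)
    y = X @ np.arange(1.0, 5.0) + 0.1 * rng.standard_normal(40)
    assert partial_r2(y, X, Z=X) <= 1e-10


def test_partial_r2_too_many_columns_rejected(rng):
    with pytest.raises(NumericalError, match="condition number"):
        partial_r2(rng.standard_normal(10), rng.standard_normal((10, 9)), rng.standard_normal((10, 3)))


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 10_000))
def test_partial_r2_bounds_and_monotone_in_predictors_fuzz(seed):
    rng = np.random.default_rng(seed)
    n = 25
    X = rng.standard_normal((n, 3))
    Z = rng.standard_normal((n, 2))
    y = rng.standard_normal(n)
    r2 = partial_r2(y, X, Z)
    assert 0.0 <= r2 <= 1.0
    extra = np.column_stack([X, rng.standard_normal(n)])
    assert partial_r2(y, extra, Z) >= r2 - 1e-12


# --- permutation test --------------------------------------------------------


def test_exhaustive_enumeration_at_tiny_n(rng):
    """Requesting 120+ Monte-Carlo permutations at n=5 enumerates all 5!
    permutations; the null set equals an explicit enumeration oracle."""
    n = 5
    y = rng.standard_normal(n)
    X = rng.standard_normal((n, 1))
    res = permutation_test(y, X, None, n_perm=120, seed=0)
    assert res.exhaustive and res.n_perm == 120

    nulls = []
    red = np.ones((n, 1))
    H = red @ np.linalg.pinv(red)
    resid = y - H @ y
    for perm in itertools.permutations(range(n)):
        ystar = H @ y + resid[list(perm)]
        nulls.append(partial_r2(ystar, X, None))
    np.testing.assert_allclose(np.sort(res.null), np.sort(nulls), atol=1e-12)


def test_permutation_reproducible_given_seed(rng):
    y = rng.standard_normal(30)
    X = rng.standard_normal((30, 3))
    Z = rng.standard_normal((30, 2))
    a = permutation_test(y, X, Z, n_perm=300, seed=42)
    b = permutation_test(y, X, Z, n_perm=300, seed=42)
    np.testing.assert_array_equal(a.null, b.null)
    assert a.p_value == b.p_value


def test_p_value_formula_and_range(rng):
    y = rng.standard_normal(25)
    X = rng.standard_normal((25, 2))
    res = permutation_test(y, X, None, n_perm=200, seed=7)
    expected = (1 + np.sum(res.null >= res.observed)) / (1 + res.n_perm)
    assert res.p_value == pytest.approx(expected)
    assert 0 < res.p_value <= 1


def test_null_calibration_quick():
    """On independent y, X, Z the rejection rate at alpha=0.05 stays near
    0.05 (loose band; the full-size calibration runs in the acceptance
    suite)."""
    rej = 0
    reps = 100
    for rep in range(reps):
        r = np.random.default_rng(rep)
        y = r.standard_normal(30)
        X = r.standard_normal((30, 3))
        Z = r.standard_normal((30, 2))
        rej += permutation_test(y, X, Z, n_perm=150, seed=rep).p_value <= 0.05
    assert 0.01 <= rej / reps <= 0.12


def test_min_permutations_enforced(rng):
    with pytest.raises(DataError, match="at least 100"):
        permutation_test(rng.standard_normal(20), rng.standard_normal((20, 2)), None, n_perm=10)


# --- per-parameter associations ----------------------------------------------


def test_single_driving_parameter_identified(rng):
    X, Z = _cohort(rng, n=50, p=5)
    y = X[:, 2] * 2.0  # noiseless, parameter 2 only
    out = per_coefficient_association(y, X, Z, n_perm=200, seed=0)
    assert abs(out.loc[2, "partial_r"]) > 0.95
    assert (out.drop(index=2)["partial_r"].abs() < 0.5).all()
    assert out.loc[2, "p_raw"] < 0.05


def test_null_parameters_give_spread_p_values(rng):
    X, Z = _cohort(rng, n=60, p=6)
    y = rng.standard_normal(60)
    out = per_coefficient_association(y, X, Z, n_perm=200, seed=1)
    assert (out["p_raw"] > 0.01).sum() >= 5  # no spurious blanket significance


def test_constant_parameter_column_rejected(rng):
    X, Z = _cohort(rng)
    X[:, 1] = 3.0
    with pytest.raises(DataError, match=r"column\(s\).*1"):
        per_coefficient_association(rng.standard_normal(40), X, Z)


# --- sex comparison ----------------------------------------------------------


def test_identical_groups_are_not_significant(rng):
    X = np.vstack([np.arange(10.0)] * 2).T  # 10 subjects, 2 parameters
    X = np.tile(np.arange(10.0)[:, None], (1, 3))
    sex = np.array(["M", "F"] * 5)
    out = sex_comparison(X, sex)
    assert (out["p_bonferroni"] == 1.0).all()


def test_tiny_case_exact_u_and_p():
    """3 vs 3 with all group-A values larger: U = 9, exact two-sided
    p = 2/20 = 0.1 (enumeration of the 20 arrangements)."""
    X = np.array([[10.0], [11.0], [12.0], [1.0], [2.0], [3.0]])
    sex = np.array(["A", "A", "A", "B", "B", "B"])
    out = sex_comparison(X, sex)
    assert out.loc[0, "U"] == 9.0
    assert out.loc[0, "p_raw"] == pytest.approx(0.1)


def test_shifted_groups_significant_after_bonferroni(rng):
    hits = 0
    for rep in range(10):
        r = np.random.default_rng(rep)
        X = np.column_stack([np.concatenate([r.standard_normal(50), r.standard_normal(50) + 2.0]) for _ in range(9)])
        sex = np.array(["M"] * 50 + ["F"] * 50)
        out = sex_comparison(X, sex)
        hits += (out["p_bonferroni"] < 0.05).all()
    assert hits >= 8


def test_empty_group_rejected(rng):
    with pytest.raises(DataError):
        sex_comparison(rng.standard_normal((6, 2)), np.array(["M"] * 6))


# --- quintile curves ---------------------------------------------------------


def test_identical_connectopies_give_coinciding_tight_curves(rng):
    n_subj, n_vox = 30, 60
    base = np.linspace(0, 1, n_vox)
    C = np.tile(base, (n_subj, 1))
    comp = rng.standard_normal(n_subj)
    out = quintile_gradient_curves(C, comp, np.arange(n_vox, dtype=float), n_bins=6, n_boot=200, seed=0)
    np.testing.assert_allclose(out["low"]["curve"], out["high"]["curve"], atol=1e-12)
    assert np.max(out["low"]["ci_high"] - out["low"]["ci_low"]) < 1e-12


def test_curves_separate_for_different_gradient_shapes(rng):
    """Subjects with g vs g² layouts separate in mid positions when scores
    track the layout."""
    n_vox = 80
    pos = np.linspace(0, 1, n_vox)
    subjects, scores = [], []
    for i in range(30):
        curved = i < 15
        subjects.append((pos**2 if curved else pos) + 0.01 * rng.standard_normal(n_vox))
        scores.append((-1.0 if curved else 1.0) + 0.05 * rng.standard_normal())
    out = quintile_gradient_curves(np.array(subjects), np.array(scores), pos, n_bins=8, n_boot=200, seed=0)
    mid = slice(2, 6)
    assert np.all(np.abs(out["high"]["curve"][mid] - out["low"]["curve"][mid]) > 0.05)


def test_single_bin_returns_group_means(rng):
    C = rng.random((30, 20))
    comp = rng.standard_normal(30)
    out = quintile_gradient_curves(C, comp, np.arange(20.0), n_bins=1, n_boot=50, seed=0)
    lo_cut, hi_cut = np.percentile(comp, [20, 80])
    np.testing.assert_allclose(out["low"]["curve"], [C[comp < lo_cut].mean()], atol=1e-12)
    np.testing.assert_allclose(out["high"]["curve"], [C[comp > hi_cut].mean()], atol=1e-12)


def test_too_many_bins_rejected(rng):
    with pytest.raises(DataError, match="exceeds ROI extent"):
        quintile_gradient_curves(rng.random((30, 10)), rng.standard_normal(30), np.arange(10.0), n_bins=11)
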