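from itertools import combinations
from math import comb

import numpy as np
import pytest
import scipy.stats as sstats
from hypothesis import given, settings
from hypothesis import strategies as st

import emwater as ew
from emwater.ranktests import (
    spearman_p,
    tie_corrected_sigma,
)

from conftest import make_dataset


def brute_force_u_distribution(x, y):
    """Oracle: U statistic for every split of the pooled values."""
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    ranks = sstats.rankdata(pooled)
    out = []
    for idx in combinations(range(n), n1):
        r1 = ranks[list(idx)].sum()
        out.append(r1 - n1 * (n1 + 1) / 2.0)
    return np.array(out)


def test_identical_groups_give_central_u():
    res = ew.mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
    assert res.U == res.n1 * res.n2 / 2 == 8
    assert res.z == 0.0
    assert res.p == 1.0


def test_separated_groups_exact_enumeration():
    res = ew.mann_whitney_u([1, 2], [3, 4])
    assert res.U == 0.0
    # oracle: 2 of the C(4,2)=6 splits are as extreme
    assert res.exact_p == pytest.approx(2 / 6)


def test_tied_case_matches_brute_force_oracle():
    x, y = np.array([1.0, 2, 3]), np.array([2.0, 3, 4])
    res = ew.mann_whitney_u(x, y)
    dist = brute_force_u_distribution(x, y)
    mu = res.n1 * res.n2 / 2.0
    # sigma from the enumerated permutation distribution
    assert tie_corrected_sigma(3, 3, res.tie_groups) == pytest.approx(
        dist.std(ddof=0)
    )
    expected_p = np.mean(np.abs(dist - mu) >= abs(res.U - mu) - 1e-9)
    assert res.exact_p == pytest.approx(expected_p)
    assert res.tie_groups == (2, 2)


def test_matches_scipy_asymptotic():
    """Independent cross-check of U and the tie-corrected normal p."""
    rng = np.random.default_rng(4)
    for _ in range(25):
        x = rng.integers(0, 12, size=15).astype(float)
        y = rng.integers(0, 12, size=9).astype(float) + rng.integers(0, 3)
        res = ew.mann_whitney_u(x, y, exact_max_group=0)
        ref = sstats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic",
            use_continuity=False,
        )
        # scipy's statistic counts pairs where x exceeds y, like ours
        assert res.U == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)


def test_exact_matches_scipy_exact_when_no_ties():
    rng = np.random.default_rng(8)
    for _ in range(5):
        pooled = rng.permutation(16).astype(float)
        x, y = pooled[:8], pooled[8:]
        res = ew.mann_whitney_u(x, y)
        ref = sstats.mannwhitneyu(x, y, alternative="two-sided",
                                  method="exact")
        assert res.exact_p == pytest.approx(ref.pvalue, rel=1e-9)


def test_exact_and_normal_p_agree_for_small_balanced_groups():
    rng = np.random.default_rng(12)
    for _ in range(20):
        pooled = rng.normal(size=16)
        x, y = pooled[:8] + rng.normal() * 0.5, pooled[8:]
        res = ew.mann_whitney_u(x, y)
        assert abs(res.exact_p - res.p) < 0.05


def test_degenerate_all_tied_raises():
    with pytest.raises(ew.DegenerateTestError):
        ew.mann_whitney_u([3.0, 3.0], [3.0, 3.0, 3.0])


@given(
    st.lists(st.integers(0, 40), min_size=2, max_size=12),
    st.lists(st.integers(0, 40), min_size=2, max_size=12),
)
@settings(deadline=None, max_examples=60)
def test_label_swap_antisymmetry(xs, ys):
    x, y = np.array(xs, float), np.array(ys, float)
    if np.unique(np.concatenate([x, y])).size < 2:
        return  # degenerate by construction
    a = ew.mann_whitney_u(x, y, exact_max_group=0)
    b = ew.mann_whitney_u(y, x, exact_max_group=0)
    assert a.U + b.U == pytest.approx(a.n1 * a.n2)
    assert a.z == pytest.approx(-b.z)
    assert a.p == pytest.approx(b.p)


@given(
    st.lists(st.integers(1, 500), min_size=3, max_size=10),
    st.lists(st.integers(1, 500), min_size=3, max_size=10),
)
@settings(deadline=None, max_examples=40)
def test_monotone_transform_invariance(xs, ys):
    # cube and log are strictly monotone and exact on these integers, so
    # the tie pattern is preserved and the test must be unchanged
    x, y = np.array(xs, float), np.array(ys, float)
    if np.unique(np.concatenate([x, y])).size < 2:
        return
    a = ew.mann_whitney_u(x, y, exact_max_group=0)
    for transform in (lambda v: v**3, np.log):
        b = ew.mann_whitney_u(transform(x), transform(y), exact_max_group=0)
        assert a.U == pytest.approx(b.U)
        assert a.z == pytest.approx(b.z)


def test_continuity_correction_shrinks_z():
    x, y = [1.0, 2, 3, 10], [4.0, 5, 6, 7]
    plain = ew.mann_whitney_u(x, y)
    corrected = ew.mann_whitney_u(x, y, continuity=True)
    assert abs(corrected.z) < abs(plain.z)


def test_period_rank_tests_sign_convention(sim_dataset):
    """A strong reduction after treatment yields a negative z."""
    ds, _ = ew.exclude_constant_parameters(sim_dataset)
    tests = ew.period_rank_tests(ds)
    assert tests.loc["HBN22", "z"] < 0  # counts fell sharply
    assert tests.loc["FEN", "z"] > 0  # enterococci rose
    assert ((tests["U"] >= 0) & (tests["U"] <= 126 * 36 / 2)).all()


# -- Spearman -------------------------------------------------------------


def test_spearman_monotone_pairs():
    x = np.arange(1.0, 9.0)
    assert ew.spearman_rho(x, np.exp(x)) == pytest.approx(1.0)
    assert ew.spearman_rho(x, -(x**3)) == pytest.approx(-1.0)


def test_spearman_five_point_example():
    # oracle: 1 - 6 * sum(d^2) / (m (m^2 - 1)) with d^2 sum = 4 -> 0.8
    rho = ew.spearman_rho([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
    assert rho == pytest.approx(1 - 6 * 4 / (5 * 24))
    assert rho == pytest.approx(0.8)


def test_spearman_matches_scipy_with_ties():
    rng = np.random.default_rng(3)
    for _ in range(10):
        x = rng.integers(0, 6, 30).astype(float)
        y = x + rng.integers(0, 6, 30)
        ref_rho, ref_p = sstats.spearmanr(x, y)
        assert ew.spearman_rho(x, y) == pytest.approx(ref_rho)
        assert spearman_p(ew.spearman_rho(x, y), 30) == pytest.approx(
            ref_p, rel=1e-6
        )


@given(st.lists(st.integers(1, 500), min_size=4, max_size=20))
@settings(deadline=None, max_examples=40)
def test_spearman_monotone_invariance(xs):
    x = np.array(xs, float)
    rng = np.random.default_rng(0)
    y = rng.permutation(x)
    if np.unique(x).size < 2:
        return
    assert ew.spearman_rho(x, y) == pytest.approx(
        ew.spearman_rho(np.log(x), y)
    )
    assert ew.spearman_rho(x, y) == pytest.approx(
        ew.spearman_rho(x, y**3)
    )


def test_spearman_matrix_structure(sim_dataset):
    ds, _ = ew.exclude_constant_parameters(sim_dataset)
    corr = ew.spearman_matrix(ds)
    rho = corr.rho
    assert np.allclose(rho.values, rho.values.T, equal_nan=True)
    assert np.allclose(np.diag(rho.values), 1.0)
    assert ((rho.abs() <= 1) | rho.isna()).all().all()
    assert corr.significant.equals(corr.p <= 0.05)


def test_spearman_matrix_constant_column_absent():
    recs = []
    for rep in (1, 2, 3):
        for date in ("2021-08-09", "2021-08-16"):
            recs.append((date, 1, 30, rep, "PH", 7.0))
            recs.append((date, 1, 30, rep, "TP", 0.1 * rep))
            recs.append((date, 1, 30, rep, "TN", 0.2 * rep + 1))
    ds = make_dataset(recs)
    corr = ew.spearman_matrix(ds)
    assert np.isnan(corr.rho.loc["PH", "TP"])
    assert corr.rho.loc["TN", "TP"] == pytest.approx(1.0)
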