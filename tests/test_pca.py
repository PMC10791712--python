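import numpy as np
import pandas as pd
import pytest

import emwater as ew
from emwater.pca import pca_correlation


def random_wide(n=60, p=14, seed=2, corr=True):
    rng = np.random.default_rng(seed)
    if corr:
        base = rng.normal(size=(n, 3))
        mix = rng.normal(size=(3, p))
        X = base @ mix + rng.normal(size=(n, p))
    else:
        X = rng.normal(size=(n, p))
    return pd.DataFrame(X, columns=[f"v{i}" for i in range(p)])


def test_two_perfectly_correlated_variables():
    x = np.linspace(0, 1, 40)
    wide = pd.DataFrame({"a": x, "b": 2 * x + 1})
    res = pca_correlation(wide)
    assert res.eigenvalues[0] == pytest.approx(2.0)
    assert res.eigenvalues[1] == pytest.approx(0.0, abs=1e-12)
    assert res.explained_pct[0] == pytest.approx(100.0)
    assert res.n_retained == 1


def test_exactly_uncorrelated_design_retains_nothing():
    """Columns built orthogonal give an identity correlation matrix; the
    Kaiser rule (> 1 strictly) then retains no component."""
    t = np.arange(16)
    wide = pd.DataFrame(
        {
            "a": np.cos(2 * np.pi * t / 16),
            "b": np.sin(2 * np.pi * t / 16),
            "c": np.cos(4 * np.pi * t / 16),
        }
    )
    res = pca_correlation(wide)
    assert np.allclose(res.eigenvalues, 1.0, atol=1e-10)
    assert res.n_retained == 0


def test_block_design_eigenvalues():
    """Two independent blocks of two variables correlated ~0.9 give
    eigenvalues near 1 +/- 0.9 and two retained components ~47.5% each."""
    rng = np.random.default_rng(7)
    n = 4000
    z1, z2 = rng.normal(size=n), rng.normal(size=n)
    noise = np.sqrt(1 / 0.9 - 1)  # corr(z + ne, z + ne') = 1/(1+n^2) = 0.9
    wide = pd.DataFrame(
        {
            "a1": z1 + noise * rng.normal(size=n),
            "a2": z1 + noise * rng.normal(size=n),
            "b1": z2 + noise * rng.normal(size=n),
            "b2": z2 + noise * rng.normal(size=n),
        }
    )
    res = pca_correlation(wide)
    assert res.n_retained == 2
    assert res.eigenvalues[0] == pytest.approx(1.9, abs=0.05)
    assert res.eigenvalues[1] == pytest.approx(1.9, abs=0.05)
    assert res.explained_pct[0] == pytest.approx(47.5, abs=1.5)
    assert res.explained_pct[1] == pytest.approx(47.5, abs=1.5)


def test_reconstruction_and_communality_invariants():
    """All-component loadings reproduce the correlation matrix and their
    squared row sums total the number of variables."""
    wide = random_wide()
    res = pca_correlation(wide)
    R = np.corrcoef(
        (wide - wide.mean()) / wide.std(ddof=1), rowvar=False
    )
    L = res.loadings.to_numpy()
    assert np.allclose(L @ L.T, R, atol=1e-8)
    assert (L**2).sum() == pytest.approx(len(res.parameters), abs=1e-8)
    assert np.all(res.communalities.to_numpy() <= 1.0 + 1e-9)
    assert np.all(res.communalities.to_numpy() >= 0.0)
    assert np.all(np.diff(res.eigenvalues) <= 1e-12)
    assert res.eigenvalues.sum() == pytest.approx(len(res.parameters))


def test_sign_convention_deterministic():
    wide = random_wide(seed=5)
    a = pca_correlation(wide)
    b = pca_correlation(wide)
    pd.testing.assert_frame_equal(a.loadings, b.loadings)
    for j in range(len(a.parameters)):
        col = a.loadings.iloc[:, j].to_numpy()
        assert col[np.argmax(np.abs(col))] >= 0


def test_constant_column_excluded_with_warning(caplog):
    wide = random_wide(p=4)
    wide["flat"] = 3.0
    with caplog.at_level("WARNING"):
        res = pca_correlation(wide)
    assert "flat" in res.excluded
    assert "flat" not in res.parameters


def test_too_few_usable_columns():
    wide = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [5.0, 5, 5, 5]})
    with pytest.raises(ew.ValidationError):
        pca_correlation(wide)


def test_correlated_counts_load_together_on_pc1():
    """With correlated microbiological counts and independent chemistry,
    the counts dominate the first component."""
    rng = np.random.default_rng(13)
    n = 162
    shared = rng.normal(size=n)
    wide = {}
    for code in ew.MICROBIOLOGICAL_COUNTS:
        wide[code] = np.exp(1.0 * shared + 0.5 * rng.normal(size=n))
    for code in ("PH", "EC", "TN", "TP"):
        wide[code] = rng.normal(10, 1, size=n)
    res = pca_correlation(pd.DataFrame(wide))
    pc1 = res.loadings["PC1"]
    micro = pc1[list(ew.MICROBIOLOGICAL_COUNTS)].abs()
    chem = pc1[["PH", "EC", "TN", "TP"]].abs()
    assert micro.min() > chem.max()


# -- KMO -------------------------------------------------------------------


@pytest.mark.parametrize("r", [0.9, 0.3, -0.6, 0.05])
def test_kmo_two_by_two_is_half(r):
    R = np.array([[1.0, r], [r, 1.0]])
    assert ew.kmo(R) == pytest.approx(0.5)


def test_kmo_identity_is_error():
    with pytest.raises(ew.ValidationError):
        ew.kmo(np.eye(3))


def test_kmo_three_by_three_against_partial_correlation_oracle():
    R = np.array(
        [
            [1.0, 0.5, 0.3],
            [0.5, 1.0, 0.4],
            [0.3, 0.4, 1.0],
        ]
    )

    def partial(i, j, k):
        return (R[i, j] - R[i, k] * R[j, k]) / np.sqrt(
            (1 - R[i, k] ** 2) * (1 - R[j, k] ** 2)
        )

    r2 = sum(R[i, j] ** 2 for i in range(3) for j in range(3) if i != j)
    q2 = sum(
        partial(i, j, 3 - i - j) ** 2
        for i in range(3)
        for j in range(3)
        if i != j
    )
    assert ew.kmo(R) == pytest.approx(r2 / (r2 + q2))


def test_kmo_singular_matrix():
    R = np.array([[1.0, 1.0], [1.0, 1.0]])
    with pytest.raises(ew.ValidationError):
        ew.kmo(R)


# -- Bartlett ----------------------------------------------------------------


def test_bartlett_identity():
    chi2, df, p = ew.bartlett_sphericity(np.eye(4), n=30)
    assert chi2 == 0.0
    assert df == 6
    assert p == pytest.approx(1.0)


def test_bartlett_two_by_two_arithmetic():
    r, n = 0.9, 50
    chi2, df, p = ew.bartlett_sphericity(
        np.array([[1.0, r], [r, 1.0]]), n=n
    )
    # |R| = 1 - r^2 = 0.19; chi2 = -(n - 1 - (2p+5)/6) ln|R|
    assert chi2 == pytest.approx(-(n - 1 - 9 / 6) * np.log(0.19))
    assert df == 1
    assert p < 1e-6


def test_bartlett_monotone_in_correlation():
    chis = []
    for r in (0.1, 0.4, 0.7, 0.9):
        chi2, _, _ = ew.bartlett_sphericity(
            np.array([[1.0, r], [r, 1.0]]), n=40
        )
        chis.append(chi2)
    assert chis == sorted(chis)


def test_bartlett_requires_enough_observations():
    with pytest.raises(ew.ValidationError):
        ew.bartlett_sphericity(np.eye(5), n=5)


def test_pca_on_synthetic_dataset(sim_dataset):
    ds, _ = ew.exclude_constant_parameters(sim_dataset)
    res = ew.pca(ds)
    assert res.n_observations == 162
    assert len(res.parameters) == 14
    assert res.eigenvalues.sum() == pytest.approx(14.0)
    assert 0.0 < res.kmo < 1.0
    assert res.bartlett_df == 14 * 13 // 2
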