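"""Nonparametric inference: tie-corrected Mann-Whitney U and Spearman rank
correlation, implemented from first principles.

These are the study's inferential workhorses: water-quality measurements
are skewed and heteroscedastic, so period comparisons use the rank-sum test
and associations use rank correlation.  The implementations here are
deliberately explicit — midrank assignment, the tie-corrected normal
approximation, and (for small samples) the exact permutation null — so each
piece can be verified independently against enumeration oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as _sstats
from scipy.stats import rankdata

from .dataset import MonitoringDataset
from .errors import DegenerateTestError, ValidationError

EXACT_MAX_GROUP = 8  # exact enumeration when the smaller group is this size
STRONG_RHO = 0.70  # conventional "strong correlation" annotation threshold


@dataclass(frozen=True)
class RankTestResult:
    """Mann-Whitney U for the first group, with tie-aware z and p.

    ``U`` counts pairs in which the first-group value exceeds the second
    (ties counted half), i.e. U = R1 - n1(n1+1)/2 with midranks.  ``z`` is
    the tie-corrected normal deviate of U; ``p`` its two-sided tail.  For
    small groups ``exact_p`` is the two-sided tail of the exact permutation
    distribution of U given the observed (tied) pooled values.
    """

    U: float
    z: float
    p: float
    n1: int
    n2: int
    tie_groups: tuple[int, ...]
    alpha: float = 0.05
    exact_p: float | None = None

    @property
    def significant(self) -> bool:
        return self.p <= self.alpha

    @property
    def U_complement(self) -> float:
        return self.n1 * self.n2 - self.U


def _u_from_ranks(ranks1: np.ndarray, n1: int) -> float:
    return float(ranks1.sum() - n1 * (n1 + 1) / 2.0)


def _tie_groups(pooled: np.ndarray) -> tuple[int, ...]:
    _, counts = np.unique(pooled, return_counts=True)
    return tuple(int(c) for c in counts if c > 1)


def tie_corrected_sigma(n1: int, n2: int, tie_groups) -> float:
    """SD of U under H0 with the tie correction.

    sigma^2 = (n1 n2 / 12) * [(n + 1) - sum(t^3 - t) / (n (n - 1))]
    """
    n = n1 + n2
    tie_term = sum(t**3 - t for t in tie_groups)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    return float(np.sqrt(max(var, 0.0)))


def exact_mann_whitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact p by enumerating all group assignments.

    Enumerates every C(n, n1) split of the pooled (possibly tied) values,
    computes U for each, and returns P(|U - n1 n2 / 2| >= |u_obs - n1 n2 /2|)
    under the uniform permutation null.
    """
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    ranks = rankdata(pooled)
    u_obs = _u_from_ranks(ranks[:n1], n1)
    mu = n1 * (n - n1) / 2.0
    dev = abs(u_obs - mu) - 1e-9
    hits = 0
    for idx in combinations(range(n), n1):
        u = _u_from_ranks(ranks[list(idx)], n1)
        if abs(u - mu) >= dev:
            hits += 1
    return hits / comb(n, n1)


def mann_whitney_u(
    x,
    y,
    alpha: float = 0.05,
    continuity: bool = False,
    exact_max_group: int = EXACT_MAX_GROUP,
) -> RankTestResult:
    """Tie-corrected Mann-Whitney U test of two independent samples.

    ``U`` is computed for ``x`` (the first group); swapping the groups maps
    U to n1*n2 - U and flips the sign of z.  The two-sided p comes from the
    normal approximation with the tie correction; when the smaller group
    has at most ``exact_max_group`` members the exact enumeration p is also
    computed and reported in ``exact_p``.

    ``continuity`` applies the 0.5 continuity correction toward the null
    mean (off by default).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValidationError("both groups need at least one value")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u = _u_from_ranks(ranks[:n1], n1)
    ties = _tie_groups(pooled)
    sigma = tie_corrected_sigma(n1, n2, ties)
    if sigma == 0.0:
        raise DegenerateTestError(
            "all values tied across both groups; rank test undefined"
        )
    dev = u - n1 * n2 / 2.0
    if continuity and dev != 0:
        dev -= np.sign(dev) * 0.5
    z = dev / sigma
    p = min(1.0, 2.0 * _sstats.norm.sf(abs(z)))
    exact_p = None
    if min(n1, n2) <= exact_max_group:
        exact_p = exact_mann_whitney_p(x, y)
    return RankTestResult(
        U=u, z=float(z), p=float(p), n1=n1, n2=n2, tie_groups=ties,
        alpha=alpha, exact_p=exact_p,
    )


def period_rank_tests(
    ds: MonitoringDataset, alpha: float = 0.05
) -> pd.DataFrame:
    """Mann-Whitney before-vs-after per parameter.

    z is computed on the after-group U, so a reduction after the treatment
    (after values ranking low) yields a negative z.  Returns one row per
    parameter: U (smaller of the two complementary statistics, the usual
    reporting convention), z, p, significant.
    """
    rows = []
    for code in sorted(ds.frame["parameter"].unique()):
        before = ds.values(code, period="before")
        after = ds.values(code, period="after")
        try:
            res = mann_whitney_u(after, before, alpha=alpha)
        except DegenerateTestError:
            rows.append((code, np.nan, np.nan, np.nan, False))
            continue
        rows.append(
            (
                code,
                min(res.U, res.U_complement),
                res.z,
                res.p,
                res.significant,
            )
        )
    return pd.DataFrame(
        rows, columns=["parameter", "U", "z", "p", "significant"]
    ).set_index("parameter")


# -- Spearman ------------------------------------------------------------


def spearman_rho(x, y) -> float:
    """Spearman rho as the Pearson correlation of midranks."""
    rx = rankdata(np.asarray(x, dtype=float))
    ry = rankdata(np.asarray(y, dtype=float))
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return np.nan
    return float((rx * ry).sum() / denom)


def spearman_p(rho: float, m: int) -> float:
    """Two-sided p for Spearman rho via the t approximation (df = m - 2)."""
    if m < 3 or not np.isfinite(rho):
        return np.nan
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((m - 2) / (1.0 - rho**2))
    return float(2.0 * _sstats.t.sf(abs(t), df=m - 2))


@dataclass
class CorrelationMatrix:
    """Pairwise Spearman correlations with significance annotations."""

    parameters: tuple[str, ...]
    rho: pd.DataFrame
    p: pd.DataFrame
    alpha: float = 0.05
    strong_threshold: float = STRONG_RHO

    @property
    def significant(self) -> pd.DataFrame:
        return self.p <= self.alpha

    @property
    def strong(self) -> pd.DataFrame:
        """Strong-correlation annotation (|rho| >= threshold); not a filter."""
        return self.rho.abs() >= self.strong_threshold

    def strong_pairs(self) -> list[tuple[str, str, float]]:
        out = []
        for i, a in enumerate(self.parameters):
            for b in self.parameters[i + 1:]:
                r = self.rho.loc[a, b]
                if np.isfinite(r) and abs(r) >= self.strong_threshold and \
                        self.p.loc[a, b] <= self.alpha:
                    out.append((a, b, float(r)))
        return out


def spearman_matrix(
    ds: MonitoringDataset, alpha: float = 0.05
) -> CorrelationMatrix:
    """Spearman correlation matrix over parameters.

    Observations are matched on (date, site, depth, replicate); each pair
    uses its complete cases.  Constant columns give undefined (NaN) entries.
    """
    wide = ds.frame.pivot_table(
        index=["date", "site", "depth_cm", "replicate"],
        columns="parameter",
        values="value",
    )
    params = tuple(sorted(wide.columns))
    k = len(params)
    rho = np.full((k, k), np.nan)
    pmat = np.full((k, k), np.nan)
    for i in range(k):
        rho[i, i] = 1.0
        pmat[i, i] = 0.0
        for j in range(i + 1, k):
            pair = wide[[params[i], params[j]]].dropna()
            if len(pair) < 3:
                continue
            xi = pair.iloc[:, 0].to_numpy()
            yj = pair.iloc[:, 1].to_numpy()
            if np.unique(xi).size < 2 or np.unique(yj).size < 2:
                continue  # constant column: rho undefined, left absent
            r = spearman_rho(xi, yj)
            rho[i, j] = rho[j, i] = r
            pmat[i, j] = pmat[j, i] = spearman_p(r, len(pair))
    return CorrelationMatrix(
        parameters=params,
        rho=pd.DataFrame(rho, index=params, columns=params),
        p=pd.DataFrame(pmat, index=params, columns=params),
        alpha=alpha,
    )
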