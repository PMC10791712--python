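"""Correlation-matrix PCA with factorability diagnostics (KMO, Bartlett).

The multivariate stage asks which water-quality parameters co-vary: the
observation unit is one replicate determination event (date, site, depth,
replicate), variables are the parameters, and the analysis is a principal
component analysis of the correlation matrix (variables standardized, no
rotation).  Component retention follows the Kaiser rule (eigenvalue
strictly greater than 1).  Two standard factorability diagnostics
accompany it:

* the Kaiser-Meyer-Olkin measure of sampling adequacy,
  KMO = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2) over i != j, where q_ij are
  the anti-image partial correlations obtained from the scaled inverse of
  the correlation matrix;
* Bartlett's test of sphericity,
  chi2 = -(n - 1 - (2p + 5) / 6) * ln |R|, df = p (p - 1) / 2,
  testing R = I against the chi-square distribution.

Loadings are eigenvector columns scaled by the square root of their
eigenvalue, with the sign fixed so each component's largest-magnitude
loading is positive; communalities are row sums of squared retained
loadings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sstats

from .dataset import MonitoringDataset
from .errors import ValidationError

logger = logging.getLogger(__name__)


def kmo(correlation: np.ndarray | pd.DataFrame) -> float:
    """Kaiser-Meyer-Olkin measure of sampling adequacy of a correlation
    matrix.

    Values near 1 indicate compact patterns of correlation suited to
    component extraction; below 0.5 is conventionally inadequate.
    """
    R = np.asarray(correlation, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValidationError("correlation matrix must be square")
    p = R.shape[0]
    off = ~np.eye(p, dtype=bool)
    r2 = float((R[off] ** 2).sum())
    if r2 == 0:
        raise ValidationError(
            "KMO undefined for an identity correlation matrix"
        )
    try:
        S = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("correlation matrix is singular") from exc
    d = np.sqrt(np.outer(np.diag(S), np.diag(S)))
    Q = -S / d  # anti-image partial correlations (off-diagonal)
    q2 = float((Q[off] ** 2).sum())
    return r2 / (r2 + q2)


def bartlett_sphericity(
    correlation: np.ndarray | pd.DataFrame, n: int
) -> tuple[float, int, float]:
    """Bartlett's test that the correlation matrix is the identity.

    Returns (chi2, df, p).  ``n`` is the number of observations behind the
    correlation matrix and must exceed the number of variables.
    """
    R = np.asarray(correlation, dtype=float)
    p = R.shape[0]
    if n <= p:
        raise ValidationError("need more observations than variables")
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValidationError("correlation matrix must be positive definite")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    chi2 = max(chi2, 0.0)
    df = p * (p - 1) // 2
    pval = float(_sstats.chi2.sf(chi2, df))
    return float(chi2), int(df), pval


@dataclass
class PCAResult:
    """Eigenstructure of the parameter correlation matrix plus diagnostics."""

    parameters: tuple[str, ...]
    eigenvalues: np.ndarray
    explained_pct: np.ndarray
    cumulative_pct: np.ndarray
    loadings: pd.DataFrame  # parameters x all components
    communalities: pd.Series  # from retained components
    n_retained: int
    n_observations: int
    kmo: float | None
    bartlett_chi2: float | None
    bartlett_df: int | None
    bartlett_p: float | None
    excluded: tuple[str, ...] = ()

    @property
    def retained_loadings(self) -> pd.DataFrame:
        return self.loadings.iloc[:, : self.n_retained]

    def scree(self) -> list[tuple[int, float]]:
        """(component number, eigenvalue) pairs for external plotting."""
        return [(i + 1, float(v)) for i, v in enumerate(self.eigenvalues)]


def pca_correlation(
    wide: pd.DataFrame, alpha: float = 0.05
) -> PCAResult:
    """PCA of the correlation matrix of a wide observations-by-variables
    table (complete cases)."""
    wide = wide.dropna()
    n = len(wide)
    if n < 3:
        raise ValidationError("need at least 3 complete observations")
    constant: list[str] = [c for c in wide.columns if wide[c].nunique() <= 1]
    if constant:
        logger.warning("excluding constant column(s): %s", constant)
        wide = wide.drop(columns=constant)
    if wide.shape[1] < 2:
        raise ValidationError("need at least 2 non-constant variables")
    params = tuple(wide.columns)
    p = len(params)
    X = wide.to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    R = np.corrcoef(X, rowvar=False)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]  # stable; ties keep variable order
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # deterministic sign: largest-magnitude loading positive per component
    for j in range(p):
        k = np.argmax(np.abs(evecs[:, j]))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]
    loadings = evecs * np.sqrt(evals)
    explained = evals / p * 100.0
    # Kaiser rule, strictly > 1; the epsilon keeps eigenvalues that are 1 up
    # to rounding (e.g. an identity correlation matrix) below the boundary
    n_retained = int((evals > 1.0 + 1e-9).sum())
    retained = loadings[:, :n_retained]
    communalities = (retained**2).sum(axis=1)
    comp_names = [f"PC{i + 1}" for i in range(p)]
    try:
        kmo_value = kmo(R)
    except ValidationError:
        kmo_value = None
    try:
        chi2, df, pval = bartlett_sphericity(R, n)
    except ValidationError:
        # singular correlation matrix (e.g. perfectly collinear variables):
        # the sphericity test is undefined
        chi2 = df = pval = None
    return PCAResult(
        parameters=params,
        eigenvalues=evals,
        explained_pct=explained,
        cumulative_pct=np.cumsum(explained),
        loadings=pd.DataFrame(loadings, index=params, columns=comp_names),
        communalities=pd.Series(communalities, index=params,
                                name="communality"),
        n_retained=n_retained,
        n_observations=n,
        kmo=kmo_value,
        bartlett_chi2=chi2,
        bartlett_df=df,
        bartlett_p=pval,
        excluded=tuple(constant),
    )


def pca(ds: MonitoringDataset) -> PCAResult:
    """PCA over a monitoring dataset (observation = replicate event)."""
    wide = ds.frame.pivot_table(
        index=["date", "site", "depth_cm", "replicate"],
        columns="parameter",
        values="value",
    )
    return pca_correlation(wide)
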