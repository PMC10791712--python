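"""Carlson trophic state index (TSI) from nutrient concentrations.

The index is computed from the mean total-phosphorus and total-nitrogen
concentrations:

    TSI(TP) = 10 * (9.40 + 1.62 * ln TP)
    TSI(TN) = 10 * (5.24 + 1.86 * ln TN)
    TSI     = (TSI(TP) + TSI(TN)) / 2

with concentrations in mg/L (a unit flag converts from ug/L explicitly —
the coefficients themselves carry no unit conversion).  Higher values mean
more eutrophic conditions; the default classification bands are the
conventional Carlson cut-offs (< 40 oligotrophic, 40-50 mesotrophic,
50-70 eutrophic, > 70 hypereutrophic), configurable because published
schemes differ at the margins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .dataset import MonitoringDataset
from .errors import ConfigurationError, ValidationError

#: Default classification: contiguous left-closed intervals over the line.
DEFAULT_SCHEME: tuple[tuple[float, float, str], ...] = (
    (-math.inf, 40.0, "oligotrophic"),
    (40.0, 50.0, "mesotrophic"),
    (50.0, 70.0, "eutrophic"),
    (70.0, math.inf, "hypereutrophic"),
)


def tsi_tp(tp: float) -> float:
    """TSI from total phosphorus (mg/L): 10 * (9.40 + 1.62 ln TP)."""
    if tp <= 0:
        raise ValidationError("TP must be positive")
    return 10.0 * (9.40 + 1.62 * math.log(tp))


def tsi_tn(tn: float) -> float:
    """TSI from total nitrogen (mg/L): 10 * (5.24 + 1.86 ln TN)."""
    if tn <= 0:
        raise ValidationError("TN must be positive")
    return 10.0 * (5.24 + 1.86 * math.log(tn))


def tsi_combined(tsi_tp_value: float, tsi_tn_value: float) -> float:
    """Arithmetic mean of the TP- and TN-based components."""
    return (tsi_tp_value + tsi_tn_value) / 2.0


def trophic_class(
    tsi: float, scheme: tuple[tuple[float, float, str], ...] = DEFAULT_SCHEME
) -> str:
    """Label of the scheme interval containing ``tsi`` (left-closed)."""
    lo_prev = None
    for lo, hi, _label in scheme:
        if lo >= hi:
            raise ConfigurationError("scheme intervals must be increasing")
        if lo_prev is not None and lo != lo_prev:
            raise ConfigurationError(
                "scheme intervals must be contiguous over the real line"
            )
        lo_prev = hi
    if scheme[0][0] != -math.inf or scheme[-1][1] != math.inf:
        raise ConfigurationError("scheme must cover the whole real line")
    for lo, hi, label in scheme:
        if lo <= tsi < hi:
            return label
    return scheme[-1][2]


@dataclass(frozen=True)
class TSIResult:
    """Combined trophic state for one set of mean concentrations."""

    tp_mean: float
    tn_mean: float
    tsi_tp: float
    tsi_tn: float
    tsi: float
    trophic_class: str


def assess_tsi(
    tp_mean: float,
    tn_mean: float,
    units: str = "mg",
    scheme=DEFAULT_SCHEME,
) -> TSIResult:
    """TSI from mean TP and TN concentrations (``units``: "mg" or "ug")."""
    if units == "ug":
        tp_mean, tn_mean = tp_mean / 1000.0, tn_mean / 1000.0
    elif units != "mg":
        raise ConfigurationError(f"unknown unit flag {units!r}")
    a = tsi_tp(tp_mean)
    b = tsi_tn(tn_mean)
    t = tsi_combined(a, b)
    return TSIResult(tp_mean, tn_mean, a, b, t, trophic_class(t, scheme))


def tsi_by_period(
    ds: MonitoringDataset, units: str = "mg", scheme=DEFAULT_SCHEME
) -> pd.DataFrame:
    """Period-wise mean TP/TN and the resulting TSI, one row per period."""
    rows = []
    for period in ("before", "after"):
        sub = ds.subset(period=period)
        tp = sub.values("TP")
        tn = sub.values("TN")
        if tp.size == 0 or tn.size == 0:
            continue
        res = assess_tsi(float(tp.mean()), float(tn.mean()), units, scheme)
        rows.append(
            (period, res.tp_mean, res.tn_mean, res.tsi_tp, res.tsi_tn,
             res.tsi, res.trophic_class)
        )
    return pd.DataFrame(
        rows,
        columns=["period", "tp_mean", "tn_mean", "tsi_tp", "tsi_tn", "tsi",
                 "trophic_class"],
    ).set_index("period")
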