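"""Per-parameter, per-period descriptive statistics and percent change.

The before/after comparison is summarized per parameter by min, max, sample
standard deviation, median and mean over all replicate-level values in the
period, and by the percent difference of the period means — the study's
headline effectiveness metric.  Replicates are pooled, not averaged, before
summarizing; the period-wise spreads are only meaningful at replicate level.

Parameters with zero variance over the whole record (here: Salmonella
presence, never detected) carry no information for the inferential stages
and are excluded with an explicit audit trail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import AFTER, BEFORE, MonitoringDataset
from .errors import UndefinedChangeError

STAT_ROWS = ("n", "min", "max", "sd", "median", "mean")


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of the study's tables)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def percent_change(before: float, after: float) -> float:
    """Percent difference of two means: 100 * (after - before) / before.

    Negative for reductions.  Undefined for a zero baseline.  The exact
    (unrounded) value is returned; use :func:`round_half_away` to match
    2-decimal reporting.
    """
    if before == 0:
        raise UndefinedChangeError("percent change undefined for zero baseline")
    return 100.0 * (after - before) / before


@dataclass(frozen=True)
class SummaryStats:
    """Six-number summary of one (parameter, period) cell."""

    n: int
    min: float
    max: float
    sd: float
    median: float
    mean: float

    @classmethod
    def from_values(cls, values: np.ndarray) -> "SummaryStats":
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            raise ValueError("cannot summarize an empty cell")
        # n=1 gets sd 0 by convention so summary tables stay total
        sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        return cls(
            n=int(v.size),
            min=float(v.min()),
            max=float(v.max()),
            sd=sd,
            median=float(np.median(v)),
            mean=float(v.mean()),
        )


@dataclass
class SummaryTable:
    """Period-wise descriptives plus the per-parameter mean difference.

    ``stats[(parameter, period)]`` holds a :class:`SummaryStats`;
    ``mean_difference_pct[parameter]`` the unrounded percent change of the
    period means (absent when a period is missing or the before mean is 0).
    """

    stats: dict[tuple[str, str], SummaryStats]
    mean_difference_pct: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        """Wide layout: rows = statistic x period, columns = parameters."""
        params = sorted({p for p, _ in self.stats})
        rows = []
        index = []
        for stat in STAT_ROWS:
            for period in (BEFORE, AFTER):
                index.append((stat, period))
                rows.append(
                    [
                        getattr(self.stats[(p, period)], stat)
                        if (p, period) in self.stats
                        else np.nan
                        for p in params
                    ]
                )
        index.append(("mean_difference_pct", ""))
        rows.append(
            [
                round_half_away(self.mean_difference_pct[p])
                if p in self.mean_difference_pct
                else np.nan
                for p in params
            ]
        )
        return pd.DataFrame(
            rows,
            index=pd.MultiIndex.from_tuples(index, names=["statistic",
                                                          "period"]),
            columns=params,
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def describe(
    ds: MonitoringDataset, group_by_period: bool = True
) -> SummaryTable:
    """Summarize each (parameter, period) cell over replicate-level values.

    With ``group_by_period=False`` a single pooled cell per parameter is
    produced (period label ``"all"``) and no mean differences are computed.
    """
    f = ds.labeled
    stats: dict[tuple[str, str], SummaryStats] = {}
    diffs: dict[str, float] = {}
    if not group_by_period:
        for p, grp in f.groupby("parameter", sort=True):
            stats[(p, "all")] = SummaryStats.from_values(
                grp["value"].to_numpy()
            )
        return SummaryTable(stats=stats, mean_difference_pct=diffs)
    for (p, period), grp in f.groupby(["parameter", "period"], sort=True):
        stats[(p, period)] = SummaryStats.from_values(grp["value"].to_numpy())
    for p in sorted({p for p, _ in stats}):
        if (p, BEFORE) in stats and (p, AFTER) in stats:
            before = stats[(p, BEFORE)].mean
            if before != 0:
                diffs[p] = percent_change(before, stats[(p, AFTER)].mean)
    return SummaryTable(stats=stats, mean_difference_pct=diffs)


def exclude_constant_parameters(
    ds: MonitoringDataset,
) -> tuple[MonitoringDataset, list[str]]:
    """Drop parameters with zero variance across the whole dataset.

    Returns the reduced dataset and the list of excluded codes (e.g. a
    pathogen never detected in any sample).
    """
    f = ds.frame
    excluded = [
        p
        for p, grp in f.groupby("parameter", sort=True)
        if grp["value"].nunique() <= 1
    ]
    keep = [p for p in f["parameter"].unique() if p not in excluded]
    return ds.subset(parameters=keep), excluded
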