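"""Per-sampling-point treatment effectiveness and duration of action.

The short-horizon assessment compares the series sampled on the
application day with the two series sampled one and two weeks later, per
sampling point (site x depth) and parameter.  The cell value is the percent
change of the point's series means; the overall row pools the raw records
across points before taking means (a per-cell arithmetic mean is reported
as an alternative aggregate).

Duration of action estimates how long a reduced parameter takes to return
to its application-day baseline, assuming the return is proportional to
the observed rate of change between the two post-application series
(linear rebound).  With only two post-application series no decay kinetics
can be fitted; estimates without an observed rebound are censored at a
configurable horizon.  Durations are reported in hours (canonical), with
minutes = round(hours * 60) and days = round(hours / 24, 2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import MICROBIOLOGICAL_COUNTS, MonitoringDataset
from .descriptives import percent_change, round_half_away
from .errors import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_HORIZON_DAYS = 60.0


@dataclass(frozen=True)
class EffectivenessCell:
    """Percent change at one sampling point for one parameter."""

    site: int
    depth_cm: int
    parameter: str
    pct_change: float


@dataclass
class EffectivenessTable:
    """Per-point percent changes plus pooled and per-cell-mean aggregates."""

    cells: list[EffectivenessCell]
    overall_pooled: dict[str, float]
    overall_cell_mean: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        params = sorted({c.parameter for c in self.cells})
        points = sorted({(c.site, c.depth_cm) for c in self.cells})
        data = {
            (c.site, c.depth_cm, c.parameter): c.pct_change
            for c in self.cells
        }
        rows = []
        index = []
        for site, depth in points:
            index.append(f"{site} ({depth} cm)")
            rows.append(
                [
                    round_half_away(data[(site, depth, p)])
                    if (site, depth, p) in data
                    else np.nan
                    for p in params
                ]
            )
        index.append("overall (pooled)")
        rows.append(
            [
                round_half_away(self.overall_pooled[p])
                if p in self.overall_pooled
                else np.nan
                for p in params
            ]
        )
        index.append("overall (mean of points)")
        rows.append(
            [
                round_half_away(self.overall_cell_mean[p])
                if p in self.overall_cell_mean
                else np.nan
                for p in params
            ]
        )
        return pd.DataFrame(rows, index=index, columns=params)


def effectiveness_table(
    ds: MonitoringDataset,
    parameters: tuple[str, ...] = MICROBIOLOGICAL_COUNTS,
) -> EffectivenessTable:
    """Short-horizon effectiveness at each sampling point.

    ``before`` is the application-day series mean at the point; ``after``
    pools the point's post-application series.  Cells whose application-day
    mean is zero (or whose series are missing) are absent, with a warning.
    """
    app = ds.application_date
    after_dates = ds.after_dates
    if not after_dates:
        raise ValidationError("dataset has no post-application series")
    cells: list[EffectivenessCell] = []
    pooled: dict[str, float] = {}
    cell_mean: dict[str, float] = {}
    f = ds.frame
    for code in parameters:
        sub = f[f["parameter"] == code]
        b_all = sub[sub["date"] == app]["value"]
        a_all = sub[sub["date"].isin(after_dates)]["value"]
        per_point: list[float] = []
        for site in sorted(sub["site"].unique()):
            for depth in sorted(sub["depth_cm"].unique()):
                at = sub[(sub["site"] == site) & (sub["depth_cm"] == depth)]
                b = at[at["date"] == app]["value"]
                a = at[at["date"].isin(after_dates)]["value"]
                if b.empty or a.empty:
                    logger.warning(
                        "missing series for %s at site %s depth %s",
                        code, site, depth,
                    )
                    continue
                if b.mean() == 0:
                    logger.warning(
                        "zero application-day mean for %s at site %s depth %s",
                        code, site, depth,
                    )
                    continue
                pct = percent_change(b.mean(), a.mean())
                cells.append(EffectivenessCell(site, depth, code, pct))
                per_point.append(pct)
        if not b_all.empty and not a_all.empty and b_all.mean() != 0:
            pooled[code] = percent_change(b_all.mean(), a_all.mean())
        if per_point:
            cell_mean[code] = float(np.mean(per_point))
    return EffectivenessTable(
        cells=cells, overall_pooled=pooled, overall_cell_mean=cell_mean
    )


@dataclass(frozen=True)
class DurationEstimate:
    """Time for a parameter to return to its application-day baseline."""

    parameter: str
    minutes: int
    hours: float
    days: float
    censored: bool
    horizon_days: float

    @classmethod
    def from_days(
        cls,
        parameter: str,
        t_days: float,
        censored: bool,
        horizon_days: float,
    ) -> "DurationEstimate":
        hours = round_half_away(t_days * 24.0, 1)  # hours are canonical
        minutes, days = convert_duration(hours)
        return cls(
            parameter=parameter,
            minutes=minutes,
            hours=hours,
            days=days,
            censored=censored,
            horizon_days=horizon_days,
        )


def convert_duration(hours: float) -> tuple[int, float]:
    """(minutes, days) for a duration given in hours.

    minutes = round(hours * 60); days = round(hours / 24, 2).
    """
    if hours < 0:
        raise ValidationError("duration must be non-negative")
    minutes = int(round_half_away(hours * 60.0, 0))
    days = round_half_away(hours / 24.0, 2)
    return minutes, days


def duration_of_action(
    v0: float,
    v1: float,
    v2: float,
    horizon_days: float = DEFAULT_HORIZON_DAYS,
    parameter: str = "",
) -> DurationEstimate:
    """Estimated time to return to the application-day baseline.

    ``v0, v1, v2`` are the series means at day 0 (application), day 7 and
    day 14.  Cases:

    * never departed or already back (``v2 >= v0``): the return time is the
      first day at which the piecewise-linear path through the three means
      re-crosses the baseline (0 if it never dropped below it);
    * still declining (``v2 <= v1 < v0``): no rebound observed — censored
      at the horizon;
    * rebounding (``v1 < v2 < v0``): the rebound rate rho = (v2 - v1) / 7
      is extrapolated linearly, T = 14 + (v0 - v2) / rho, capped (censored)
      at the horizon.
    """
    if v0 <= 0:
        raise ValidationError("baseline mean must be positive")
    if min(v1, v2) < 0:
        raise ValidationError("series means must be non-negative")
    if v2 >= v0:
        if v1 >= v0:
            t = 0.0  # never dropped below baseline
        else:
            # dropped by day 7, back above baseline by day 14
            t = 7.0 + 7.0 * (v0 - v1) / (v2 - v1)
        return DurationEstimate.from_days(parameter, t, False, horizon_days)
    if v2 <= v1:
        return DurationEstimate.from_days(
            parameter, horizon_days, True, horizon_days
        )
    rho = (v2 - v1) / 7.0
    if rho <= 0.0:  # underflow guard: no measurable rebound rate
        return DurationEstimate.from_days(
            parameter, horizon_days, True, horizon_days
        )
    t = 14.0 + (v0 - v2) / rho
    if t > horizon_days:
        return DurationEstimate.from_days(
            parameter, horizon_days, True, horizon_days
        )
    return DurationEstimate.from_days(parameter, t, False, horizon_days)


def duration_table(
    ds: MonitoringDataset,
    parameters: tuple[str, ...] = MICROBIOLOGICAL_COUNTS,
    horizon_days: float = DEFAULT_HORIZON_DAYS,
) -> pd.DataFrame:
    """Duration of action per parameter from pooled series means.

    Uses the application-day series and the first two post-application
    series, pooled across sampling points.
    """
    app = ds.application_date
    after = ds.after_dates
    if len(after) < 2:
        raise ValidationError("need two post-application series")
    d7, d14 = after[0], after[1]
    rows = []
    f = ds.frame
    for code in parameters:
        sub = f[f["parameter"] == code]
        v0 = sub[sub["date"] == app]["value"].mean()
        v1 = sub[sub["date"] == d7]["value"].mean()
        v2 = sub[sub["date"] == d14]["value"].mean()
        est = duration_of_action(
            v0, v1, v2, horizon_days=horizon_days, parameter=code
        )
        rows.append(
            (code, est.days, est.hours, est.minutes, est.censored)
        )
    return pd.DataFrame(
        rows, columns=["parameter", "days", "hours", "minutes", "censored"]
    ).set_index("parameter")
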