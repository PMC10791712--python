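"""Domain model and I/O for reservoir water-quality monitoring data.

The study design is a before/after intervention assessment: a fixed sampling
schedule of 9 dates spanning three seasons, 3 sites inside a floating dam,
2 sampling depths (30 and 100 cm) and 3 laboratory replicates per sample,
with an effective-microorganism (EM) application on a single date.  Every
series sampled on or before the application date belongs to the "before"
period; later series are "after".

Measurements are stored long-format (one row per replicate determination)
in the units the field reports: CFU per mL for bacterial counts, mg per L
for chemistry, uS per cm for conductivity.  Missing values are not allowed
in a validated dataset; the reader can optionally drop incomplete rows and
report how many were dropped.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

MICROBIOLOGICAL = "microbiological"
PHYSICOCHEMICAL = "physicochemical"


@dataclass(frozen=True)
class ParameterDef:
    """A monitored water-quality parameter.

    ``lower_is_better`` encodes the direction of improvement used by the
    regulatory and effectiveness stages (bacterial counts and nutrient
    concentrations should fall; dissolved oxygen should rise).
    """

    code: str
    unit: str
    kind: str
    lower_is_better: bool
    description: str = ""


#: Registry of the 15 monitored parameters.  SALM is binary presence/absence
#: of Salmonella spp.; all other microbiological parameters are plate/MPN
#: counts expressed per mL.
PARAMETERS: dict[str, ParameterDef] = {
    p.code: p
    for p in [
        ParameterDef("HBN22", "CFU/mL", MICROBIOLOGICAL, True,
                     "heterotrophic bacteria cultured at 22 C"),
        ParameterDef("HBN36", "CFU/mL", MICROBIOLOGICAL, True,
                     "heterotrophic bacteria cultured at 36 C"),
        ParameterDef("CBN", "CFU/mL", MICROBIOLOGICAL, True,
                     "total coliform bacteria"),
        ParameterDef("FCBN", "CFU/mL", MICROBIOLOGICAL, True,
                     "fecal coliform bacteria"),
        ParameterDef("FEN", "CFU/mL", MICROBIOLOGICAL, True,
                     "fecal enterococci"),
        ParameterDef("SALM", "presence", MICROBIOLOGICAL, True,
                     "Salmonella spp. presence (0/1)"),
        ParameterDef("PH", "-", PHYSICOCHEMICAL, False, "pH"),
        ParameterDef("EC", "uS/cm", PHYSICOCHEMICAL, True,
                     "electrolytic conductivity"),
        ParameterDef("TN", "mg/L", PHYSICOCHEMICAL, True, "total nitrogen"),
        ParameterDef("NO3N", "mg/L", PHYSICOCHEMICAL, True,
                     "nitrate nitrogen"),
        ParameterDef("PO4P", "mg/L", PHYSICOCHEMICAL, True,
                     "phosphate phosphorus"),
        ParameterDef("TP", "mg/L", PHYSICOCHEMICAL, True, "total phosphorus"),
        ParameterDef("DO", "mg/L", PHYSICOCHEMICAL, False,
                     "dissolved oxygen"),
        ParameterDef("BOD5", "mg/L", PHYSICOCHEMICAL, True,
                     "5-day biochemical oxygen demand"),
        ParameterDef("COD", "mg/L", PHYSICOCHEMICAL, True,
                     "chemical oxygen demand"),
    ]
}

MICROBIOLOGICAL_COUNTS = ("HBN22", "HBN36", "CBN", "FCBN", "FEN")
PHYSICOCHEMICAL_CODES = tuple(
    c for c, p in PARAMETERS.items() if p.kind == PHYSICOCHEMICAL
)

#: The study's sampling schedule: three series per year 2019-2021, the EM
#: application taking place on the first 2021 series.
APPLICATION_DATE = dt.date(2021, 8, 9)
STUDY_SCHEDULE: tuple[dt.date, ...] = (
    dt.date(2019, 7, 2),
    dt.date(2019, 9, 16),
    dt.date(2019, 11, 20),
    dt.date(2020, 7, 28),
    dt.date(2020, 9, 16),
    dt.date(2020, 11, 23),
    dt.date(2021, 8, 9),
    dt.date(2021, 8, 16),
    dt.date(2021, 8, 23),
)

SITES = (1, 2, 3)
DEPTHS_CM = (30, 100)
REPLICATES = (1, 2, 3)

COLUMNS = ["date", "site", "depth_cm", "replicate", "parameter", "value"]
KEY_COLUMNS = ["date", "site", "depth_cm", "replicate", "parameter"]

BEFORE = "before"
AFTER = "after"


def _as_date(x) -> dt.date:
    if isinstance(x, dt.datetime):
        return x.date()
    if isinstance(x, dt.date):
        return x
    return dt.date.fromisoformat(str(x))


@dataclass
class MonitoringDataset:
    """Validated long-format monitoring records plus the study metadata.

    ``frame`` holds one row per replicate determination with columns
    ``date, site, depth_cm, replicate, parameter, value`` (dates as
    ``datetime.date``).  ``schedule`` is the ordered list of sampling dates;
    ``application_date`` splits it into the before/after periods.
    """

    frame: pd.DataFrame
    application_date: dt.date = APPLICATION_DATE
    schedule: tuple[dt.date, ...] = STUDY_SCHEDULE
    validate_on_init: bool = True

    def __post_init__(self) -> None:
        self.application_date = _as_date(self.application_date)
        self.schedule = tuple(sorted(_as_date(d) for d in self.schedule))
        f = self.frame.copy()
        missing = [c for c in COLUMNS if c not in f.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        f = f[COLUMNS + [c for c in f.columns if c not in COLUMNS]]
        f["date"] = [_as_date(d) for d in f["date"]]
        for col in ("site", "depth_cm", "replicate"):
            f[col] = f[col].astype(int)
        f["parameter"] = f["parameter"].astype(str)
        f["value"] = pd.to_numeric(f["value"], errors="raise")
        self.frame = f.reset_index(drop=True)
        if self.validate_on_init:
            self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        """Enforce all domain invariants; raise ValidationError on breach."""
        f = self.frame
        unknown = sorted(set(f["parameter"]) - set(PARAMETERS))
        if unknown:
            raise ValidationError(f"unknown parameter code(s): {unknown}")
        if f["value"].isna().any():
            n = int(f["value"].isna().sum())
            raise ValidationError(f"{n} missing value(s); drop them at ingest")
        if (f["value"] < 0).any():
            bad = f.loc[f["value"] < 0].iloc[0]
            raise ValidationError(
                f"negative value {bad['value']} for {bad['parameter']} "
                f"on {bad['date']}"
            )
        ph = f.loc[f["parameter"] == "PH", "value"]
        if ((ph < 0) | (ph > 14)).any():
            raise ValidationError("pH value outside [0, 14]")
        salm = f.loc[f["parameter"] == "SALM", "value"]
        if (~salm.isin([0.0, 1.0])).any():
            raise ValidationError("SALM values must be 0 or 1")
        if not f["site"].isin(SITES).all():
            raise ValidationError("site must be in 1..3")
        if not f["depth_cm"].isin(DEPTHS_CM).all():
            raise ValidationError("depth_cm must be 30 or 100")
        if not f["replicate"].isin(REPLICATES).all():
            raise ValidationError("replicate must be in 1..3")
        off_schedule = sorted(set(f["date"]) - set(self.schedule))
        if off_schedule:
            raise ValidationError(
                f"record date(s) not in the sampling schedule: {off_schedule}"
            )
        dup = f.duplicated(subset=KEY_COLUMNS)
        if dup.any():
            keys = f.loc[dup, KEY_COLUMNS].iloc[0].to_dict()
            raise ValidationError(f"duplicate record key: {keys}")

    # -- periods ---------------------------------------------------------

    def period_of(self, date) -> str:
        """Period label for a date: application day and earlier -> before."""
        return BEFORE if _as_date(date) <= self.application_date else AFTER

    def label_periods(self) -> "MonitoringDataset":
        """Return a copy whose frame carries a ``period`` column."""
        f = self.frame.copy()
        f["period"] = [self.period_of(d) for d in f["date"]]
        return MonitoringDataset(
            f, self.application_date, self.schedule, validate_on_init=False
        )

    @property
    def labeled(self) -> pd.DataFrame:
        """Frame with the period column (computed on the fly)."""
        if "period" in self.frame.columns:
            return self.frame
        return self.label_periods().frame

    @property
    def before_dates(self) -> tuple[dt.date, ...]:
        return tuple(d for d in self.schedule if d <= self.application_date)

    @property
    def after_dates(self) -> tuple[dt.date, ...]:
        return tuple(d for d in self.schedule if d > self.application_date)

    # -- subsetting ------------------------------------------------------

    def subset(
        self,
        *,
        period: str | None = None,
        dates: Iterable | None = None,
        sites: Iterable[int] | None = None,
        depths: Iterable[int] | None = None,
        parameters: Iterable[str] | None = None,
    ) -> "MonitoringDataset":
        """Filter records; all given clauses must hold.  Empty result is OK."""
        f = self.labeled
        mask = pd.Series(True, index=f.index)
        if period is not None:
            if period not in (BEFORE, AFTER):
                raise ValidationError(f"unknown period {period!r}")
            mask &= f["period"] == period
        if dates is not None:
            want = {_as_date(d) for d in dates}
            mask &= f["date"].isin(want)
        if sites is not None:
            mask &= f["site"].isin(set(sites))
        if depths is not None:
            mask &= f["depth_cm"].isin(set(depths))
        if parameters is not None:
            want_p = set(parameters)
            unknown = sorted(want_p - set(PARAMETERS))
            if unknown:
                raise ValidationError(f"unknown parameter code(s): {unknown}")
            mask &= f["parameter"].isin(want_p)
        out = f.loc[mask].reset_index(drop=True)
        return MonitoringDataset(
            out, self.application_date, self.schedule, validate_on_init=False
        )

    def values(self, parameter: str, period: str | None = None) -> np.ndarray:
        """Replicate-level values for one parameter (optionally one period)."""
        sub = self.subset(parameters=[parameter], period=period)
        return sub.frame["value"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.frame)

    # -- I/O -------------------------------------------------------------

    def to_csv(self, path) -> None:
        f = self.frame[COLUMNS].copy()
        f["date"] = [d.isoformat() for d in f["date"]]
        f.to_csv(path, index=False)

    def to_json(self) -> str:
        payload = {
            "application_date": self.application_date.isoformat(),
            "schedule": [d.isoformat() for d in self.schedule],
            "records": [
                {
                    "date": r.date.isoformat(),
                    "site": int(r.site),
                    "depth_cm": int(r.depth_cm),
                    "replicate": int(r.replicate),
                    "parameter": r.parameter,
                    "value": float(r.value),
                }
                for r in self.frame[COLUMNS].itertuples(index=False)
            ],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MonitoringDataset":
        payload = json.loads(text)
        frame = pd.DataFrame(payload["records"], columns=COLUMNS)
        return cls(
            frame,
            application_date=payload["application_date"],
            schedule=tuple(payload["schedule"]),
        )


def read_dataset(
    path,
    *,
    application_date=APPLICATION_DATE,
    schedule: Sequence | None = None,
    drop_incomplete: bool = False,
) -> MonitoringDataset:
    """Read a long-format monitoring CSV into a validated dataset.

    The header must contain ``date,site,depth_cm,replicate,parameter,value``.
    With ``drop_incomplete=True`` rows with a missing value are removed and
    their count logged instead of raising.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    frame = pd.read_csv(path)
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    if drop_incomplete:
        n0 = len(frame)
        frame = frame.dropna(subset=COLUMNS)
        dropped = n0 - len(frame)
        if dropped:
            logger.info("dropped %d incomplete row(s) at ingest", dropped)
    if schedule is None:
        schedule = tuple(sorted({_as_date(d) for d in frame["date"]}))
    return MonitoringDataset(
        frame, application_date=application_date, schedule=tuple(schedule)
    )


def write_dataset(ds: MonitoringDataset, path) -> None:
    ds.to_csv(path)
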