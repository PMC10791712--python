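"""Bathing-water compliance scoring and ecological-status classification.

Two regulatory assessments are implemented:

* **Bathing-water compliance** (microbiological): each sample of an
  assessed parameter scores 1 if it meets the regulatory maximum, else 0;
  the final rating is the fraction of compliant samples on a 0-1 scale,
  rounded to 2 decimals, with 0.00-0.50 read as non-compliance and
  0.51-1.00 as compliance.

* **Ecological status** (physicochemical): each observation is weighted
  1 / 2 / 3 points for class I (very good) / II (good) / III (below good)
  by the parameter's class boundaries, the points are averaged over the
  assessment window, rounded to 2 decimals, and the average maps back to a
  class: 1.00-1.66 -> I, 1.67-2.33 -> II, 2.34-3.00 -> III.

The scoring and aggregation logic is fixed; the threshold tables are
configuration.  The shipped defaults for compliance are the Polish bathing
regulation limits for total coliforms (1000 per 100 mL) and fecal
enterococci (400 per 100 mL) converted to the per-mL unit used here; the
status class boundaries are documented placeholders for an undetermined
abiotic type and should be replaced with the values applicable to the
water body under assessment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import MonitoringDataset
from .descriptives import percent_change, round_half_away
from .errors import ConfigurationError, ValidationError

COMPLIANCE_BOUNDARY = 0.51  # rounded score at/above which water complies


@dataclass(frozen=True)
class ComplianceConfig:
    """Regulatory maxima (same unit as the data, CFU/mL) per parameter."""

    thresholds: dict[str, float] = field(
        default_factory=lambda: {"CBN": 10.0, "FEN": 4.0}
    )

    def __post_init__(self):
        for code, thr in self.thresholds.items():
            if thr <= 0:
                raise ConfigurationError(
                    f"threshold for {code} must be positive"
                )

    def to_json(self) -> str:
        return json.dumps(
            {c: {"max": t} for c, t in self.thresholds.items()}, indent=1
        )

    @classmethod
    def from_json(cls, text: str) -> "ComplianceConfig":
        data = json.loads(text)
        return cls({c: float(d["max"]) for c, d in data.items()})


@dataclass(frozen=True)
class StatusBounds:
    """Class boundaries for one physicochemical parameter.

    ``direction``:
      * ``"upper"``  — value <= class1 -> I, <= class2 -> II, else III;
      * ``"lower"``  — value >= class1 -> I, >= class2 -> II, else III
        (parameters where more is better, e.g. dissolved oxygen);
      * ``"range"``  — class1/class2 are (lo, hi) windows, class I inside
        the narrow window, class II inside the wide one, else III (pH).
    """

    direction: str
    class1: float | tuple[float, float]
    class2: float | tuple[float, float]

    def __post_init__(self):
        if self.direction not in ("upper", "lower", "range"):
            raise ConfigurationError(
                f"unknown direction {self.direction!r}"
            )
        if self.direction == "upper" and not self.class1 < self.class2:
            raise ConfigurationError("class I bound must be stricter")
        if self.direction == "lower" and not self.class1 > self.class2:
            raise ConfigurationError("class I bound must be stricter")
        if self.direction == "range":
            (a1, b1), (a2, b2) = self.class1, self.class2
            if not (a2 <= a1 and b1 <= b2):
                raise ConfigurationError(
                    "class I window must lie inside class II window"
                )

    def points(self, value: float) -> int:
        if self.direction == "upper":
            if value <= self.class1:
                return 1
            return 2 if value <= self.class2 else 3
        if self.direction == "lower":
            if value >= self.class1:
                return 1
            return 2 if value >= self.class2 else 3
        (a1, b1), (a2, b2) = self.class1, self.class2
        if a1 <= value <= b1:
            return 1
        return 2 if a2 <= value <= b2 else 3


#: Placeholder class boundaries (replace with the regulation applicable to
#: the assessed water body).
DEFAULT_STATUS_BOUNDS: dict[str, StatusBounds] = {
    "PH": StatusBounds("range", (6.5, 8.5), (6.0, 9.0)),
    "EC": StatusBounds("upper", 400.0, 600.0),
    "TN": StatusBounds("upper", 2.0, 3.5),
    "NO3N": StatusBounds("upper", 1.0, 2.0),
    "PO4P": StatusBounds("upper", 0.065, 0.13),
    "TP": StatusBounds("upper", 0.2, 0.4),
    "DO": StatusBounds("lower", 8.0, 6.0),
    "BOD5": StatusBounds("upper", 3.0, 6.0),
    "COD": StatusBounds("upper", 10.0, 20.0),
}


@dataclass(frozen=True)
class StatusConfig:
    bounds: dict[str, StatusBounds] = field(
        default_factory=lambda: dict(DEFAULT_STATUS_BOUNDS)
    )

    def to_json(self) -> str:
        return json.dumps(
            {
                c: {
                    "direction": b.direction,
                    "class1": b.class1,
                    "class2": b.class2,
                }
                for c, b in self.bounds.items()
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "StatusConfig":
        data = json.loads(text)
        bounds = {}
        for c, d in data.items():
            c1, c2 = d["class1"], d["class2"]
            if d["direction"] == "range":
                c1, c2 = tuple(c1), tuple(c2)
            bounds[c] = StatusBounds(d["direction"], c1, c2)
        return cls(bounds)


@dataclass(frozen=True)
class AssessmentResult:
    """Score and verdict for one parameter under one assessment."""

    parameter: str
    score: float
    class_or_verdict: str
    n: int


def compliance_score(
    values, parameter: str, cfg: ComplianceConfig | None = None
) -> AssessmentResult:
    """Fraction of samples meeting the regulatory maximum, with verdict.

    The verdict applies the 0.51 boundary to the score rounded to two
    decimals, so the printed boundary is exact.
    """
    cfg = cfg or ComplianceConfig()
    if parameter not in cfg.thresholds:
        raise ConfigurationError(
            f"no compliance threshold configured for {parameter}"
        )
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("compliance needs at least one sample")
    frac = float((v <= cfg.thresholds[parameter]).mean())
    score = round_half_away(frac, 2)
    verdict = (
        "compliance" if score >= COMPLIANCE_BOUNDARY else "non-compliance"
    )
    return AssessmentResult(parameter, score, verdict, int(v.size))


def compliance_fraction(values, parameter: str,
                        cfg: ComplianceConfig | None = None) -> float:
    """Unrounded compliant fraction (used for percent-change reporting)."""
    cfg = cfg or ComplianceConfig()
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("compliance needs at least one sample")
    return float((v <= cfg.thresholds[parameter]).mean())


def compliance_change(before_score: float, after_score: float) -> float:
    """Percent change of the compliant fraction, on unrounded fractions."""
    if before_score == 0:
        raise ValidationError(
            "compliance change undefined for a zero before-score"
        )
    return percent_change(before_score, after_score)


STATUS_CLASSES = (
    (1.00, 1.66, "class I"),
    (1.67, 2.33, "class II"),
    (2.34, 3.00, "class III"),
)


def classify_status_score(score: float) -> str:
    """Map a 2-decimal mean-points score onto the ecological class bands."""
    for lo, hi, label in STATUS_CLASSES:
        if lo <= score <= hi:
            return label
    raise ConfigurationError(f"status score {score} outside [1, 3]")


def ecological_status(
    values, parameter: str, cfg: StatusConfig | None = None
) -> AssessmentResult:
    """Mean class points (1/2/3) over observations, mapped to a class."""
    cfg = cfg or StatusConfig()
    if parameter not in cfg.bounds:
        raise ConfigurationError(
            f"no status boundaries configured for {parameter}"
        )
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("status assessment needs at least one value")
    pts = np.array([cfg.bounds[parameter].points(x) for x in v], dtype=float)
    score = round_half_away(float(pts.mean()), 2)
    return AssessmentResult(
        parameter, score, classify_status_score(score), int(v.size)
    )


def assessment_table(
    ds: MonitoringDataset,
    compliance_cfg: ComplianceConfig | None = None,
    status_cfg: StatusConfig | None = None,
) -> pd.DataFrame:
    """Before/after compliance and status assessment over a dataset.

    One row per assessed parameter and period, with the score, the verdict
    or class, and the before-to-after percent change of the underlying
    unrounded score.
    """
    compliance_cfg = compliance_cfg or ComplianceConfig()
    status_cfg = status_cfg or StatusConfig()
    rows = []
    present = set(ds.frame["parameter"].unique())
    for code in sorted(compliance_cfg.thresholds):
        if code not in present:
            continue
        b = ds.values(code, period="before")
        a = ds.values(code, period="after")
        res_b = compliance_score(b, code, compliance_cfg)
        res_a = compliance_score(a, code, compliance_cfg)
        fb = compliance_fraction(b, code, compliance_cfg)
        fa = compliance_fraction(a, code, compliance_cfg)
        change = compliance_change(fb, fa) if fb > 0 else np.nan
        rows.append(
            (code, "compliance", res_b.score, res_b.class_or_verdict,
             res_a.score, res_a.class_or_verdict, change)
        )
    for code in sorted(status_cfg.bounds):
        if code not in present:
            continue
        b = ds.values(code, period="before")
        a = ds.values(code, period="after")
        res_b = ecological_status(b, code, status_cfg)
        res_a = ecological_status(a, code, status_cfg)
        raw_b = np.mean(
            [status_cfg.bounds[code].points(x) for x in b]
        )
        raw_a = np.mean(
            [status_cfg.bounds[code].points(x) for x in a]
        )
        change = percent_change(float(raw_b), float(raw_a))
        rows.append(
            (code, "ecological status", res_b.score, res_b.class_or_verdict,
             res_a.score, res_a.class_or_verdict, change)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "parameter", "assessment", "score_before", "verdict_before",
            "score_after", "verdict_after", "pct_change",
        ],
    ).set_index(["assessment", "parameter"])
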