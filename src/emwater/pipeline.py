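"""End-to-end before/after assessment pipeline.

Runs the full analysis in a fixed order on one dataset (read from CSV or
simulated): constant-parameter exclusion, period-wise descriptives, rank
tests, per-point effectiveness plus duration of action, regulatory
compliance and ecological status, trophic state, PCA and the Spearman
matrix.  All outputs are plain CSV/JSON; a manifest records the seed, the
configuration hash and per-stage record counts so a run is reproducible
and auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .dataset import MICROBIOLOGICAL_COUNTS, read_dataset
from .descriptives import describe, exclude_constant_parameters
from .effectiveness import (
    DEFAULT_HORIZON_DAYS,
    duration_table,
    effectiveness_table,
)
from .errors import ValidationError
from .pca import pca
from .ranktests import period_rank_tests, spearman_matrix
from .regulatory import ComplianceConfig, StatusConfig, assessment_table
from .simulate import SimConfig, generate
from .trophic import tsi_by_period

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One reproducible analysis run.

    Exactly one of ``input_path`` (a monitoring CSV) or ``sim_config``
    (a simulation design; defaults to the study-calibrated one when
    ``simulate=True``) provides the data.
    """

    input_path: str | None = None
    sim_config: SimConfig | None = None
    seed: int = 0
    alpha: float = 0.05
    horizon_days: float = DEFAULT_HORIZON_DAYS
    tsi_units: str = "mg"
    compliance: ComplianceConfig = field(default_factory=ComplianceConfig)
    status: StatusConfig = field(default_factory=StatusConfig)
    out_dir: str = "emwater_out"

    def __post_init__(self):
        if (self.input_path is None) == (self.sim_config is None):
            raise ValidationError(
                "provide exactly one of input_path or sim_config"
            )

    def config_hash(self) -> str:
        payload = {
            "input_path": self.input_path,
            "sim_config": None
            if self.sim_config is None
            else json.loads(self.sim_config.to_json()),
            "seed": self.seed,
            "alpha": self.alpha,
            "horizon_days": self.horizon_days,
            "tsi_units": self.tsi_units,
            "compliance": json.loads(self.compliance.to_json()),
            "status": json.loads(self.status.to_json()),
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage; write outputs under ``cfg.out_dir``.

    Returns a dict of in-memory results keyed by stage name; the same
    content is written as CSV/JSON files plus ``manifest.json``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    if cfg.input_path is not None:
        ds = read_dataset(cfg.input_path)
    else:
        ds = generate(cfg.sim_config, cfg.seed)
    counts["input_records"] = len(ds)

    ds_used, excluded = exclude_constant_parameters(ds)
    counts["after_constant_exclusion"] = len(ds_used)
    logger.info("excluded constant parameter(s): %s", excluded)

    results: dict = {"excluded_parameters": excluded}

    summary = describe(ds_used)
    summary.to_csv(out / "summary.csv")
    results["summary"] = summary

    tests = period_rank_tests(ds_used, alpha=cfg.alpha)
    tests.to_csv(out / "rank_tests.csv")
    results["rank_tests"] = tests

    micro = tuple(
        c for c in MICROBIOLOGICAL_COUNTS
        if c in set(ds_used.frame["parameter"])
    )
    eff = effectiveness_table(ds_used, parameters=micro)
    eff.to_frame().to_csv(out / "effectiveness.csv")
    results["effectiveness"] = eff

    durations = duration_table(
        ds_used, parameters=micro, horizon_days=cfg.horizon_days
    )
    durations.to_csv(out / "duration.csv")
    results["duration"] = durations

    assessment = assessment_table(ds_used, cfg.compliance, cfg.status)
    assessment.to_csv(out / "assessment.csv")
    results["assessment"] = assessment

    tsi = tsi_by_period(ds_used, units=cfg.tsi_units)
    tsi.to_csv(out / "tsi.csv")
    results["tsi"] = tsi

    pca_res = pca(ds_used)
    pca_payload = {
        "parameters": list(pca_res.parameters),
        "eigenvalues": [float(v) for v in pca_res.eigenvalues],
        "explained_pct": [float(v) for v in pca_res.explained_pct],
        "cumulative_pct": [float(v) for v in pca_res.cumulative_pct],
        "n_retained": pca_res.n_retained,
        "n_observations": pca_res.n_observations,
        "kmo": pca_res.kmo,
        "bartlett": {
            "chi2": pca_res.bartlett_chi2,
            "df": pca_res.bartlett_df,
            "p": pca_res.bartlett_p,
        },
        "communalities": {
            k: float(v) for k, v in pca_res.communalities.items()
        },
        "scree": pca_res.scree(),
    }
    (out / "pca.json").write_text(json.dumps(pca_payload, indent=1))
    pca_res.retained_loadings.to_csv(out / "pca_loadings.csv")
    results["pca"] = pca_res

    corr = spearman_matrix(ds_used, alpha=cfg.alpha)
    corr.rho.to_csv(out / "spearman_rho.csv")
    corr.p.to_csv(out / "spearman_p.csv")
    results["spearman"] = corr

    manifest = {
        "package_version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "alpha": cfg.alpha,
        "excluded_parameters": excluded,
        "record_counts": counts,
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    results["manifest"] = manifest
    return results
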