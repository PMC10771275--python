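"""Config-driven end-to-end pipeline: simulate/load -> include -> summarize ->
model comparison -> covariate associations -> growth classification ->
margin of error, with JSON/CSV artifacts and a run manifest.

The pipeline is a pure function of (input data, configuration, seed):
identical configuration produces identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import covariates as cov_mod
from . import measurement, nlme
from .cohort import (
    Cohort,
    apply_inclusion_criteria,
    read_cohort,
    summarize_cohort,
    write_cohort,
)
from .simulate import SimulationConfig, simulate_cohort, simulate_measurement_pairs

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("meningrowth")

ALL_STAGES = ("summarize", "compare", "associations", "classify", "moe")


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run: input, stages, per-stage settings, output, seed."""

    output_dir: str
    input_csv: str | None = None  # mutually exclusive with simulation
    simulation: dict | None = None  # SimulationConfig overrides
    stages: tuple = ALL_STAGES
    seed: int = 0
    min_scans: int = 3
    min_span_months: float = 6.0
    models: tuple = ("linear", "exponential", "radial", "gompertz")
    covariates: tuple = cov_mod.DEFAULT_COVARIATES
    placement: str = "log_k"
    growth_cutoff: float = 0.15
    n_measurement_pairs: int = 20
    measurement_error_sd: float = 0.094
    bootstrap_B: int = 10_000
    fit: dict = field(default_factory=dict)  # FitConfig overrides
    log_level: str = "INFO"

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if self.input_csv is not None and self.simulation is not None:
            raise ValueError("give either input_csv or simulation, not both")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("stages", "models", "covariates"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def digest(self) -> str:
        """Hash of the scientific configuration (not the output location)."""
        payload = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(self).items()
            if k not in ("output_dir", "log_level")
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_json_default) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages and return {artifact name: payload}.

    Artifacts are also written under ``config.output_dir`` (JSON sidecar for
    every table), each stamped with the config hash and root seed.
    """
    logging.basicConfig(level=config.log_level, format="%(levelname)s %(name)s: %(message)s")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    stamp = {"config_hash": config.digest(), "seed": config.seed}

    # --- input stage
    if config.input_csv is not None:
        logger.info("reading cohort from %s", config.input_csv)
        cohort = read_cohort(config.input_csv)
    else:
        sim = dict(config.simulation or {})
        sim.setdefault("seed", config.seed)
        sim_config = SimulationConfig.from_dict(sim)
        logger.info(
            "simulating cohort: n=%d, model=%s, seed=%d",
            sim_config.n_patients, sim_config.model, sim_config.seed,
        )
        cohort, truth = simulate_cohort(sim_config)
        write_cohort(cohort, out / "cohort.csv")
        truth.to_csv(out / "truth.csv", index=False)

    cohort, exclusion_log = apply_inclusion_criteria(
        cohort, config.min_scans, config.min_span_months
    )
    exclusion_log.to_csv(out / "exclusions.csv", index=False)
    if cohort.n_patients == 0:
        raise RuntimeError("stage 'include': no patients left after inclusion criteria")

    fit_config = nlme.FitConfig(**config.fit) if config.fit else nlme.FitConfig()

    def _stage(name, fn):
        if name not in config.stages:
            return
        logger.info("stage %s", name)
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    def _summarize():
        summary = summarize_cohort(cohort, growth_cutoff=config.growth_cutoff)
        bundle["summary"] = summary
        _write_json(out / "summary.json", {**stamp, **summary})

    def _compare():
        table = nlme.compare_models(cohort, config.models, config=fit_config)
        bundle["comparison"] = table
        table.to_csv(out / "comparison.csv", index=False)
        _write_json(out / "comparison.json", {**stamp, "rows": table.to_dict("records")})

    def _associations():
        result = cov_mod.fit_gompertz_with_covariates(
            cohort, config.covariates, config.placement, config=fit_config
        )
        table = cov_mod.effects_table(result)
        bundle["associations"] = result
        table.to_csv(out / "associations.csv", index=False)
        _write_json(
            out / "associations.json",
            {
                **stamp,
                "placement": result.placement,
                "n_patients_used": result.n_patients_used,
                "n_patients_dropped": result.n_patients_dropped,
                "rows": table.to_dict("records"),
            },
        )

    def _classify():
        result = measurement.classify_cohort(cohort, cutoff=config.growth_cutoff)
        bundle["classification"] = result
        result.per_patient.to_csv(out / "classification.csv", index=False)
        _write_json(
            out / "classification.json",
            {**stamp, "counts": result.counts, "proportions": result.proportions,
             "cutoff": result.cutoff},
        )

    def _moe():
        pairs = simulate_measurement_pairs(
            config.n_measurement_pairs, config.measurement_error_sd, seed=config.seed
        )
        est = measurement.bootstrap_margin_of_error(
            pairs, B=config.bootstrap_B, seed=config.seed
        )
        bundle["margin_of_error"] = est
        _write_json(
            out / "margin_of_error.json",
            {
                **stamp,
                "median_error": est.median_error,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "n_pairs": est.n_pairs,
                "B": est.B,
                "ci_level": est.ci_level,
            },
        )

    _stage("summarize", _summarize)
    _stage("compare", _compare)
    _stage("associations", _associations)
    _stage("classify", _classify)
    _stage("moe", _moe)

    _write_json(out / "manifest.json", {**stamp, "stages": list(config.stages),
                                        "n_patients": cohort.n_patients,
                                        "n_scans": cohort.n_scans})
    bundle["cohort"] = cohort
    return bundle
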