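"""Association between tumor growth and patient-level risk factors.

Risk factors (sex, age, follow-up length, initial tumor volume,
multifocality, T2 signal category, peritumoral edema) enter the Gompertz
mixed model linearly on one fixed-effect parameter — by default log K, the
attained-size parameter, so a positive coefficient means the covariate is
associated with a larger growth endpoint. Inference is Wald: z = coef/SE
against the standard normal, two-sided p, and a 95% CI of coef +/- 1.96 SE.

Continuous covariates (age, follow-up months, log initial volume) are
standardized internally for optimizer conditioning and reported back on
their natural per-unit scales. Patients missing any requested covariate are
dropped casewise; the count is reported. No multiplicity correction is
applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, exclude_multifocal
from .nlme import CovariateDesign, FitConfig, FitResult, RandomEffectSpec, fit_nlme

__all__ = [
    "CovariateEffect",
    "AssociationResult",
    "wald_summary",
    "build_covariate_design",
    "fit_gompertz_with_covariates",
    "sensitivity_excluding_multifocal",
    "effects_table",
]

Z_975 = 1.959964  # standard-normal 97.5% quantile

DEFAULT_COVARIATES = (
    "sex",
    "age_at_first_scan",
    "followup_months",
    "initial_volume",
    "multifocal",
    "t2_category",
    "edema",
)


@dataclass(frozen=True)
class CovariateEffect:
    """One risk-factor row: coefficient, SE, Wald z, p and 95% CI."""

    name: str
    coef: float
    se: float
    z: float
    p: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class AssociationResult:
    """Joint covariate fit: effects plus the underlying mixed-model fit."""

    effects: tuple
    fit: FitResult
    n_patients_used: int
    n_patients_dropped: int
    placement: str


def wald_summary(name: str, coef: float, se: float) -> CovariateEffect:
    """Wald inference for one coefficient against the normal reference."""
    if not se > 0:
        raise ValueError(f"standard error must be > 0, got {se}")
    z = coef / se
    p = 2.0 * stats.norm.sf(abs(z))
    return CovariateEffect(
        name=name,
        coef=float(coef),
        se=float(se),
        z=float(z),
        p=float(p),
        ci_low=float(coef - Z_975 * se),
        ci_high=float(coef + Z_975 * se),
    )


def _patient_covariate_row(patient, names):
    """Raw covariate values for one patient, or None if any is missing."""
    c = patient.covariates
    row = {}
    for name in names:
        if name == "sex":
            if c.sex is None:
                return None
            row["sex"] = float(c.sex)
        elif name == "age_at_first_scan":
            if c.age_at_first_scan is None:
                return None
            row["age_at_first_scan"] = float(c.age_at_first_scan)
        elif name == "followup_months":
            row["followup_months"] = float(patient.span_months)
        elif name == "initial_volume":
            # log-transformed: volumes span almost three orders of magnitude
            row["log_initial_volume"] = math.log(patient.baseline_volume)
        elif name == "multifocal":
            if c.multifocal is None:
                return None
            row["multifocal"] = float(c.multifocal)
        elif name == "t2_category":
            if c.t2_category is None:
                return None
            row["t2_iso_vs_hypo"] = float(c.t2_category == "isointense")
            row["t2_hyper_vs_hypo"] = float(c.t2_category == "hyperintense")
        elif name == "edema":
            if c.edema is None:
                return None
            row["edema"] = float(c.edema)
        else:
            raise KeyError(f"unknown covariate {name!r}")
    return row


CONTINUOUS = ("age_at_first_scan", "followup_months", "log_initial_volume")


def build_covariate_design(
    cohort: Cohort, covariates, placement: str = "log_k"
) -> tuple[Cohort, CovariateDesign, np.ndarray, np.ndarray, int]:
    """Casewise-complete covariate design matrix for the requested factors.

    Returns the reduced cohort (patients with complete requested covariates),
    the standardized design, the per-column centers and scales used, and the
    number of patients dropped. T2 category expands to two contrasts versus
    the hypointense reference.
    """
    kept, rows = [], []
    for patient in cohort:
        row = _patient_covariate_row(patient, covariates)
        if row is None:
            continue
        kept.append(patient)
        rows.append(row)
    if not rows:
        raise ValueError("no patients with complete covariate data")
    frame = pd.DataFrame(rows)
    X = frame.to_numpy(dtype=float)
    names = tuple(frame.columns)
    center = np.zeros(X.shape[1])
    scale = np.ones(X.shape[1])
    for j, name in enumerate(names):
        col = X[:, j]
        if np.all(col == col[0]):
            raise ValueError(f"covariate {name!r} is constant in the fitted sample")
        if name in CONTINUOUS:
            center[j] = col.mean()
            scale[j] = col.std(ddof=1)
            X[:, j] = (col - center[j]) / scale[j]
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X]))
    if rank < X.shape[1] + 1:
        raise ValueError("covariate design matrix is collinear")
    design = CovariateDesign(names=names, matrix=X, placement=placement)
    n_dropped = cohort.n_patients - len(kept)
    return Cohort(tuple(kept)), design, center, scale, n_dropped


def fit_gompertz_with_covariates(
    cohort: Cohort,
    covariates=DEFAULT_COVARIATES,
    placement: str = "log_k",
    re_spec: RandomEffectSpec | None = None,
    config: FitConfig | None = None,
) -> AssociationResult:
    """Joint Gompertz mixed-model fit with all requested risk factors.

    All covariates enter linearly on the ``placement`` parameter's fixed
    effect in one multivariable model. Coefficients and SEs for
    standardized continuous covariates are reported back-transformed to
    per-natural-unit scale.
    """
    used, design, _center, scale, n_dropped = build_covariate_design(
        cohort, covariates, placement
    )
    if re_spec is None:
        re_spec = RandomEffectSpec(("log_v0", "log_k"))
    fit = fit_nlme("gompertz", re_spec, used, config=config, covariate_design=design)
    effects = []
    for j, name in enumerate(design.names):
        coef = fit.theta_hat[name] / scale[j]
        se = fit.se_theta[name] / scale[j]
        effects.append(wald_summary(name, coef, se))
    return AssociationResult(
        effects=tuple(effects),
        fit=fit,
        n_patients_used=used.n_patients,
        n_patients_dropped=n_dropped,
        placement=placement,
    )


def sensitivity_excluding_multifocal(
    cohort: Cohort,
    covariates=None,
    placement: str = "log_k",
    re_spec: RandomEffectSpec | None = None,
    config: FitConfig | None = None,
) -> tuple[AssociationResult, AssociationResult]:
    """Full-cohort fit next to a refit excluding multifocal patients.

    The sensitivity fit drops the multifocality covariate itself (it is
    constant once multifocal patients are removed).
    """
    if covariates is None:
        covariates = DEFAULT_COVARIATES
    full = fit_gompertz_with_covariates(
        cohort, covariates, placement, re_spec, config
    )
    reduced_cohort = exclude_multifocal(cohort)
    reduced_covs = tuple(c for c in covariates if c != "multifocal")
    if reduced_cohort.n_patients == cohort.n_patients and "multifocal" in covariates:
        reduced_covs = covariates  # nothing excluded; identical refit
    sensitivity = fit_gompertz_with_covariates(
        reduced_cohort, reduced_covs, placement, re_spec, config
    )
    return full, sensitivity


def effects_table(result: AssociationResult) -> pd.DataFrame:
    """Risk-factor table: coefficient, SE, z, p, 95% CI per covariate."""
    return pd.DataFrame(
        [
            {
                "variable": e.name,
                "coef": e.coef,
                "se": e.se,
                "z": e.z,
                "p": e.p,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
            }
            for e in result.effects
        ]
    )
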