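"""Longitudinal tumor-volume cohort: data model, CSV IO, inclusion, summaries.

A cohort is a set of patients, each with a time-ordered series of MRI volume
measurements (one total tumor volume per scan; multifocal tumors are already
summed into a single series) and time-invariant covariates. Time is measured
in months since each patient's first scan, so every series starts at t = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScanObservation",
    "PatientCovariates",
    "Patient",
    "Cohort",
    "CohortError",
    "DEFAULT_SCHEMA",
    "read_cohort",
    "write_cohort",
    "apply_inclusion_criteria",
    "summarize_cohort",
]

DAYS_PER_MONTH = 30.4375  # mean Gregorian month, used when dates are supplied

T2_CATEGORIES = ("hypointense", "isointense", "hyperintense")

DEFAULT_SCHEMA: dict[str, str] = {
    "patient_id": "patient_id",
    "t_months": "t_months",
    "volume_ml": "volume_ml",
    "sex": "sex",
    "age_at_first_scan": "age_at_first_scan",
    "multifocal": "multifocal",
    "t2_category": "t2_category",
    "edema": "edema",
}

REQUIRED_COLUMNS = ("patient_id", "t_months", "volume_ml")


class CohortError(ValueError):
    """Invalid cohort data (bad volumes, duplicate scans, schema problems)."""


@dataclass(frozen=True)
class ScanObservation:
    """One MRI measurement: months since first scan and total volume in mL."""

    patient_id: str
    t_months: float
    volume_ml: float

    def __post_init__(self):
        if not self.volume_ml > 0:
            raise CohortError(
                f"patient {self.patient_id}: volume must be > 0 mL, "
                f"got {self.volume_ml} at t={self.t_months}"
            )
        if self.t_months < 0:
            raise CohortError(
                f"patient {self.patient_id}: t_months must be >= 0, got {self.t_months}"
            )


@dataclass(frozen=True)
class PatientCovariates:
    """Time-invariant patient covariates; T2 category and edema may be missing."""

    sex: int | None = None
    age_at_first_scan: float | None = None
    multifocal: bool | None = None
    t2_category: str | None = None
    edema: bool | None = None
    followup_months: float | None = None

    def __post_init__(self):
        if self.t2_category is not None and self.t2_category not in T2_CATEGORIES:
            raise CohortError(
                f"t2_category must be one of {T2_CATEGORIES} or None, "
                f"got {self.t2_category!r}"
            )


@dataclass(frozen=True)
class Patient:
    """One patient: covariates plus a strictly time-ordered scan series."""

    patient_id: str
    covariates: PatientCovariates
    scans: tuple[ScanObservation, ...]

    def __post_init__(self):
        if len(self.scans) < 1:
            raise CohortError(f"patient {self.patient_id}: needs at least one scan")
        times = [s.t_months for s in self.scans]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise CohortError(
                f"patient {self.patient_id}: scan times must be strictly increasing"
            )
        if times[0] != 0.0:
            raise CohortError(
                f"patient {self.patient_id}: first scan must be at t=0, got {times[0]}"
            )

    @property
    def n_scans(self) -> int:
        return len(self.scans)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t_months for s in self.scans])

    @property
    def volumes(self) -> np.ndarray:
        return np.array([s.volume_ml for s in self.scans])

    @property
    def span_months(self) -> float:
        return self.scans[-1].t_months

    @property
    def baseline_volume(self) -> float:
        return self.scans[0].volume_ml


@dataclass(frozen=True)
class Cohort:
    """A collection of patients with unique ids."""

    patients: tuple[Patient, ...] = field(default_factory=tuple)

    def __post_init__(self):
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortError(f"duplicate patient ids: {dupes}")

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_scans(self) -> int:
        return sum(p.n_scans for p in self.patients)

    def __iter__(self):
        return iter(self.patients)

    def __len__(self) -> int:
        return len(self.patients)


# ---------------------------------------------------------------------------
# CSV IO


def _parse_bool(value) -> bool | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in {"1", "true", "yes"}:
        return True
    if s in {"0", "false", "no"}:
        return False
    try:
        return bool(int(float(s)))
    except ValueError:
        raise CohortError(f"cannot parse boolean value {value!r}") from None


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value)) or value == ""


def read_cohort(path, schema: dict[str, str] | None = None) -> Cohort:
    """Read a long-format per-scan CSV into a :class:`Cohort`.

    One row per scan. Required columns (after applying the ``schema``
    column-name map): patient_id, t_months, volume_ml. Optional covariate
    columns: sex, age_at_first_scan, multifocal, t2_category, edema.
    Rows are grouped by patient and sorted by time; times are re-anchored so
    each patient's first scan is at t = 0. Covariates are taken from the
    first row of each patient and checked constant within the patient.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path, dtype={colmap["patient_id"]: str})
    for key in REQUIRED_COLUMNS:
        if colmap[key] not in df.columns:
            raise CohortError(f"missing required column {colmap[key]!r} in {path}")

    patients = []
    for pid, grp in df.groupby(colmap["patient_id"], sort=True):
        grp = grp.sort_values(colmap["t_months"]).reset_index(drop=True)
        times = grp[colmap["t_months"]].to_numpy(dtype=float)
        vols = grp[colmap["volume_ml"]].to_numpy(dtype=float)
        if np.any(vols <= 0) or np.any(~np.isfinite(vols)):
            bad = int(np.flatnonzero((vols <= 0) | ~np.isfinite(vols))[0])
            raise CohortError(
                f"patient {pid}: non-positive or non-finite volume "
                f"{vols[bad]!r} in row {bad} of the patient's series"
            )
        if len(np.unique(times)) != len(times):
            raise CohortError(f"patient {pid}: duplicate (patient, time) pair")
        times = times - times[0]

        cov_kwargs: dict = {}
        for cov in ("sex", "age_at_first_scan", "multifocal", "t2_category", "edema"):
            col = colmap.get(cov)
            if col is None or col not in grp.columns:
                continue
            values = grp[col]
            non_missing = values[~values.apply(_is_missing)]
            if non_missing.nunique() > 1:
                raise CohortError(
                    f"patient {pid}: covariate {cov!r} is not constant "
                    f"within the patient: {sorted(non_missing.unique())}"
                )
            raw = None if non_missing.empty else non_missing.iloc[0]
            if raw is None:
                cov_kwargs[cov] = None
            elif cov in ("multifocal", "edema"):
                cov_kwargs[cov] = _parse_bool(raw)
            elif cov == "sex":
                cov_kwargs[cov] = int(float(raw))
            elif cov == "age_at_first_scan":
                cov_kwargs[cov] = float(raw)
            else:
                cov_kwargs[cov] = str(raw)
        cov_kwargs["followup_months"] = float(times[-1]) if times[-1] > 0 else None
        scans = tuple(
            ScanObservation(str(pid), float(t), float(v)) for t, v in zip(times, vols)
        )
        patients.append(Patient(str(pid), PatientCovariates(**cov_kwargs), scans))
    return Cohort(tuple(patients))


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    """Flatten a cohort to the long-format one-row-per-scan table."""
    rows = []
    for patient in cohort:
        c = patient.covariates
        for scan in patient.scans:
            rows.append(
                {
                    "patient_id": patient.patient_id,
                    "t_months": scan.t_months,
                    "volume_ml": scan.volume_ml,
                    "sex": c.sex,
                    "age_at_first_scan": c.age_at_first_scan,
                    "multifocal": None if c.multifocal is None else int(c.multifocal),
                    "t2_category": c.t2_category,
                    "edema": None if c.edema is None else int(c.edema),
                }
            )
    return pd.DataFrame(
        rows, columns=list(DEFAULT_SCHEMA)
    )


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort to long-format CSV; inverse of :func:`read_cohort`."""
    cohort_to_frame(cohort).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Inclusion and summaries


def apply_inclusion_criteria(
    cohort: Cohort, min_scans: int = 3, min_span_months: float = 6.0
) -> tuple[Cohort, pd.DataFrame]:
    """Apply the study inclusion criteria, returning (kept, exclusion log).

    A patient is retained when they have at least ``min_scans`` scans and the
    first-to-last scan span is at least ``min_span_months`` (both boundaries
    inclusive). The log has one row per excluded patient with the reason.
    """
    kept, log_rows = [], []
    for patient in cohort:
        if patient.n_scans < min_scans:
            log_rows.append(
                {
                    "patient_id": patient.patient_id,
                    "reason": "too few scans",
                    "n_scans": patient.n_scans,
                    "span_months": patient.span_months,
                }
            )
        elif patient.span_months < min_span_months:
            log_rows.append(
                {
                    "patient_id": patient.patient_id,
                    "reason": "span below minimum",
                    "n_scans": patient.n_scans,
                    "span_months": patient.span_months,
                }
            )
        else:
            kept.append(patient)
    log = pd.DataFrame(
        log_rows, columns=["patient_id", "reason", "n_scans", "span_months"]
    )
    return Cohort(tuple(kept)), log


def _mir(values) -> dict:
    """Median, IQR and range of a sequence."""
    arr = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return {
        "median": float(med),
        "iqr": float(q3 - q1),
        "min": float(arr.min()),
        "max": float(arr.max()),
    }


def summarize_cohort(cohort: Cohort, growth_cutoff: float = 0.15) -> dict:
    """Descriptive cohort summary in the style of a patient-characteristics table.

    Counts, per-patient scan numbers, age, baseline volume and follow-up as
    median (IQR; range), covariate proportions among non-missing, and
    growth/no-change/shrinkage counts at the given relative-change cutoff
    (patients with a single scan are not classifiable and are skipped).
    """
    if cohort.n_patients == 0:
        raise CohortError("cannot summarize an empty cohort")
    from .measurement import classify_cohort  # local import avoids a cycle

    summary: dict = {
        "n_patients": cohort.n_patients,
        "n_scans": cohort.n_scans,
        "scans_per_patient": _mir([p.n_scans for p in cohort]),
        "baseline_volume_ml": _mir([p.baseline_volume for p in cohort]),
        "followup_months": _mir([p.span_months for p in cohort]),
    }
    ages = [
        p.covariates.age_at_first_scan
        for p in cohort
        if p.covariates.age_at_first_scan is not None
    ]
    if ages:
        summary["age_at_first_scan"] = _mir(ages)

    for cov in ("multifocal", "edema"):
        values = [getattr(p.covariates, cov) for p in cohort]
        known = [v for v in values if v is not None]
        if known:
            summary[f"{cov}_proportion"] = sum(known) / len(known)
            summary[f"{cov}_n_known"] = len(known)
    t2 = [p.covariates.t2_category for p in cohort if p.covariates.t2_category]
    if t2:
        summary["t2_proportions"] = {
            cat: t2.count(cat) / len(t2) for cat in T2_CATEGORIES
        }
        summary["t2_n_known"] = len(t2)
    sexes = [p.covariates.sex for p in cohort if p.covariates.sex is not None]
    if sexes:
        summary["sex_proportion"] = float(np.mean(sexes))

    classifiable = Cohort(tuple(p for p in cohort if p.n_scans >= 2))
    if classifiable.n_patients:
        result = classify_cohort(classifiable, cutoff=growth_cutoff)
        summary["growth_classes"] = {
            "counts": result.counts,
            "proportions": result.proportions,
        }
    return summary


def exclude_multifocal(cohort: Cohort) -> Cohort:
    """Drop patients flagged multifocal (missing multifocality is retained)."""
    return Cohort(
        tuple(p for p in cohort if p.covariates.multifocal is not True)
    )
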