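"""Relative volume change, +/-15% growth classification, and the bootstrap
margin-of-error procedure for repeated tumor segmentations.

Serial volumetry of small tumors carries a non-trivial measurement error, so
a tumor is only called grown (or shrunk) when the first-to-last relative
volume change clears a cutoff — 15% by default, chosen because the upper
bootstrap confidence limit of the typical segmentation error in repeated
measurements lies near that value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort

__all__ = [
    "GrowthClass",
    "GrowthClassification",
    "CohortClassification",
    "MarginOfErrorEstimate",
    "relative_change",
    "classify_growth",
    "classify_cohort",
    "pairwise_error",
    "bootstrap_margin_of_error",
]

GROWTH_CLASSES = ("growth", "no_change", "shrinkage")


@dataclass(frozen=True)
class GrowthClassification:
    """Growth class of one volume series with the relative change behind it."""

    label: str
    rel_change: float


# Back-compat alias used in type hints elsewhere
GrowthClass = GrowthClassification


@dataclass(frozen=True)
class CohortClassification:
    """Per-class counts and proportions plus the per-patient table."""

    counts: dict
    proportions: dict
    per_patient: pd.DataFrame
    cutoff: float

    @property
    def n(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class MarginOfErrorEstimate:
    """Bootstrap estimate of the median relative segmentation error."""

    median_error: float
    ci_low: float
    ci_high: float
    n_pairs: int
    B: int
    seed: int
    ci_level: float
    replicates: np.ndarray = field(repr=False, compare=False, default=None)


def relative_change(v_first: float, v_last: float) -> float:
    """Relative volume change (v_last - v_first) / v_first."""
    if not v_first > 0:
        raise ValueError(f"first volume must be > 0, got {v_first}")
    return (v_last - v_first) / v_first


def classify_growth(rel_change: float, cutoff: float = 0.15) -> GrowthClassification:
    """Classify a relative change as growth / no_change / shrinkage.

    The boundary is inclusive: a change of exactly +cutoff counts as growth
    and exactly -cutoff as shrinkage ("15% or more").
    """
    if not cutoff > 0:
        raise ValueError(f"cutoff must be > 0, got {cutoff}")
    if rel_change >= cutoff:
        label = "growth"
    elif rel_change <= -cutoff:
        label = "shrinkage"
    else:
        label = "no_change"
    return GrowthClassification(label, float(rel_change))


def classify_cohort(cohort: Cohort, cutoff: float = 0.15) -> CohortClassification:
    """Classify every patient on first-vs-last scan volume.

    Every patient needs at least two scans. Counts always sum to the number
    of patients and proportions to 1.
    """
    rows = []
    for patient in cohort:
        if patient.n_scans < 2:
            raise ValueError(
                f"patient {patient.patient_id} has a single scan; "
                "growth cannot be classified"
            )
        rc = relative_change(patient.scans[0].volume_ml, patient.scans[-1].volume_ml)
        cls = classify_growth(rc, cutoff=cutoff)
        rows.append(
            {
                "patient_id": patient.patient_id,
                "v_first": patient.scans[0].volume_ml,
                "v_last": patient.scans[-1].volume_ml,
                "rel_change": cls.rel_change,
                "label": cls.label,
            }
        )
    table = pd.DataFrame(rows)
    counts = {c: int((table["label"] == c).sum()) for c in GROWTH_CLASSES}
    n = len(table)
    assert sum(counts.values()) == n
    proportions = {c: counts[c] / n for c in GROWTH_CLASSES}
    return CohortClassification(counts, proportions, table, cutoff)


def pairwise_error(v_a, v_b) -> np.ndarray:
    """Symmetric relative difference |v_a - v_b| / mean(v_a, v_b).

    Symmetric in the two measurements so that neither segmentation is
    designated as the truth; scale-invariant.
    """
    a = np.asarray(v_a, dtype=float)
    b = np.asarray(v_b, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("volumes must be positive")
    return np.abs(a - b) / ((a + b) / 2.0)


def bootstrap_margin_of_error(
    pairs,
    B: int = 10_000,
    ci_level: float = 0.95,
    seed: int = 0,
) -> MarginOfErrorEstimate:
    """Percentile-bootstrap estimate of the median relative segmentation error.

    ``pairs`` is a table (DataFrame with columns v_a/v_b, or an (n, 2)
    array) of repeated volume measurements of the same tumors. The per-pair
    error is the symmetric relative difference; the statistic is its median
    over pairs; the confidence interval is the percentile interval of the
    statistic over ``B`` resamples of the n pairs with replacement.
    """
    if isinstance(pairs, pd.DataFrame):
        arr = pairs[["v_a", "v_b"]].to_numpy(dtype=float)
    else:
        arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) table of repeated volumes")
    n = arr.shape[0]
    if n < 2:
        raise ValueError("need at least 2 measurement pairs")
    if B < 1:
        raise ValueError("B must be >= 1")
    errors = pairwise_error(arr[:, 0], arr[:, 1])
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    replicates = np.median(errors[idx], axis=1)
    alpha = 1.0 - ci_level
    lo, hi = np.percentile(replicates, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return MarginOfErrorEstimate(
        median_error=float(np.median(errors)),
        ci_low=float(lo),
        ci_high=float(hi),
        n_pairs=n,
        B=B,
        seed=seed,
        ci_level=ci_level,
        replicates=replicates,
    )
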