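import numpy as np
import pytest

from meningrowth.cohort import Cohort, Patient, PatientCovariates, ScanObservation


def make_patient(pid, times, volumes, **cov):
    scans = tuple(
        ScanObservation(pid, float(t), float(v)) for t, v in zip(times, volumes)
    )
    cov.setdefault(
        "followup_months", float(times[-1]) if float(times[-1]) > 0 else None
    )
    return Patient(pid, PatientCovariates(**cov), scans)


def make_cohort(series, **cov):
    """Build a cohort from {pid: (times, volumes)} mappings."""
    return Cohort(
        tuple(make_patient(pid, t, v, **cov) for pid, (t, v) in series.items())
    )


@pytest.fixture
def two_patient_cohort():
    return make_cohort(
        {
            "A": ([0.0, 12.0, 24.0], [2.0, 2.5, 3.1]),
            "B": ([0.0, 6.0, 18.0], [1.0, 1.1, 0.9]),
        },
        sex=1,
        age_at_first_scan=60.0,
        multifocal=False,
        t2_category="hypointense",
        edema=False,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
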