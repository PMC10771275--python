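"""Cohort data model, CSV round trips, inclusion filtering and summaries."""

import numpy as np
import pandas as pd
import pytest

from meningrowth.cohort import (
    Cohort,
    CohortError,
    apply_inclusion_criteria,
    read_cohort,
    summarize_cohort,
    write_cohort,
)

from conftest import make_cohort, make_patient


def test_round_trip_identity(two_patient_cohort, tmp_path):
    path = tmp_path / "cohort.csv"
    write_cohort(two_patient_cohort, path)
    assert read_cohort(path) == two_patient_cohort


def test_round_trip_preserves_missing_covariates(tmp_path):
    cohort = make_cohort(
        {"A": ([0, 6, 13], [1.0, 1.2, 1.4])}, edema=None, t2_category=None, sex=0
    )
    path = tmp_path / "c.csv"
    write_cohort(cohort, path)
    back = read_cohort(path)
    assert back.patients[0].covariates.edema is None
    assert back.patients[0].covariates.t2_category is None
    assert back == cohort


def test_empty_cohort_writes_header_only(tmp_path):
    path = tmp_path / "empty.csv"
    write_cohort(Cohort(()), path)
    text = path.read_text().strip().splitlines()
    assert len(text) == 1 and text[0].startswith("patient_id,")
    assert read_cohort(path).n_patients == 0


def test_read_sorts_and_reanchors_times(tmp_path):
    path = tmp_path / "shuffled.csv"
    pd.DataFrame(
        {
            "patient_id": ["A", "A", "A"],
            "t_months": [17.0, 5.0, 11.0],
            "volume_ml": [3.0, 1.0, 2.0],
        }
    ).to_csv(path, index=False)
    cohort = read_cohort(path)
    patient = cohort.patients[0]
    assert list(patient.times) == [0.0, 6.0, 12.0]
    assert list(patient.volumes) == [1.0, 2.0, 3.0]


@pytest.mark.parametrize(
    "frame,match",
    [
        (pd.DataFrame({"patient_id": ["A"], "t_months": [0.0]}), "missing required"),
        (
            pd.DataFrame(
                {"patient_id": ["A", "A"], "t_months": [0, 6], "volume_ml": [1.0, 0.0]}
            ),
            "non-positive",
        ),
        (
            pd.DataFrame(
                {"patient_id": ["A", "A"], "t_months": [3, 3], "volume_ml": [1.0, 1.1]}
            ),
            "duplicate",
        ),
        (
            pd.DataFrame(
                {
                    "patient_id": ["A", "A"],
                    "t_months": [0, 6],
                    "volume_ml": [1.0, 1.1],
                    "sex": [0, 1],
                }
            ),
            "not constant",
        ),
    ],
)
def test_read_errors(tmp_path, frame, match):
    path = tmp_path / "bad.csv"
    frame.to_csv(path, index=False)
    with pytest.raises(CohortError, match=match):
        read_cohort(path)


def test_schema_mapping(tmp_path):
    path = tmp_path / "mapped.csv"
    pd.DataFrame(
        {"id": ["A", "A", "A"], "months": [0, 6, 12], "vol": [1.0, 1.5, 2.0]}
    ).to_csv(path, index=False)
    cohort = read_cohort(
        path, schema={"patient_id": "id", "t_months": "months", "volume_ml": "vol"}
    )
    assert cohort.n_patients == 1 and cohort.n_scans == 3


def test_invariants_rejected():
    with pytest.raises(CohortError):
        make_patient("A", [0, 6, 6], [1, 2, 3])  # non-increasing times
    with pytest.raises(CohortError):
        make_patient("A", [1, 6], [1, 2])  # first scan not at t=0
    with pytest.raises(CohortError):
        make_cohort({"A": ([0], [1.0])}).patients  # fine
        Cohort((make_patient("A", [0], [1.0]), make_patient("A", [0], [2.0])))


class TestInclusion:
    def test_too_few_scans(self):
        cohort = make_cohort({"A": ([0, 8], [1, 2]), "B": ([0, 4, 9], [1, 2, 3])})
        kept, log = apply_inclusion_criteria(cohort)
        assert [p.patient_id for p in kept] == ["B"]
        assert log.iloc[0]["reason"] == "too few scans"

    @pytest.mark.parametrize("span,included", [(5.9, False), (6.0, True)])
    def test_span_boundary_inclusive(self, span, included):
        cohort = make_cohort({"A": ([0, span / 2, span], [1, 2, 3])})
        kept, log = apply_inclusion_criteria(cohort)
        assert (kept.n_patients == 1) is included
        if not included:
            assert log.iloc[0]["reason"] == "span below minimum"

    def test_idempotent(self):
        cohort = make_cohort(
            {
                "A": ([0, 8], [1, 2]),
                "B": ([0, 4, 9], [1, 2, 3]),
                "C": ([0, 2, 5], [1, 2, 3]),
            }
        )
        once, _ = apply_inclusion_criteria(cohort)
        twice, log2 = apply_inclusion_criteria(once)
        assert twice == once and log2.empty


class TestSummary:
    def test_hand_computable(self):
        cohort = make_cohort(
            {
                "A": ([0, 12], [1.0, 2.0]),
                "B": ([0, 12], [2.0, 2.1]),
                "C": ([0, 12], [4.0, 2.0]),
            }
        )
        s = summarize_cohort(cohort)
        assert s["baseline_volume_ml"]["median"] == 2.0
        assert s["baseline_volume_ml"]["min"] == 1.0
        assert s["baseline_volume_ml"]["max"] == 4.0
        assert s["growth_classes"]["counts"] == {
            "growth": 1,
            "no_change": 1,
            "shrinkage": 1,
        }

    def test_single_patient_degenerate(self):
        s = summarize_cohort(make_cohort({"A": ([0, 10], [1.5, 1.6])}))
        assert s["followup_months"] == {
            "median": 10.0,
            "iqr": 0.0,
            "min": 10.0,
            "max": 10.0,
        }

    def test_matches_brute_force(self, rng):
        series = {}
        for i in range(17):
            n = rng.integers(2, 7)
            t = np.concatenate([[0.0], np.sort(rng.uniform(1, 100, n - 1))])
            v = rng.uniform(0.2, 30, n)
            series[f"P{i:02d}"] = (t, v)
        cohort = make_cohort(series)
        s = summarize_cohort(cohort)
        baselines = sorted(v[0] for _, v in (series[k] for k in sorted(series)))
        assert s["baseline_volume_ml"]["median"] == pytest.approx(
            float(np.median(baselines))
        )
        q1, q3 = np.percentile(baselines, [25, 75])
        assert s["baseline_volume_ml"]["iqr"] == pytest.approx(float(q3 - q1))

    def test_empty_cohort_rejected(self):
        with pytest.raises(CohortError):
            summarize_cohort(Cohort(()))
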