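"""Cohort rules on hand-built toy patients, plus set-level filter properties."""

import datetime

import numpy as np
import pytest

from tsann.cohort import (
    apply_inclusion_exclusion,
    assign_label,
    find_exacerbation_date,
    find_index_date,
    prediction_date,
)
from conftest import day, make_patient


class TestIndexDate:
    def test_diagnosis_with_same_day_asthma_medication(self, med_classes):
        p = make_patient([(0, ["493.90"], ["fluticasone"])])
        assert find_index_date(p, med_classes) == day(0)

    def test_first_visit_without_medication_is_skipped(self, med_classes):
        p = make_patient([(0, ["493.90"], []), (10, ["493.90"], ["albuterol"])])
        assert find_index_date(p, med_classes) == day(10)

    def test_non_asthma_medication_does_not_qualify(self, med_classes):
        p = make_patient([(0, ["493.90"], ["lisinopril"]), (5, ["493.90"], ["unknown-drug"])])
        assert find_index_date(p, med_classes) is None

    def test_no_asthma_diagnosis_anywhere(self, med_classes):
        p = make_patient([(0, ["401.9"], ["albuterol"])])
        assert find_index_date(p, med_classes) is None


class TestExacerbationDate:
    def test_primary_ed_diagnosis_with_same_day_ocs(self, med_classes):
        p = make_patient([
            (0, ["493.90"], ["albuterol"]),
            (30, [("493.92", 1, "ED")], ["prednisone"]),
        ])
        assert find_exacerbation_date(p, day(0), med_classes) == day(30)

    def test_missing_ocs_fails(self, med_classes):
        p = make_patient([(0, ["493.90"], ["albuterol"]), (30, [("493.92", 1, "ED")], [])])
        assert find_exacerbation_date(p, day(0), med_classes) is None

    def test_outpatient_encounter_fails(self, med_classes):
        p = make_patient([
            (0, ["493.90"], ["albuterol"]),
            (30, [("493.92", 1, "OUTPATIENT")], ["prednisone"]),
        ])
        assert find_exacerbation_date(p, day(0), med_classes) is None

    def test_non_primary_diagnosis_fails(self, med_classes):
        p = make_patient([
            (0, ["493.90"], ["albuterol"]),
            (30, [("493.92", 0, "ED")], ["prednisone"]),
        ])
        assert find_exacerbation_date(p, day(0), med_classes) is None

    def test_inpatient_encounter_qualifies(self, med_classes):
        p = make_patient([
            (0, ["493.90"], ["albuterol"]),
            (40, [("493.01", 1, "INPATIENT")], ["prednisone"]),
        ])
        assert find_exacerbation_date(p, day(0), med_classes) == day(40)


@pytest.mark.parametrize("gap,expected", [(100, 1), (365, 1), (366, 0), (400, 0)])
def test_label_365_day_boundary(gap, expected):
    assert assign_label(day(0), day(gap)) == expected


def test_label_without_exacerbation_is_control():
    assert assign_label(day(0), None) == 0


def test_label_agrees_with_brute_force_on_random_records(med_classes):
    """The composed index/exacerbation/label pipeline matches an exhaustive scan."""
    rng = np.random.default_rng(42)
    for _ in range(50):
        days = np.unique(rng.integers(0, 500, size=rng.integers(2, 8)))
        specs = []
        for d in days:
            dx = []
            if rng.random() < 0.6:
                dx.append(("493.90", int(rng.random() < 0.4),
                           ["ED", "INPATIENT", "OUTPATIENT"][rng.integers(0, 3)]))
            meds = []
            if rng.random() < 0.5:
                meds.append(["albuterol", "prednisone", "lisinopril"][rng.integers(0, 3)])
            specs.append((int(d), dx, meds))
        p = make_patient(specs)
        index = find_index_date(p, med_classes)
        if index is None:
            continue
        exac = find_exacerbation_date(p, index, med_classes)
        # brute force: first visit after index satisfying the exacerbation rule
        brute = None
        for v in p.visits:
            if v.date <= index:
                continue
            ok_dx = any(c.startswith("493") and pr == 1 and e in ("ED", "INPATIENT")
                        for c, pr, e in v.dx_codes)
            ok_med = any(med_classes.get(m) == "OCS" for m in v.med_codes)
            if ok_dx and ok_med:
                brute = v.date
                break
        assert exac == brute
        expected = int(brute is not None and (brute - index).days <= 365)
        assert assign_label(index, exac) == expected


class TestPredictionDate:
    def test_training_case_visit_before_exacerbation(self, med_classes):
        p = make_patient([
            (0, ["493.90"], ["albuterol"]),
            (10, ["401.9"], []), (20, ["401.9"], []), (30, ["401.9"], []),
            (40, [("493.92", 1, "ED")], ["prednisone"]),
        ])
        assert prediction_date(p, day(0), day(40), 1, "training") == day(30)

    def test_testA_fifth_visit_from_index(self, med_classes):
        p = make_patient([(d, ["401.9"], ["albuterol"] if d == 0 else [])
                          for d in (0, 5, 9, 14, 21, 30)])
        assert prediction_date(p, day(0), None, 0, "testA") == day(21)

    def test_testB_penultimate_visit(self, med_classes):
        p = make_patient([(d, ["401.9"], []) for d in (0, 5, 9, 14, 21)])
        assert prediction_date(p, day(0), None, 0, "testB") == day(14)

    def test_testA_excludes_exacerbation_before_fifth_visit(self, med_classes):
        p = make_patient([(d, ["401.9"], []) for d in (0, 5, 9, 14, 21, 30)])
        assert prediction_date(p, day(0), day(14), 1, "testA") is None

    def test_training_control_penultimate_within_365(self, med_classes):
        p = make_patient([(d, ["401.9"], []) for d in (0, 50, 100, 200, 300, 400)])
        # visit at day 400 is outside the 365-day window: penultimate in-window is day 200
        assert prediction_date(p, day(0), None, 0, "training") == day(200)


def _well_formed(pid, n_visits=6, age=40, gender="M"):
    specs = [(0, ["493.90"], ["albuterol"])]
    specs += [(10 * (i + 1), ["401.9"], []) for i in range(n_visits - 1)]
    return make_patient(specs, patient_id=pid, age=age, gender=gender)


class TestInclusionExclusion:
    def test_filter_boundaries_and_audit(self, med_classes):
        patients = [
            _well_formed("ok18", age=18),
            _well_formed("ok80", age=80),
            _well_formed("age17", age=17),
            _well_formed("age81", age=81),
            _well_formed("genderX", gender="X"),
            _well_formed("fourvisits", n_visits=4),
            make_patient([(None, ["493.90"], ["albuterol"]), (5, ["401.9"], [])],
                         patient_id="badtime"),
            make_patient([(0, ["401.9"], [])], patient_id="noasthma"),
        ]
        cohort, audit = apply_inclusion_exclusion(patients, med_classes)
        assert {s.patient.patient_id for s in cohort} == {"ok18", "ok80"}
        assert audit == {
            "age17": "age", "age81": "age", "genderX": "gender",
            "fourvisits": "visits<5", "badtime": "time",
            "noasthma": "no_asthma_index",
        }

    def test_conservation(self, med_classes):
        patients = [_well_formed(f"p{i}", age=15 + i) for i in range(10)]
        cohort, audit = apply_inclusion_exclusion(patients, med_classes)
        assert len(cohort) + len(audit) == len(patients)
        assert set(audit) == {p.patient_id for p in patients} - {s.patient.patient_id for s in cohort}

    def test_relaxing_visit_threshold_is_monotone(self, med_classes):
        patients = [_well_formed(f"p{i}", n_visits=4 + (i % 3)) for i in range(9)]
        kept5, _ = apply_inclusion_exclusion(patients, med_classes, min_visits=5)
        kept4, _ = apply_inclusion_exclusion(patients, med_classes, min_visits=4)
        assert len(kept4) >= len(kept5)

    def test_identity_on_conforming_synthetic_cohort(self, small_cohort):
        assert len(small_cohort["samples"]) == len(small_cohort["records"])

    def test_window_visits_lie_inside_window(self, small_cohort):
        for s in small_cohort["samples"]:
            assert s.index_date <= s.prediction_date
            for v in s.window_visits:
                assert s.index_date <= v.date <= s.prediction_date
            if s.label:
                assert (s.exacerbation_date - s.index_date).days <= 365
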