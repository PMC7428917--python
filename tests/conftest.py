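"""Shared fixtures: toy patients, medication classes, and a small synthetic cohort."""

import datetime

import numpy as np
import pytest

import tsann
from tsann.cohort import PatientRecord, Visit

BASE = datetime.date(2012, 1, 1)

MED_CLASSES = {
    "albuterol": "SABA",
    "fluticasone": "ICS",
    "salmeterol": "LABA",
    "montelukast": "LTRA",
    "ipratropium": "ANTICHOLINERGIC",
    "fluticasone-salmeterol": "ICS_LABA",
    "prednisone": "OCS",
    "lisinopril": "ANTIHYPERTENSIVE",  # never an asthma medication
}


def day(n: int) -> datetime.date:
    return BASE + datetime.timedelta(days=int(n))


def make_patient(visit_specs, patient_id="T1", age=40, gender="M", race="white"):
    """Build a PatientRecord from (day, dx list, med list) tuples.

    dx entries are (code, primary, encounter) triples or bare code strings
    (non-primary outpatient).
    """
    visits = []
    for d, dxs, meds in visit_specs:
        dx = [
            (c, 0, "OUTPATIENT") if isinstance(c, str) else c
            for c in dxs
        ]
        visits.append(Visit(date=None if d is None else day(d), dx_codes=dx, med_codes=list(meds)))
    visits.sort(key=lambda v: (v.date is None, v.date or datetime.date.min))
    return PatientRecord(patient_id=patient_id, age_years=age, gender=gender, race=race, visits=visits)


@pytest.fixture(scope="session")
def med_classes():
    return dict(MED_CLASSES)


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-patient synthetic cohort with one planted factor, fully processed."""
    factor = tsann.PlantedFactor(
        "530.81", effect_logit=5.0, active_window_days=(0, 100),
        carrier_fraction=0.5, occurrence_gap_days=(0, 100),
    )
    config = tsann.SimConfig(n_patients=300, seed=11, planted_factors=[factor])
    sim = tsann.generate_cohort(config)
    mc = dict(zip(tsann.default_med_classes()["generic_name"], tsann.default_med_classes()["class"]))
    records = tsann.cohort.load_patients(sim.patients, sim.events)
    samples, audit = tsann.apply_inclusion_exclusion(records, mc)
    vocab = tsann.build_vocabulary(samples)
    encoded = tsann.encode_cohort(samples, vocab)
    return {
        "sim": sim, "med_classes": mc, "records": records, "samples": samples,
        "audit": audit, "vocab": vocab, "encoded": encoded,
    }
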