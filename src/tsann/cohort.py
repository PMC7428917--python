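"""Retrospective cohort construction for exacerbation risk prediction.

Implements the case-control rules on longitudinal EHR tables:

* **Index date** — the earliest visit carrying an asthma diagnosis
  (ICD-9 ``493.xx``; ICD-10 ``J45.xx`` mapped first) together with at
  least one asthma-class medication (SABA, ICS, LABA, LTRA,
  anticholinergic, or ICS/LABA combination).
* **Exacerbation date** — the earliest visit after the index at which an
  asthma code is the *primary* diagnosis for an ED or inpatient
  encounter and an oral corticosteroid is given the same day.
* **Label** — case if the exacerbation falls within 365 days of the
  index (inclusive), control otherwise.
* **Prediction date** — the visit at which risk is scored: for training
  (and testing set B), the visit before the exacerbation for cases and
  the penultimate in-window visit for controls; for testing set A, the
  fifth visit counting the index visit as the first.
* **Inclusion/exclusion** — adults aged 18–80, male/female gender,
  usable timestamps, and at least five visits in the observed window.

Events sharing a calendar date are grouped into one visit.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import pandas as pd

from .encoding import map_icd10_to_icd9

logger = logging.getLogger(__name__)

__all__ = [
    "Visit",
    "PatientRecord",
    "CohortSample",
    "load_med_classes",
    "load_icd_mapping",
    "load_patients",
    "find_index_date",
    "find_exacerbation_date",
    "assign_label",
    "prediction_date",
    "apply_inclusion_exclusion",
    "write_cohort",
    "ASTHMA_MED_CLASSES",
]

Mode = Literal["training", "testA", "testB"]

#: medication classes whose same-day prescription qualifies an asthma index visit
ASTHMA_MED_CLASSES = frozenset({"SABA", "ICS", "LABA", "LTRA", "ANTICHOLINERGIC", "ICS_LABA"})

LABEL_WINDOW_DAYS = 365  # "within 365 days", inclusive
MIN_VISITS = 5
AGE_RANGE = (18, 80)  # inclusive bounds


@dataclass
class Visit:
    """All events of one patient on one calendar date."""

    date: datetime.date
    dx_codes: list[tuple[str, int, str]] = field(default_factory=list)  # (code, primary, encounter)
    med_codes: list[str] = field(default_factory=list)

    @property
    def n_codes(self) -> int:
        return len(self.dx_codes) + len(self.med_codes)


@dataclass
class PatientRecord:
    patient_id: str
    age_years: int
    gender: str
    race: str
    visits: list[Visit] = field(default_factory=list)  # strictly date-ordered


@dataclass
class CohortSample:
    patient: PatientRecord
    label: int  # 1 = case
    index_date: datetime.date
    exacerbation_date: datetime.date | None
    prediction_date: datetime.date
    window_visits: list[Visit]  # visits in [index_date, prediction_date]


def load_med_classes(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path)
    return dict(zip(df["generic_name"].astype(str), df["class"].astype(str)))


def load_icd_mapping(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path)
    return dict(zip(df["icd10_code"].astype(str), df["icd9_code"].astype(str)))


def _is_asthma_code(code: str) -> bool:
    return code.startswith("493")


def load_patients(
    patients: pd.DataFrame,
    events: pd.DataFrame,
    icd_mapping: Mapping[str, str] | None = None,
) -> list[PatientRecord]:
    """Group dated events into per-patient, calendar-date visits.

    ICD-10 diagnosis codes are mapped to ICD-9 where the mapping table has
    an entry; unmapped codes pass through.  Codes are deduplicated within
    a visit (presence semantics).  Rows with unparseable dates are kept as
    sentinel visits with ``date=None`` so the exclusion filter can flag
    the patient rather than silently dropping data.
    """
    records: dict[str, PatientRecord] = {}
    for row in patients.itertuples(index=False):
        records[str(row.patient_id)] = PatientRecord(
            patient_id=str(row.patient_id),
            age_years=int(row.age_years),
            gender=str(row.gender),
            race=str(row.race),
        )

    parsed = pd.to_datetime(events["date"], errors="coerce")
    visits: dict[tuple[str, datetime.date | None], Visit] = {}
    for i, row in enumerate(events.itertuples(index=False)):
        pid = str(row.patient_id)
        if pid not in records:
            continue
        ts = parsed.iloc[i]
        date = None if pd.isna(ts) else ts.date()
        key = (pid, date)
        if key not in visits:
            visits[key] = Visit(date=date)
        v = visits[key]
        code = str(row.code)
        if row.code_type == "DX":
            if icd_mapping is not None:
                code = map_icd10_to_icd9(code, icd_mapping)
            entry = (code, int(row.primary_dx), str(row.encounter_type))
            if entry not in v.dx_codes:
                v.dx_codes.append(entry)
        else:
            if code not in v.med_codes:
                v.med_codes.append(code)

    for (pid, _date), v in visits.items():
        records[pid].visits.append(v)
    for rec in records.values():
        rec.visits.sort(key=lambda v: (v.date is None, v.date or datetime.date.min))
    return list(records.values())


def find_index_date(
    patient: PatientRecord, med_classes: Mapping[str, str]
) -> datetime.date | None:
    """Earliest visit with an asthma diagnosis and a same-day asthma medication.

    Medications absent from the class mapping are treated as non-asthma
    medications (logged at debug level), not as errors.
    """
    for v in patient.visits:
        if v.date is None:
            continue
        if not any(_is_asthma_code(c) for c, _, _ in v.dx_codes):
            continue
        for med in v.med_codes:
            cls = med_classes.get(med)
            if cls is None:
                logger.debug("medication %r not in class mapping; ignored", med)
            elif cls in ASTHMA_MED_CLASSES:
                return v.date
    return None


def find_exacerbation_date(
    patient: PatientRecord,
    index_date: datetime.date,
    med_classes: Mapping[str, str],
) -> datetime.date | None:
    """Earliest post-index visit with primary asthma dx at ED/inpatient + same-day OCS."""
    for v in patient.visits:
        if v.date is None or v.date <= index_date:
            continue
        severe = any(
            _is_asthma_code(c) and primary == 1 and enc in ("ED", "INPATIENT")
            for c, primary, enc in v.dx_codes
        )
        if not severe:
            continue
        if any(med_classes.get(m) == "OCS" for m in v.med_codes):
            return v.date
    return None


def assign_label(
    index_date: datetime.date, exacerbation_date: datetime.date | None
) -> int:
    """Case (1) iff the exacerbation occurs within 365 days of the index, inclusive."""
    if exacerbation_date is None:
        return 0
    return int((exacerbation_date - index_date).days <= LABEL_WINDOW_DAYS)


def _window_visits(patient: PatientRecord, index_date: datetime.date) -> list[Visit]:
    """Visits within 365 days of the index (inclusive), dated only."""
    end = index_date + datetime.timedelta(days=LABEL_WINDOW_DAYS)
    return [v for v in patient.visits if v.date is not None and index_date <= v.date <= end]


def prediction_date(
    patient: PatientRecord,
    index_date: datetime.date,
    exacerbation_date: datetime.date | None,
    label: int,
    mode: Mode,
) -> datetime.date | None:
    """The visit date at which risk is scored, or None if the mode is undefined.

    training / testB — cases: the visit before the exacerbation date;
    controls: the penultimate visit within the 365-day window.
    testA — the fifth visit starting from the index-date visit; patients
    whose exacerbation precedes the fifth visit yield None (excluded).
    """
    in_window = _window_visits(patient, index_date)
    if mode == "testA":
        if len(in_window) < 5:
            return None
        fifth = in_window[4].date
        if label and exacerbation_date is not None and exacerbation_date <= fifth:
            return None
        return fifth
    # training and testB share the Table-style definition
    if label:
        if exacerbation_date is None:
            return None
        before = [v for v in in_window if v.date < exacerbation_date]
        return before[-1].date if before else None
    if len(in_window) < 2:
        return None
    return in_window[-2].date


def apply_inclusion_exclusion(
    patients: list[PatientRecord],
    med_classes: Mapping[str, str],
    mode: Mode = "training",
    min_visits: int = MIN_VISITS,
) -> tuple[list[CohortSample], dict[str, str]]:
    """Apply the inclusion/exclusion cascade; audit every dropped patient.

    Returns the retained cohort samples and a mapping from dropped
    patient id to the first failing rule, one of ``time``, ``gender``,
    ``age``, ``no_asthma_index``, ``no_prediction_date``, ``visits<5``.
    """
    cohort: list[CohortSample] = []
    audit: dict[str, str] = {}
    for p in patients:
        if any(v.date is None for v in p.visits) or not p.visits:
            audit[p.patient_id] = "time"
            continue
        if p.gender not in ("M", "F"):
            audit[p.patient_id] = "gender"
            continue
        if not (AGE_RANGE[0] <= p.age_years <= AGE_RANGE[1]):
            audit[p.patient_id] = "age"
            continue
        index = find_index_date(p, med_classes)
        if index is None:
            audit[p.patient_id] = "no_asthma_index"
            continue
        exac = find_exacerbation_date(p, index, med_classes)
        label = assign_label(index, exac)
        pred = prediction_date(p, index, exac, label, mode)
        if pred is None:
            audit[p.patient_id] = "no_prediction_date"
            continue
        window = [v for v in p.visits if v.date is not None and index <= v.date <= pred]
        if len(window) < min_visits:
            audit[p.patient_id] = "visits<5"
            continue
        cohort.append(
            CohortSample(
                patient=p,
                label=label,
                index_date=index,
                exacerbation_date=exac,
                prediction_date=pred,
                window_visits=window,
            )
        )
    return cohort, audit


def write_cohort(cohort: list[CohortSample], path: str | Path, mode: Mode) -> Path:
    path = Path(path)
    rows = [
        (s.patient.patient_id, s.label, s.index_date.isoformat(), s.prediction_date.isoformat(), mode)
        for s in cohort
    ]
    pd.DataFrame(rows, columns=["patient_id", "label", "index_date", "prediction_date", "mode"]).to_csv(
        path, index=False
    )
    return path
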