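"""Synthetic EHR cohorts with planted, time-localized risk factors.

Generates patient and event tables that structurally mimic a retrospective
asthma exacerbation cohort: every patient gets an asthma index visit
(diagnosis 493.x plus an asthma-class medication), a sequence of irregularly
spaced follow-up visits carrying background diagnosis/medication codes, and
— for patients sampled as cases — a terminal exacerbation visit (primary
asthma diagnosis at an ED encounter with a same-day oral corticosteroid).

Case/control status is drawn from a logistic model.  "Planted" factor codes
are attached to carrier patients at controlled day-gaps before the
prediction-reference visit; a factor shifts the exacerbation log-odds only
when its occurrence falls inside its active window.  Because the planted
signal and its timing are known exactly, every downstream stage (cohort
rules, encoding, model training, attention-based interpretation) can be
validated against ground truth.
"""

from __future__ import annotations

import dataclasses
import datetime
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PlantedFactor",
    "SimConfig",
    "SyntheticGroundTruth",
    "SyntheticCohort",
    "generate_cohort",
    "write_ehr_tables",
    "read_ehr_tables",
    "default_med_classes",
]

_BASE_DATE = datetime.date(2010, 1, 1)
# latest day (from index) at which the prediction-reference visit may fall,
# leaving room for a post-window visit inside the 365-day bound
_MAX_REF_DAY = 350

GENDERS = ("M", "F")
RACES = ("white", "black", "asian", "other")


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


@dataclass(frozen=True)
class PlantedFactor:
    """A synthetic risk-factor code with a time-localized effect.

    ``effect_logit`` is added to the exacerbation log-odds when the code
    occurs within ``active_window_days`` (a closed interval of day-gaps
    before the prediction-reference date).  ``carrier_fraction`` of
    patients receive one occurrence, placed at a gap drawn uniformly from
    ``occurrence_gap_days`` (defaults to the whole 365-day window) and
    snapped to the patient's nearest visit.
    """

    code: str
    effect_logit: float
    active_window_days: tuple[int, int] = (0, 364)
    carrier_fraction: float = 0.5
    occurrence_gap_days: tuple[int, int] | None = None

    def __post_init__(self):
        a, b = self.active_window_days
        if not (0 <= a <= b <= 365):
            raise ValueError(f"active_window_days must satisfy 0 <= a <= b <= 365, got {self.active_window_days}")
        if not math.isfinite(self.effect_logit):
            raise ValueError("effect_logit must be finite")
        if not (0.0 <= self.carrier_fraction <= 1.0):
            raise ValueError("carrier_fraction must be in [0, 1]")


@dataclass
class SimConfig:
    """Study conditions for the generator.

    Defaults mirror the cohort statistics of the emulated study: about
    1 case per 13 controls and a mean of 5.78 visits (floor 5, matching
    the inclusion rule) in the observed window before the prediction date.
    """

    n_patients: int = 2000
    vocab_dx: int = 80
    vocab_med: int = 40
    mean_visits: float = 5.78
    target_case_fraction: float = 1.0 / 14.0
    planted_factors: list[PlantedFactor] = field(default_factory=list)
    baseline_logit: float | None = None
    visit_gap_mean_days: float = 60.0
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.vocab_dx < 1 or self.vocab_med < 1:
            raise ValueError("vocabulary counts must be >= 1")
        if not (0.0 < self.target_case_fraction < 1.0):
            raise ValueError("target_case_fraction must be in (0, 1)")
        if self.mean_visits < 5:
            raise ValueError("mean_visits must be >= 5 (inclusion floor)")
        if self.visit_gap_mean_days <= 0:
            raise ValueError("visit_gap_mean_days must be positive")
        if self.baseline_logit is None:
            self.baseline_logit = _logit(self.target_case_fraction)


@dataclass
class SyntheticGroundTruth:
    """Per-patient truth emitted alongside the tables; used only by tests."""

    labels: pd.DataFrame          # patient_id, label, logit
    occurrences: pd.DataFrame     # patient_id, code, date, gap_days, active
    case_fraction: float


@dataclass
class SyntheticCohort:
    patients: pd.DataFrame
    events: pd.DataFrame
    ground_truth: SyntheticGroundTruth
    config: SimConfig


def default_med_classes() -> pd.DataFrame:
    """Medication-class mapping covering the classes the cohort rules use."""
    rows = [
        ("albuterol", "SABA"),
        ("levalbuterol", "SABA"),
        ("fluticasone", "ICS"),
        ("budesonide", "ICS"),
        ("salmeterol", "LABA"),
        ("formoterol", "LABA"),
        ("montelukast", "LTRA"),
        ("ipratropium", "ANTICHOLINERGIC"),
        ("fluticasone-salmeterol", "ICS_LABA"),
        ("budesonide-formoterol", "ICS_LABA"),
        ("prednisone", "OCS"),
        ("methylprednisolone", "OCS"),
        ("dexamethasone", "OCS"),
    ]
    return pd.DataFrame(rows, columns=["generic_name", "class"])


def _draw_visit_days(rng: np.random.Generator, n_vis: int, gap_mean: float) -> np.ndarray:
    """Irregular visit days: accumulated exponential gaps truncated to the window."""
    gaps = rng.exponential(gap_mean, size=max(n_vis - 1, 4))
    days = np.concatenate([[0.0], np.cumsum(gaps)])
    if days[4] > _MAX_REF_DAY:  # compress so >=5 visits fit the window
        days = days * (_MAX_REF_DAY / days[4])
    days = days[days <= _MAX_REF_DAY][:n_vis]
    days = np.unique(np.round(days).astype(int))
    if len(days) < 5:  # rounding collisions at tiny gaps: fall back to even spacing
        days = np.round(np.linspace(0, _MAX_REF_DAY, n_vis)).astype(int)
    return days


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Simulate patients and dated DX/MED events with known labels.

    Deterministic given ``config.seed``.  Every patient has at least five
    visits between the index date (first visit, carrying an asthma
    diagnosis plus an asthma medication) and the prediction-reference
    visit, so the downstream inclusion filters pass by construction.
    Cases receive a subsequent exacerbation visit (primary 493.92 at an
    ED encounter with prednisone) and controls a plain trailing visit,
    both within 365 days of the index date.
    """
    rng = np.random.default_rng(config.seed)
    dx_vocab = [f"7{i:02d}.{i % 10}0" for i in range(config.vocab_dx)]
    med_vocab = [f"med{i:03d}" for i in range(config.vocab_med)]
    bg_vocab = [("DX", c) for c in dx_vocab] + [("MED", c) for c in med_vocab]

    pat_rows, ev_rows, lab_rows, occ_rows = [], [], [], []

    for p in range(config.n_patients):
        pid = f"P{p:06d}"
        age = int(rng.integers(18, 81))
        gender = GENDERS[int(rng.integers(0, 2))]
        race = RACES[int(rng.integers(0, 4))]
        start = _BASE_DATE + datetime.timedelta(days=int(rng.integers(0, 1500)))
        pat_rows.append((pid, age, gender, race))

        n_vis = 5 + int(rng.poisson(max(config.mean_visits - 5.0, 0.0)))
        days = _draw_visit_days(rng, n_vis, config.visit_gap_mean_days)
        ref_day = int(days[-1])  # prediction-reference visit

        def add_event(day: int, code_type: str, code: str, primary: int = 0,
                      encounter: str = "OUTPATIENT"):
            date = (start + datetime.timedelta(days=int(day))).isoformat()
            ev_rows.append((pid, date, code_type, code, primary, encounter))
            return date

        # index visit: asthma diagnosis + asthma-class medication
        add_event(days[0], "DX", "493.00")
        add_event(days[0], "MED", "albuterol")

        # background codes on every visit
        for d in days:
            k = 1 + int(rng.poisson(3))
            for j in rng.integers(0, len(bg_vocab), size=k):
                ctype, code = bg_vocab[int(j)]
                add_event(d, ctype, code)

        # planted factors
        logit = float(config.baseline_logit)
        for f in config.planted_factors:
            if rng.random() >= f.carrier_fraction:
                continue
            lo, hi = f.occurrence_gap_days if f.occurrence_gap_days is not None else (0, 364)
            target_gap = int(rng.integers(lo, hi + 1))
            # snap the occurrence to the patient's nearest visit
            day = int(days[np.argmin(np.abs((ref_day - days) - target_gap))])
            gap = ref_day - day
            ctype = "MED" if f.code.upper().startswith("MED") else "DX"
            date = add_event(day, ctype, f.code)
            a, b = f.active_window_days
            active = a <= gap <= b
            if active:
                logit += f.effect_logit
            occ_rows.append((pid, f.code, date, gap, int(active)))

        label = int(rng.random() < _sigmoid(logit))
        lab_rows.append((pid, label, logit))

        # outcome visit after the reference visit, within 365 days of index
        out_day = min(ref_day + 1 + int(rng.integers(0, 14)), 365)
        if label:
            add_event(out_day, "DX", "493.92", primary=1, encounter="ED")
            add_event(out_day, "MED", "prednisone")
        else:
            ctype, code = bg_vocab[int(rng.integers(0, len(bg_vocab)))]
            add_event(out_day, ctype, code)

    patients = pd.DataFrame(pat_rows, columns=["patient_id", "age_years", "gender", "race"])
    events = pd.DataFrame(
        ev_rows,
        columns=["patient_id", "date", "code_type", "code", "primary_dx", "encounter_type"],
    ).sort_values(["patient_id", "date"], kind="stable").reset_index(drop=True)
    labels = pd.DataFrame(lab_rows, columns=["patient_id", "label", "logit"])
    occurrences = pd.DataFrame(
        occ_rows, columns=["patient_id", "code", "date", "gap_days", "active"]
    )
    truth = SyntheticGroundTruth(
        labels=labels,
        occurrences=occurrences,
        case_fraction=float(labels["label"].mean()),
    )
    return SyntheticCohort(patients=patients, events=events, ground_truth=truth, config=config)


def write_ehr_tables(cohort: SyntheticCohort, path: str | Path) -> dict[str, Path]:
    """Write patients/events/ground-truth/medication-class tables as CSV."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    out = {
        "patients": path / "patients.csv",
        "events": path / "events.csv",
        "ground_truth_labels": path / "ground_truth_labels.csv",
        "ground_truth_occurrences": path / "ground_truth_occurrences.csv",
        "med_classes": path / "med_classes.csv",
    }
    cohort.patients.to_csv(out["patients"], index=False)
    cohort.events.to_csv(out["events"], index=False)
    cohort.ground_truth.labels.to_csv(out["ground_truth_labels"], index=False)
    cohort.ground_truth.occurrences.to_csv(out["ground_truth_occurrences"], index=False)
    default_med_classes().to_csv(out["med_classes"], index=False)
    return out


def read_ehr_tables(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read back the patients and events tables written by :func:`write_ehr_tables`."""
    path = Path(path)
    patients = pd.read_csv(path / "patients.csv", dtype={"patient_id": str})
    events = pd.read_csv(
        path / "events.csv",
        dtype={"patient_id": str, "code": str, "primary_dx": int},
    )
    return patients, events
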