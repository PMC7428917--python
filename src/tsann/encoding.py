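"""Vocabulary construction and integer/elapsed-time encoding of visit sequences.

Each cohort sample becomes an :class:`EncodedSequence`: one entry per
visit holding the deduplicated integer code indices and the whole-day gap
between the visit and the prediction date (clamped to the 365-bin time
vocabulary, indices 0..364).  Visits are ordered oldest first (decreasing
gap); the prediction-date visit has gap 0 and additionally carries the
patient's demographic tokens (age decade, gender, race), which enter the
model only at that visit.

Diagnosis and medication codes are namespaced (``DX:...`` / ``MED:...``)
so the two code systems cannot collide in one vocabulary.  Index 0 is
reserved for padding and index 1 for out-of-vocabulary codes; the
vocabulary is built from the training split only, with codes sorted
lexicographically so the mapping is stable across runs.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import CohortSample

logger = logging.getLogger(__name__)

__all__ = [
    "PAD_INDEX",
    "UNK_INDEX",
    "MAX_GAP",
    "Vocabulary",
    "EncodedSequence",
    "map_icd10_to_icd9",
    "build_vocabulary",
    "elapsed_gap",
    "encode_patient",
    "encode_cohort",
    "write_encoded",
    "read_encoded",
]

PAD_INDEX = 0
UNK_INDEX = 1
MAX_GAP = 364  # V_t = 365 day-gap bins, indices 0..364
DEFAULT_MAX_VISITS = 50


def map_icd10_to_icd9(code: str, mapping: Mapping[str, str] | None) -> str:
    """Map an ICD-10 code to ICD-9 where the table has an entry.

    Codes absent from the table (including codes already in ICD-9) pass
    through unchanged; genuinely unmapped ICD-10-looking codes are logged.
    """
    if mapping is None:
        return code
    mapped = mapping.get(code)
    if mapped is not None:
        return mapped
    if code[:1].isalpha() and code[:1].upper() not in ("V", "E"):
        # ICD-9 has only V/E alphanumeric prefixes; anything else looks ICD-10
        logger.warning("ICD-10 code %r has no ICD-9 mapping; kept as-is", code)
    return code


@dataclass
class Vocabulary:
    """Bijective code-to-index mapping with reserved padding/unknown slots."""

    code_to_index: dict[str, int]
    index_to_code: dict[int, str] = field(init=False)

    def __post_init__(self):
        self.index_to_code = {i: c for c, i in self.code_to_index.items()}

    @property
    def size(self) -> int:
        """V_c: number of known codes plus the PAD and UNK slots."""
        return len(self.code_to_index) + 2

    def index(self, code: str) -> int:
        return self.code_to_index.get(code, UNK_INDEX)

    def code(self, index: int) -> str:
        if index == PAD_INDEX:
            return "<PAD>"
        if index == UNK_INDEX:
            return "<UNK>"
        return self.index_to_code[index]


@dataclass
class EncodedSequence:
    patient_id: str
    label: int
    visits: list[tuple[list[int], int]]  # (code indices, day gap), oldest first


def _demographic_tokens(age_years: int, gender: str, race: str) -> list[str]:
    return [f"AGE_{(age_years // 10) * 10}", f"GENDER_{gender}", f"RACE_{race}"]


def _visit_tokens(visit) -> list[str]:
    toks = [f"DX:{c}" for c, _p, _e in visit.dx_codes] + [f"MED:{m}" for m in visit.med_codes]
    seen: set[str] = set()
    out = []
    for t in toks:
        if t not in seen:
            seen.add(t)
            out.append(t)
    return out


def build_vocabulary(cohort: Iterable["CohortSample"]) -> Vocabulary:
    """Collect all code and demographic tokens of the training cohort.

    Tokens are sorted lexicographically before indexing, so the mapping
    is a pure function of the token set.
    """
    tokens: set[str] = set()
    n = 0
    for sample in cohort:
        n += 1
        for v in sample.window_visits:
            tokens.update(_visit_tokens(v))
        tokens.update(
            _demographic_tokens(sample.patient.age_years, sample.patient.gender, sample.patient.race)
        )
    if n == 0:
        raise ValueError("cannot build a vocabulary from an empty cohort")
    return Vocabulary({c: i + 2 for i, c in enumerate(sorted(tokens))})


def elapsed_gap(visit_date: datetime.date, prediction_date: datetime.date) -> int:
    """Whole days between a visit and the prediction date, clamped to [0, 364]."""
    delta = (prediction_date - visit_date).days
    if delta < 0:
        raise ValueError(
            f"visit {visit_date} falls after the prediction date {prediction_date}"
        )
    return min(delta, MAX_GAP)


def encode_patient(
    sample: "CohortSample",
    vocab: Vocabulary,
    max_visits: int = DEFAULT_MAX_VISITS,
) -> EncodedSequence:
    """Convert one cohort sample into the model's integer/time representation."""
    if not sample.window_visits:
        raise ValueError(f"patient {sample.patient.patient_id} has an empty observed window")
    visits: list[tuple[list[int], int]] = []
    for v in sample.window_visits:
        gap = elapsed_gap(v.date, sample.prediction_date)
        idxs = [vocab.index(t) for t in _visit_tokens(v)]
        visits.append((idxs, gap))
    visits = visits[-max_visits:]  # keep the most recent
    demo = [
        vocab.index(t)
        for t in _demographic_tokens(
            sample.patient.age_years, sample.patient.gender, sample.patient.race
        )
    ]
    codes, gap = visits[-1]
    visits[-1] = (codes + [i for i in demo if i not in codes], gap)
    return EncodedSequence(
        patient_id=sample.patient.patient_id, label=sample.label, visits=visits
    )


def encode_cohort(
    cohort: Iterable["CohortSample"],
    vocab: Vocabulary,
    max_visits: int = DEFAULT_MAX_VISITS,
) -> list[EncodedSequence]:
    return [encode_patient(s, vocab, max_visits) for s in cohort]


def write_encoded(encoded: Iterable[EncodedSequence], path: str | Path) -> Path:
    """One record per line: ``patient_id<TAB>label<TAB>gap:idx,idx;gap:idx...``"""
    path = Path(path)
    with open(path, "w") as fh:
        for seq in encoded:
            groups = ";".join(
                f"{gap}:" + ",".join(str(i) for i in idxs) for idxs, gap in seq.visits
            )
            fh.write(f"{seq.patient_id}\t{seq.label}\t{groups}\n")
    return path


def read_encoded(path: str | Path) -> list[EncodedSequence]:
    out: list[EncodedSequence] = []
    with open(path) as fh:
        for line in fh:
            pid, label, groups = line.rstrip("\n").split("\t")
            visits = []
            for grp in groups.split(";"):
                gap, idxs = grp.split(":")
                visits.append(([int(i) for i in idxs.split(",")], int(gap)))
            out.append(EncodedSequence(patient_id=pid, label=int(label), visits=visits))
    return out
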