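"""Attention-based interpretation: heatmaps, cohort factors, temporal scatters.

A patient's contribution matrix multiplies the visit-level weight beta_i
by the code-level weight alpha_ij and renormalizes so the patient's total
contribution mass is 1; variants without visit attention use uniform
visit weights.  Cohort-level factors aggregate that mass per
(code, month-bucket) pair over patients — bucket N covers gaps
[30N, 30N+29] days before the prediction date, the "/N months before"
notation — and rank descending.  Temporal scatters show, for one code,
each (patient, occurrence) as a point at its day gap weighted by its
contribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .encoding import EncodedSequence, Vocabulary
from .model import RiskOutput

logger = logging.getLogger(__name__)

__all__ = [
    "ContributionMatrix",
    "patient_contributions",
    "render_heatmap",
    "cohort_level_factors",
    "temporal_scatter",
]

MONTH_DAYS = 30
MAX_BUCKET = 12


@dataclass
class ContributionMatrix:
    """codes x visits contribution weights for one patient; entries sum to 1."""

    patient_id: str
    code_indices: list[int]       # row labels (vocabulary indices)
    code_labels: list[str]        # row labels (tokens, for rendering)
    visit_gaps: list[int]         # column labels (days before prediction date)
    values: np.ndarray            # (n_codes, n_visits), >= 0, total 1
    probability: float


def patient_contributions(
    risk: RiskOutput,
    encoded: EncodedSequence,
    vocab: Vocabulary | None = None,
) -> ContributionMatrix:
    """Normalized product of visit- and code-level attention weights.

    c_ij = beta_i * alpha_ij / sum(all); for variants without visit
    attention (beta is None) visits are weighted uniformly.
    """
    n_vis = len(encoded.visits)
    if len(risk.alpha) != n_vis:
        raise ValueError("attention weights do not match the encoded sequence shape")
    beta = risk.beta if risk.beta is not None else np.full(n_vis, 1.0 / n_vis)
    if len(beta) != n_vis:
        raise ValueError("visit weights do not match the number of visits")

    rows = sorted({i for idxs, _ in encoded.visits for i in idxs})
    row_of = {c: r for r, c in enumerate(rows)}
    M = np.zeros((len(rows), n_vis))
    for t, (idxs, _gap) in enumerate(encoded.visits):
        for j, code in enumerate(idxs):
            M[row_of[code], t] += beta[t] * risk.alpha[t][j]
    total = M.sum()
    if total <= 0:
        raise ValueError("empty contribution matrix")
    M /= total
    labels = [vocab.code(i) if vocab is not None else str(i) for i in rows]
    return ContributionMatrix(
        patient_id=encoded.patient_id,
        code_indices=rows,
        code_labels=labels,
        visit_gaps=[gap for _, gap in encoded.visits],
        values=M,
        probability=risk.probability,
    )


def render_heatmap(matrix: ContributionMatrix, path: str | Path,
                   image: bool = False) -> Path:
    """Write the contribution matrix as TSV (optionally also a PNG).

    The header comment carries the patient id and risk probability;
    columns are labelled by the day gap of each visit.
    """
    if matrix.values.size == 0:
        raise ValueError("cannot render an empty contribution matrix")
    path = Path(path)
    cols = [f"gap_{g}d" for g in matrix.visit_gaps]
    df = pd.DataFrame(matrix.values, index=matrix.code_labels, columns=cols)
    with open(path, "w") as fh:
        fh.write(f"# patient={matrix.patient_id} P={matrix.probability:.6f}\n")
        df.to_csv(fh, sep="\t", index_label="code")
    if image:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(1 + 0.5 * len(cols), 1 + 0.3 * len(df)))
        im = ax.imshow(matrix.values, cmap="Greys", aspect="auto")
        ax.set_xticks(range(len(cols)), cols, rotation=45, ha="right")
        ax.set_yticks(range(len(df)), matrix.code_labels)
        ax.set_title(f"{matrix.patient_id}  P={matrix.probability:.3f}")
        fig.colorbar(im)
        fig.tight_layout()
        fig.savefig(path.with_suffix(".png"), dpi=100)
        plt.close(fig)
    return path


def cohort_level_factors(matrices: list[ContributionMatrix]) -> pd.DataFrame:
    """Aggregate contribution mass per (code, month bucket) over patients.

    Each patient contributes total mass 1, so long records cannot
    dominate.  Returns a DataFrame (code, month_bucket, score, support)
    sorted by descending score; support counts contributing patients.
    """
    if not matrices:
        raise ValueError("at least one patient is required")
    acc: dict[tuple[str, int], list] = {}
    for mat in matrices:
        seen: set[tuple[str, int]] = set()
        for r, code in enumerate(mat.code_labels):
            for t, gap in enumerate(mat.visit_gaps):
                w = mat.values[r, t]
                if w == 0:
                    continue
                key = (code, min(gap // MONTH_DAYS, MAX_BUCKET))
                entry = acc.setdefault(key, [0.0, 0])
                entry[0] += w
                if key not in seen:
                    entry[1] += 1
                    seen.add(key)
    rows = [
        (code, bucket, score, support)
        for (code, bucket), (score, support) in acc.items()
    ]
    df = pd.DataFrame(rows, columns=["code", "month_bucket", "score", "support"])
    return df.sort_values(["score", "code", "month_bucket"],
                          ascending=[False, True, True]).reset_index(drop=True)


def temporal_scatter(
    code: str,
    matrices: list[ContributionMatrix],
    max_patients: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-occurrence contribution of one code across time.

    One row per (patient, occurrence) with the day gap and contribution
    weight; patients holding the code are subsampled without replacement
    to ``max_patients``.  Returns an empty frame with a warning when the
    code occurs nowhere.
    """
    holders = [m for m in matrices if code in m.code_labels]
    if not holders:
        warnings.warn(f"code {code!r} does not occur in any patient")
        return pd.DataFrame(columns=["patient_id", "gap_days", "weight"])
    if len(holders) > max_patients:
        rng = np.random.default_rng(seed)
        pick = rng.choice(len(holders), size=max_patients, replace=False)
        holders = [holders[i] for i in sorted(pick)]
    rows = []
    for m in holders:
        r = m.code_labels.index(code)
        for t, gap in enumerate(m.visit_gaps):
            w = m.values[r, t]
            if w > 0:
                rows.append((m.patient_id, gap, w))
    return pd.DataFrame(rows, columns=["patient_id", "gap_days", "weight"])
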