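"""Cutoff-based prognostic comparators: KPS and PPI.

KPS (Karnofsky Performance Status, 100 = normal down to 0 in steps of 10)
predicts in-hospital death when strictly below 50; PPI (Palliative Prognostic
Index, 0–15) predicts death when strictly above 6.0.  Both boundaries are
strict: a patient exactly at the cutoff falls in the negative (stable) class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .evaluate import ContingencyTable
from .simulate import PatientMeta

__all__ = [
    "CutoffRule",
    "KPS_RULE",
    "PPI_RULE",
    "apply_cutoff",
    "contingency_from_predictions",
    "scores_from_cohort",
    "write_contingency_csv",
]

logger = logging.getLogger(__name__)

_REQUIRED_DIRECTION = {
    "KPS": "below_predicts_death",
    "PPI": "above_predicts_death",
}


@dataclass(frozen=True)
class CutoffRule:
    """A one-threshold classifier on a clinical score."""

    score_name: str
    cutoff: float
    direction: str

    def __post_init__(self) -> None:
        if self.score_name not in _REQUIRED_DIRECTION:
            raise ValueError(f"unknown score_name {self.score_name!r}")
        required = _REQUIRED_DIRECTION[self.score_name]
        if self.direction != required:
            raise ValueError(
                f"{self.score_name} must use direction {required!r}"
            )


#: validated clinical cutoffs
KPS_RULE = CutoffRule("KPS", 50.0, "below_predicts_death")
PPI_RULE = CutoffRule("PPI", 6.0, "above_predicts_death")


def apply_cutoff(
    scores: dict[str, Optional[float]], rule: CutoffRule
) -> dict[str, int]:
    """Predict death (1) / stable (0) by a strict threshold on the score.

    Patients with a missing score are excluded from the output (and logged),
    mirroring score availability in real cohorts.
    """
    predictions: dict[str, int] = {}
    n_missing = 0
    for pid, value in scores.items():
        if value is None or pd.isna(value):
            n_missing += 1
            continue
        if rule.direction == "below_predicts_death":
            predictions[pid] = int(value < rule.cutoff)
        else:
            predictions[pid] = int(value > rule.cutoff)
    if n_missing:
        logger.info(
            "%s: excluded %d patient(s) with missing score", rule.score_name, n_missing
        )
    return predictions


def contingency_from_predictions(
    predictions: dict[str, int], outcomes: dict[str, int]
) -> ContingencyTable:
    """2x2 counts; a true positive is predicted-death and observed death."""
    if set(predictions) != set(outcomes):
        diff = sorted(set(predictions) ^ set(outcomes))
        raise ValueError(f"prediction/outcome id mismatch: {diff}")
    tp = fp = fn = tn = 0
    for pid, pred in predictions.items():
        truth = outcomes[pid]
        if pred == 1 and truth == 1:
            tp += 1
        elif pred == 1 and truth == 0:
            fp += 1
        elif pred == 0 and truth == 1:
            fn += 1
        else:
            tn += 1
    return ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn)


def scores_from_cohort(
    metas: Sequence[PatientMeta], score_name: str
) -> dict[str, Optional[float]]:
    """Extract a score column (with missing values) from cohort metadata."""
    if score_name == "KPS":
        return {m.patient_id: (None if m.kps is None else float(m.kps)) for m in metas}
    if score_name == "PPI":
        return {m.patient_id: m.ppi for m in metas}
    raise ValueError(f"unknown score_name {score_name!r}")


def write_contingency_csv(table: ContingencyTable, path: str | Path) -> None:
    pd.DataFrame(
        [{"tp": table.tp, "fp": table.fp, "fn": table.fn, "tn": table.tn, "n": table.n}]
    ).to_csv(path, index=False)
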