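"""Diagnostic evaluation: 2x2 tables, exact binomial CIs, ROC/AUC, Youden cutoff.

All proportions derived from a 2x2 contingency table (sensitivity,
specificity, PPV, NPV, accuracy) carry Clopper–Pearson exact confidence
intervals.  ROC curves are empirical (no smoothing) and the AUC is the
Mann–Whitney concordance probability with ties counted one half.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ContingencyTable",
    "Metric",
    "MetricReport",
    "RocCurve",
    "metrics_from_contingency",
    "confusion_matrix",
    "roc_and_auc",
    "optimal_cutoff",
    "write_metric_report",
    "write_roc_csv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 diagnostic counts; positive class is in-hospital death."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("all counts must be nonnegative")
        if self.n < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


class Metric(NamedTuple):
    """Point estimate with its confidence interval."""

    estimate: float
    ci_low: float
    ci_high: float


@dataclass
class MetricReport:
    """All reported diagnostics for one classifier on one patient set.

    A metric whose denominator is zero is None rather than 0 or 1; the AUC is
    None when no continuous score was available.
    """

    sensitivity: Optional[Metric]
    specificity: Optional[Metric]
    ppv: Optional[Metric]
    npv: Optional[Metric]
    accuracy: Optional[Metric]
    auc: Optional[float]
    n: int
    provenance: dict = field(default_factory=dict)


def _proportion(count: int, nobs: int, name: str, ci_level: float) -> Optional[Metric]:
    if nobs == 0:
        logger.info("metric %s has zero denominator; reported as missing", name)
        return None
    lo, hi = proportion_confint(count, nobs, alpha=1.0 - ci_level, method="beta")
    return Metric(count / nobs, float(lo), float(hi))


def metrics_from_contingency(
    table: ContingencyTable, ci_level: float = 0.95
) -> MetricReport:
    """Sensitivity, specificity, PPV, NPV and accuracy with exact binomial CIs."""
    if not 0.0 < ci_level < 1.0:
        raise ValueError("ci_level must lie in (0, 1)")
    t = table
    return MetricReport(
        sensitivity=_proportion(t.tp, t.tp + t.fn, "sensitivity", ci_level),
        specificity=_proportion(t.tn, t.tn + t.fp, "specificity", ci_level),
        ppv=_proportion(t.tp, t.tp + t.fp, "ppv", ci_level),
        npv=_proportion(t.tn, t.tn + t.fn, "npv", ci_level),
        accuracy=_proportion(t.tp + t.tn, t.n, "accuracy", ci_level),
        auc=None,
        n=t.n,
    )


def confusion_matrix(
    predictions: np.ndarray, labels: np.ndarray, normalize: bool = False
) -> np.ndarray:
    """2x2 matrix with rows = true class (0, 1) and columns = predicted class.

    With ``normalize=True`` each row is divided by its sum, so rows sum to 1;
    a row for an absent true class is reported as NaN (missing), never 0/0.
    """
    predictions = np.asarray(predictions).astype(int)
    labels = np.asarray(labels).astype(int)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    mat = np.zeros((2, 2), dtype=float)
    for true in (0, 1):
        for pred in (0, 1):
            mat[true, pred] = np.sum((labels == true) & (predictions == pred))
    if normalize:
        sums = mat.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            mat = np.where(sums > 0, mat / sums, np.nan)
    return mat


@dataclass
class RocCurve:
    """Empirical ROC curve on oriented scores (higher = higher death risk).

    ``direction`` records how raw scores were oriented:
    "above_predicts_death" leaves scores unchanged, "below_predicts_death"
    negates them, so ``threshold`` values for the latter are negated raw
    scores (use :meth:`to_score_units` to convert back).
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    direction: str = "above_predicts_death"

    def to_score_units(self, threshold: float) -> float:
        return -threshold if self.direction == "below_predicts_death" else threshold


def roc_and_auc(
    scores: dict[str, float],
    outcomes: dict[str, int],
    direction: str = "above_predicts_death",
) -> tuple[RocCurve, float]:
    """ROC curve and Mann–Whitney AUC for a continuous score.

    ``direction`` orients the score so that higher oriented score means
    higher death risk; both outcome classes must be present.
    """
    if direction not in ("above_predicts_death", "below_predicts_death"):
        raise ValueError(f"unknown direction {direction!r}")
    if set(scores) != set(outcomes):
        diff = sorted(set(scores) ^ set(outcomes))
        raise ValueError(f"score/outcome id mismatch: {diff}")
    ids = sorted(scores)
    y = np.array([outcomes[i] for i in ids], dtype=int)
    s = np.array([scores[i] for i in ids], dtype=float)
    if direction == "below_predicts_death":
        s = -s
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present for ROC analysis")
    fpr, tpr, thr = roc_curve(y, s, drop_intermediate=False)
    auc = float(roc_auc_score(y, s))
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr, direction=direction), auc


def optimal_cutoff(roc: RocCurve) -> float:
    """Threshold maximising Youden's J = tpr - fpr.

    Ties are broken toward the threshold classifying fewer patients as death,
    i.e. the highest tied oriented threshold.  The returned value is on the
    oriented-score scale; use ``roc.to_score_units`` for the raw scale.
    """
    if len(roc.thresholds) == 0:
        raise ValueError("roc curve is empty")
    j = np.asarray(roc.tpr) - np.asarray(roc.fpr)
    best = int(np.argmax(j))  # thresholds descend, so first max = fewest positives
    return float(roc.thresholds[best])


# ---------------------------------------------------------------------------
# on-disk formats


def _metric_to_json(m: Optional[Metric]):
    if m is None:
        return None
    return {"estimate": m.estimate, "ci_low": m.ci_low, "ci_high": m.ci_high}


def write_metric_report(report: MetricReport, path: str | Path) -> None:
    payload = {
        "sensitivity": _metric_to_json(report.sensitivity),
        "specificity": _metric_to_json(report.specificity),
        "ppv": _metric_to_json(report.ppv),
        "npv": _metric_to_json(report.npv),
        "accuracy": _metric_to_json(report.accuracy),
        "auc": report.auc,
        "n": report.n,
        "provenance": report.provenance,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_roc_csv(roc: RocCurve, path: str | Path) -> None:
    pd.DataFrame(
        {"threshold": roc.thresholds, "fpr": roc.fpr, "tpr": roc.tpr}
    ).to_csv(path, index=False)
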