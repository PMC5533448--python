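"""Confusion-matrix metrics: accuracy, Cohen's kappa, PRF, TPR/FPR, ROC area.

Kappa is the chance-corrected agreement (Po - Pc) / (1 - Pc) with Po the
observed accuracy and Pc the marginal chance agreement

    Pc = [(TP+FP)(TP+FN) + (FN+TN)(FP+TN)] / (P+N)^2 .

Its role here: a majority-vote classifier on a 99:1 dataset scores 99%
accuracy but kappa 0 — kappa is the credibility monitor that accuracy alone
cannot provide.  The conventional credibility bands are kappa >= 0.75 (high),
0.4 <= kappa < 0.75 (moderate), kappa < 0.4 (low or none).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionCounts",
    "EvalResult",
    "confusion_from_labels",
    "accuracy",
    "chance_agreement",
    "kappa",
    "credibility_band",
    "weighted_prf",
    "roc_area",
    "eval_result",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion matrix must contain at least one count")

    @property
    def P(self) -> int:
        """Actual positives."""
        return self.TP + self.FN

    @property
    def N(self) -> int:
        """Actual negatives."""
        return self.FP + self.TN

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.FP + other.FP,
            self.FN + other.FN, self.TN + other.TN,
        )


@dataclass(frozen=True)
class EvalResult:
    """One evaluation's metric block, mirroring the standard report columns."""

    accuracy: float
    kappa: float
    precision: float
    recall: float
    f_measure: float
    tpr: float
    fpr: float
    roc_area: float
    counts: ConfusionCounts

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    def table_row(self, psize: int | None = None, nsize: int | None = None) -> dict:
        """One row in the conventional column order."""
        return {
            "Accuracy": self.accuracy,
            "Kappa": self.kappa,
            "Psize": psize,
            "Nsize": nsize,
            "TPR": self.tpr,
            "FPR": self.fpr,
            "Precision": self.precision,
            "Recall": self.recall,
            "F-Measure": self.f_measure,
            "ROC Area": self.roc_area,
        }


def confusion_from_labels(true: np.ndarray, pred: np.ndarray) -> ConfusionCounts:
    true = np.asarray(true, dtype=int)
    pred = np.asarray(pred, dtype=int)
    return ConfusionCounts(
        TP=int(np.sum((true == 1) & (pred == 1))),
        FP=int(np.sum((true == 0) & (pred == 1))),
        FN=int(np.sum((true == 1) & (pred == 0))),
        TN=int(np.sum((true == 0) & (pred == 0))),
    )


def accuracy(c: ConfusionCounts) -> float:
    return (c.TP + c.TN) / c.total


def chance_agreement(c: ConfusionCounts) -> float:
    t = c.total
    return ((c.TP + c.FP) * (c.TP + c.FN) + (c.FN + c.TN) * (c.FP + c.TN)) / t**2


def kappa(c: ConfusionCounts) -> float:
    """(Po - Pc)/(1 - Pc); defined 0 with a warning when Pc = 1.

    Pc = 1 only for a single-cell confusion matrix (one class, constant
    predictions); returning 0 there keeps parameter sweeps alive instead of
    crashing on degenerate windows.
    """
    po = accuracy(c)
    pc = chance_agreement(c)
    if pc == 1.0:
        warnings.warn("degenerate single-cell confusion matrix; kappa set to 0",
                      stacklevel=2)
        return 0.0
    return (po - pc) / (1.0 - pc)


def credibility_band(k: float) -> str:
    """'high' (>= 0.75), 'moderate' ([0.4, 0.75)) or 'low' (< 0.4)."""
    if not -1.0 <= k <= 1.0:
        raise ValueError(f"kappa must lie in [-1, 1], got {k}")
    if k >= 0.75:
        return "high"
    if k >= 0.4:
        return "moderate"
    return "low"


def _prf_one_class(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    if tp + fp == 0:
        warnings.warn("no predictions for a class; precision set to 0", stacklevel=3)
        prec = 0.0
    else:
        prec = tp / (tp + fp)
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return prec, rec, f1


def weighted_prf(c: ConfusionCounts, per_class: bool = False):
    """Support-weighted precision/recall/F1 over the two classes.

    With ``per_class`` returns ``((prec, rec, f1), {1: ..., 0: ...})`` so the
    aggregation is auditable.
    """
    pos = _prf_one_class(c.TP, c.FP, c.FN)
    neg = _prf_one_class(c.TN, c.FN, c.FP)
    wp, wn = c.P / c.total, c.N / c.total
    agg = tuple(wp * a + wn * b for a, b in zip(pos, neg))
    if per_class:
        return agg, {1: pos, 0: neg}
    return agg


def roc_area(scores, labels) -> float:
    """Probability a random positive outscores a random negative, ties at 1/2."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC area undefined with a single class present")
    return float(roc_auc_score(labels, scores))


def eval_result(
    true: np.ndarray,
    pred: np.ndarray,
    scores: np.ndarray | None = None,
) -> EvalResult:
    """Bundle the full metric block for one set of predictions.

    When no continuous scores are available the hard labels stand in as
    scores for the ROC column (a coarse rank estimate).
    """
    c = confusion_from_labels(true, pred)
    prec, rec, f1 = weighted_prf(c)
    tpr = c.TP / c.P if c.P else 0.0
    fpr = c.FP / c.N if c.N else 0.0
    if scores is None:
        warnings.warn("no scores provided; ROC area from hard labels", stacklevel=2)
        scores = pred
    try:
        auc = roc_area(scores, true)
    except ValueError:
        auc = 0.5
    return EvalResult(
        accuracy=accuracy(c),
        kappa=kappa(c),
        precision=prec,
        recall=rec,
        f_measure=f1,
        tpr=tpr,
        fpr=fpr,
        roc_area=auc,
        counts=c,
    )
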