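"""Assessment metrics and the case-level cross-validation protocol.

Positive class is malignant throughout: sensitivity (TPR) is the fraction
of malignant samples flagged, specificity (TNR) the fraction of benign
samples cleared. ROC/AUC use the standard threshold sweep with the
rank-statistic tie convention. Cross-validation folds are stratified and
assigned at *case* level so that the nine crops of one image can never
straddle a train/test boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import ValidationError


@dataclass
class EvaluationReport:
    """Confusion counts and derived rates; rates with an empty denominator
    are None with the condition recorded in ``undefined``."""

    accuracy: float
    sensitivity: float | None
    specificity: float | None
    confusion: tuple[int, int, int, int]  # (TP, FP, TN, FN)
    n: int
    auc: float | None = None
    roc_points: list[tuple[float, float]] | None = None
    undefined: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        tp, fp, tn, fn = self.confusion
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "confusion": {"TP": tp, "FP": fp, "TN": tn, "FN": fn},
            "n": self.n,
            "undefined": self.undefined,
        }


@dataclass(frozen=True)
class CVPlan:
    """Case-level fold assignment: fold_of[case_id] in 0..k-1."""

    k: int
    fold_of: dict
    seed: int

    def fold_cases(self, fold: int) -> list:
        return [cid for cid, f in self.fold_of.items() if f == fold]


def confusion_metrics(predicted: Sequence[int], truth: Sequence[int]) -> EvaluationReport:
    """Accuracy, sensitivity and specificity from hard labels (1 = malignant)."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValidationError("predicted and truth must have equal length")
    n = truth.size
    if n < 1:
        raise ValidationError("need at least one sample")
    tp = int(np.sum((predicted == 1) & (truth == 1)))
    tn = int(np.sum((predicted == 0) & (truth == 0)))
    fp = int(np.sum((predicted == 1) & (truth == 0)))
    fn = int(np.sum((predicted == 0) & (truth == 1)))
    undefined = []
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    if sens is None:
        undefined.append("sensitivity: no positive cases in truth")
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    if spec is None:
        undefined.append("specificity: no negative cases in truth")
    return EvaluationReport(accuracy=(tp + tn) / n, sensitivity=sens,
                            specificity=spec, confusion=(tp, fp, tn, fn),
                            n=n, undefined=undefined)


def roc_auc(scores: Sequence[float], truth: Sequence[int]) -> tuple[float, list[tuple[float, float]]]:
    """AUC (trapezoidal, ties count half) and the ROC polyline (FPR, TPR)."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    if scores.shape != truth.shape:
        raise ValidationError("scores and truth must have equal length")
    if np.unique(truth).size < 2:
        raise ValidationError("ROC needs both classes present")
    auc = float(roc_auc_score(truth, scores))
    fpr, tpr, _ = roc_curve(truth, scores)
    return auc, list(zip(fpr.tolist(), tpr.tolist()))


def make_cv_plan(case_ids: Sequence, labels: Sequence, k: int = 10,
                 seed: int = 0) -> CVPlan:
    """Stratified case-level fold assignment.

    Cases are shuffled within each class and dealt round-robin into one
    continuous stream, which keeps both the per-class counts and the total
    fold sizes within one case of each other. Deterministic for a seed.
    """
    case_ids = list(case_ids)
    labels = list(labels)
    if len(case_ids) != len(labels):
        raise ValidationError("case_ids and labels must have equal length")
    if len(set(case_ids)) != len(case_ids):
        raise ValidationError("case_ids must be unique")
    if k > len(case_ids):
        raise ValidationError(f"k={k} exceeds the {len(case_ids)} cases")
    rng = np.random.default_rng(seed)
    by_class: dict = {}
    for cid, lb in zip(case_ids, labels):
        by_class.setdefault(lb, []).append(cid)
    fold_of: dict = {}
    slot = 0
    for lb in sorted(by_class, key=str):
        ids = by_class[lb]
        order = rng.permutation(len(ids))
        for j in order:
            fold_of[ids[j]] = slot % k
            slot += 1
    return CVPlan(k=k, fold_of=fold_of, seed=seed)


def evaluate_predictions(scores: Sequence[float], predicted: Sequence[int],
                         truth: Sequence[int]) -> EvaluationReport:
    """Full report: confusion metrics plus ROC/AUC when both classes exist."""
    report = confusion_metrics(predicted, truth)
    truth_arr = np.asarray(truth)
    if np.unique(truth_arr).size == 2:
        report.auc, report.roc_points = roc_auc(scores, truth)
    else:
        report.undefined.append("auc: single-class truth")
    return report
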