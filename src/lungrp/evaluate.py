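"""Scoring of RP predictions: ROC/AUC, sensitivity, specificity, accuracy.

Sensitivity = TP / (TP + FN), specificity = TN / (TN + FP) and
accuracy = (TP + TN) / (TP + FN + TN + FP); a patient is classified
positive when the predicted probability is >= the operating threshold.
The AUC is threshold-free (trapezoidal area, equivalent to the rank /
Mann-Whitney formulation). The default operating point is Youden's
index on the training ROC, frozen when the model is applied to a test
cohort; a fixed 0.5 threshold is available instead.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .model import EnsembleModel

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "roc_auc",
    "confusion_metrics",
    "youden_threshold",
    "evaluate_cohort",
    "evaluate_train_test",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class EvalReport:
    """One row of the evaluation table: AUC + threshold metrics."""

    roi: str
    cohort: str
    auc: float
    sensitivity: float
    specificity: float
    accuracy: float
    threshold: float
    counts: ConfusionCounts

    def to_dict(self) -> dict:
        d = asdict(self)
        d.update(d.pop("counts"))
        return d


def _check_two_class(labels: np.ndarray) -> None:
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present to evaluate")


def roc_auc(probabilities, labels) -> float:
    """Area under the ROC curve (rank formulation handles ties)."""
    labels = np.asarray(labels, dtype=int)
    _check_two_class(labels)
    return float(roc_auc_score(labels, np.asarray(probabilities, dtype=float)))


def confusion_metrics(probabilities, labels, threshold: float) -> dict:
    """Sensitivity/specificity/accuracy at one probability threshold.

    Probability exactly at the threshold classifies positive.
    """
    labels = np.asarray(labels, dtype=int)
    _check_two_class(labels)
    pred = np.asarray(probabilities, dtype=float) >= threshold
    pos = labels == 1
    counts = ConfusionCounts(
        tp=int((pred & pos).sum()),
        fp=int((pred & ~pos).sum()),
        tn=int((~pred & ~pos).sum()),
        fn=int((~pred & pos).sum()),
    )
    return {
        "sensitivity": counts.tp / (counts.tp + counts.fn),
        "specificity": counts.tn / (counts.tn + counts.fp),
        "accuracy": (counts.tp + counts.tn) / counts.n,
        "counts": counts,
    }


def youden_threshold(probabilities, labels) -> float:
    """Threshold maximizing sensitivity + specificity - 1 on this ROC."""
    labels = np.asarray(labels, dtype=int)
    _check_two_class(labels)
    probs = np.asarray(probabilities, dtype=float)
    best_t, best_j = 0.5, -np.inf
    for t in np.unique(probs):
        m = confusion_metrics(probs, labels, t)
        j = m["sensitivity"] + m["specificity"] - 1.0
        if j > best_j:
            best_j, best_t = j, float(t)
    return best_t


def evaluate_cohort(
    model: EnsembleModel,
    features: pd.DataFrame,
    labels: pd.Series,
    cohort: str = "train",
    threshold_rule: str = "youden",
    threshold: float | None = None,
) -> EvalReport:
    """Score one cohort with an ensemble model.

    ``threshold_rule`` is ``"youden"`` (optimal on this cohort's ROC —
    use for training) or ``"fixed"`` (0.5). Passing ``threshold``
    overrides both, which is how a training-derived Youden threshold is
    frozen for a test cohort.
    """
    labels = labels.loc[features.index]
    probs = model.predict_proba(features)
    y = labels.to_numpy(dtype=int)
    auc = roc_auc(probs, y)
    if threshold is None:
        if threshold_rule == "youden":
            threshold = youden_threshold(probs, y)
        elif threshold_rule == "fixed":
            threshold = 0.5
        else:
            raise ValueError(f"unknown threshold_rule {threshold_rule!r}")
    m = confusion_metrics(probs, y, threshold)
    return EvalReport(
        roi=model.roi,
        cohort=cohort,
        auc=auc,
        sensitivity=m["sensitivity"],
        specificity=m["specificity"],
        accuracy=m["accuracy"],
        threshold=float(threshold),
        counts=m["counts"],
    )


def evaluate_train_test(
    model: EnsembleModel,
    train_features: pd.DataFrame,
    train_labels: pd.Series,
    test_features: pd.DataFrame,
    test_labels: pd.Series,
    threshold_rule: str = "youden",
) -> tuple[EvalReport, EvalReport]:
    """Train and test reports; the operating threshold is derived on the
    training cohort and frozen for the test cohort."""
    train_report = evaluate_cohort(
        model, train_features, train_labels, cohort="train", threshold_rule=threshold_rule
    )
    test_report = evaluate_cohort(
        model,
        test_features,
        test_labels,
        cohort="test",
        threshold=train_report.threshold,
    )
    return train_report, test_report
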