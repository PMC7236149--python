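"""Classification performance metrics and multi-trial aggregation.

Subset accuracy (exact-match Iverson mean), support-weighted F1, the
multiclass Matthews correlation coefficient (Gorodkin's confusion-matrix
generalization), one-vs-rest ROC AUC per topology label plus a micro
average pooling all (sample, class) decisions, and the 3×3 confusion
matrix. Trial-level reports aggregate to mean ± sample standard deviation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    confusion_matrix as _sk_confusion,
    f1_score as _sk_f1,
    matthews_corrcoef as _sk_mcc,
    roc_auc_score as _sk_auc,
)

__all__ = [
    "EvaluationReport",
    "subset_accuracy",
    "classification_scores",
    "roc_auc_ovr",
    "evaluate",
    "aggregate_trials",
]


def subset_accuracy(pred, true) -> float:
    """Mean of exact-match indicators: (1/n) Σ ⟦Z_i = Y_i⟧."""
    pred = np.asarray(pred)
    true = np.asarray(true)
    if pred.shape != true.shape:
        raise ValueError("pred and true must have equal length")
    if pred.size == 0:
        raise ValueError("cannot score an empty prediction set")
    return float(np.mean(pred == true))


def classification_scores(pred, true, labels: tuple[str, ...] | None = None):
    """(weighted F1, multiclass MCC, confusion matrix with true labels as rows)."""
    pred = np.asarray(pred)
    true = np.asarray(true)
    if labels is None:
        labels = tuple(sorted(set(true) | set(pred)))
    cm = _sk_confusion(true, pred, labels=list(labels))
    if len(set(true)) < 2:
        warnings.warn("single-label truth: MCC undefined, reported as 0")
        mcc = 0.0
    else:
        mcc = float(_sk_mcc(true, pred))
    f1 = float(_sk_f1(true, pred, labels=list(labels), average="weighted", zero_division=0))
    return f1, mcc, cm


def roc_auc_ovr(probabilities: np.ndarray, true, labels: tuple[str, ...]):
    """One-vs-rest AUC per class (midrank ties) and the micro average.

    ``probabilities`` columns must align with ``labels``. A class absent from
    the truth gets AUC ``None``.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    true = np.asarray(true)
    if probabilities.shape != (true.size, len(labels)):
        raise ValueError("probability matrix must be (n_samples, n_labels)")
    per_class: dict[str, float | None] = {}
    onehot = np.zeros_like(probabilities)
    for j, lab in enumerate(labels):
        mask = true == lab
        onehot[:, j] = mask
        if mask.all() or not mask.any():
            per_class[lab] = None
        else:
            per_class[lab] = float(_sk_auc(mask.astype(int), probabilities[:, j]))
    present = [v for v in per_class.values() if v is not None]
    micro = float(_sk_auc(onehot.ravel(), probabilities.ravel())) if present else None
    return per_class, micro


@dataclass
class EvaluationReport:
    """Per-trial evaluation over one held-out image set."""

    n: int
    labels: tuple[str, ...]
    accuracy: float
    f1_weighted: float
    mcc: float
    confusion: np.ndarray  # rows = true labels, in ``labels`` order
    per_class_auc: dict = field(default_factory=dict)
    micro_auc: float | None = None

    @property
    def true_positive_rates(self) -> dict[str, float]:
        """Row-normalized confusion diagonal: per-class recall."""
        out = {}
        for i, lab in enumerate(self.labels):
            support = self.confusion[i].sum()
            out[lab] = float(self.confusion[i, i] / support) if support else float("nan")
        return out

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "labels": list(self.labels),
            "accuracy": self.accuracy,
            "f1_weighted": self.f1_weighted,
            "mcc": self.mcc,
            "confusion": self.confusion.tolist(),
            "per_class_auc": self.per_class_auc,
            "micro_auc": self.micro_auc,
            "true_positive_rates": self.true_positive_rates,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def evaluate(pred, true, probabilities=None, labels: tuple[str, ...] | None = None) -> EvaluationReport:
    """Assemble a full report from hard labels and optional probabilities."""
    true = np.asarray(true)
    pred = np.asarray(pred)
    if labels is None:
        labels = tuple(sorted(set(true) | set(pred)))
    acc = subset_accuracy(pred, true)
    f1, mcc, cm = classification_scores(pred, true, labels)
    per_class, micro = ({}, None)
    if probabilities is not None:
        per_class, micro = roc_auc_ovr(probabilities, true, labels)
    return EvaluationReport(
        n=int(true.size), labels=labels, accuracy=acc, f1_weighted=f1,
        mcc=mcc, confusion=cm, per_class_auc=per_class, micro_auc=micro,
    )


def aggregate_trials(reports: list[EvaluationReport]) -> dict:
    """Mean ± sample standard deviation per metric, plus the mean confusion matrix."""
    if len(reports) < 2:
        raise ValueError("aggregation needs at least 2 trial reports")
    label_sets = {r.labels for r in reports}
    if len(label_sets) != 1:
        raise ValueError(f"trial reports carry heterogeneous label sets: {label_sets}")
    labels = reports[0].labels

    def mean_std(values):
        arr = np.asarray(values, dtype=float)
        return {"mean": float(arr.mean()), "std": float(arr.std(ddof=1))}

    summary = {
        "n_trials": len(reports),
        "labels": list(labels),
        "accuracy": mean_std([r.accuracy for r in reports]),
        "f1_weighted": mean_std([r.f1_weighted for r in reports]),
        "mcc": mean_std([r.mcc for r in reports]),
        "mean_confusion": np.mean([r.confusion for r in reports], axis=0).tolist(),
        "mean_true_positive_rates": {
            lab: float(np.mean([r.true_positive_rates[lab] for r in reports]))
            for lab in labels
        },
    }
    micro = [r.micro_auc for r in reports if r.micro_auc is not None]
    if micro:
        summary["micro_auc"] = mean_std(micro)
    return summary
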