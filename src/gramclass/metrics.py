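"""Multi-class evaluation: accuracy, macro precision/recall, one-vs-rest AUC.

Per-class values that are undefined (a class never predicted, or absent
from the truth) are treated as 0 and flagged, so macro averages stay
comparable across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support, roc_auc_score


@dataclass
class Metrics:
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_auc: float
    per_class: dict[str, dict[str, float]]
    confusion: list[list[int]]
    flagged: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "Metrics":
        with open(path) as fh:
            return cls(**json.load(fh))


def evaluate(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    probs: np.ndarray | None,
    class_names: list[str],
) -> Metrics:
    """Compute accuracy, macro precision/recall and macro one-vs-rest AUC.

    ``probs`` rows must sum to 1 (ensemble-averaged member probabilities);
    pass None to skip AUC (reported as 0 and flagged).
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    n_classes = len(class_names)
    if y_pred.min() < 0 or y_pred.max() >= n_classes:
        raise ValueError("y_pred contains labels outside the known classes")
    if y_true.min() < 0 or y_true.max() >= n_classes:
        raise ValueError("y_true contains labels outside the known classes")

    labels = np.arange(n_classes)
    accuracy = float(np.mean(y_true == y_pred))
    precision, recall, _, support = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )
    flagged: list[str] = []
    pred_counts = np.bincount(y_pred, minlength=n_classes)
    for c in range(n_classes):
        if pred_counts[c] == 0:
            flagged.append(f"precision undefined for {class_names[c]} (never predicted)")
        if support[c] == 0:
            flagged.append(f"recall undefined for {class_names[c]} (no true records)")

    aucs = np.zeros(n_classes)
    if probs is None:
        flagged.append("AUC skipped: no probabilities provided")
    else:
        probs = np.asarray(probs, dtype=float)
        if probs.shape != (y_true.size, n_classes):
            raise ValueError("probs must be (n_records, n_classes)")
        for c in range(n_classes):
            truth = (y_true == c).astype(int)
            if truth.min() == truth.max():
                flagged.append(f"AUC undefined for {class_names[c]} (one-class truth)")
                continue
            aucs[c] = roc_auc_score(truth, probs[:, c])

    cm = confusion_matrix(y_true, y_pred, labels=labels)
    per_class = {
        class_names[c]: {
            "precision": float(precision[c]),
            "recall": float(recall[c]),
            "auc": float(aucs[c]),
            "support": int(support[c]),
        }
        for c in range(n_classes)
    }
    return Metrics(
        accuracy=accuracy,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_auc=float(aucs.mean()),
        per_class=per_class,
        confusion=cm.tolist(),
        flagged=flagged,
    )
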