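"""Example-based and ranking-based multilabel evaluation metrics.

All metrics operate on binary label matrices ``Y`` (truth) and ``Z``
(prediction) or real-valued score matrices, instances in rows and AOI
labels in columns, and live in [0, 1].

Conventions for the degenerate cases the closed formulas leave undefined:
an instance with ``Y_i ∪ Z_i = ∅`` contributes 1 to accuracy (nothing to
get wrong); an instance with ``|Z_i| = 0`` contributes 0 to precision and
one with ``|Y_i| = 0`` contributes 0 to recall; labels without both a
positive and a negative instance are excluded from the macro AUC mean
(with a warning) rather than imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


def macro_auc(scores: np.ndarray, Y: np.ndarray) -> float:
    """Macro-averaged pairwise ranking AUC.

    Per label, the fraction of (positive, negative) instance pairs whose
    positive scores at least as high as the negative (ties count as
    successes); averaged over labels having both classes.  NaN if no label
    qualifies.
    """
    scores = np.asarray(scores, dtype=float)
    Y = np.asarray(Y)
    vals = []
    for l in range(Y.shape[1]):
        pos = scores[Y[:, l] == 1, l]
        neg = scores[Y[:, l] == 0, l]
        if len(pos) == 0 or len(neg) == 0:
            warnings.warn(f"label {l} has a single class; excluded from macro AUC")
            continue
        wins = (pos[:, None] >= neg[None, :]).sum()
        vals.append(wins / (len(pos) * len(neg)))
    return float(np.mean(vals)) if vals else float("nan")


def example_based_metrics(Z: np.ndarray, Y: np.ndarray) -> dict[str, float]:
    """Accuracy (Jaccard), subset accuracy, precision, recall and F.

    Per-instance terms are averaged over instances; F is the harmonic mean
    of the aggregated precision and recall.
    """
    Z = np.asarray(Z)
    Y = np.asarray(Y)
    if Z.shape != Y.shape or len(Y) == 0:
        raise ValueError("Z and Y must be nonempty matrices of equal shape")
    inter = ((Y == 1) & (Z == 1)).sum(axis=1).astype(float)
    union = ((Y == 1) | (Z == 1)).sum(axis=1).astype(float)
    ny = (Y == 1).sum(axis=1).astype(float)
    nz = (Z == 1).sum(axis=1).astype(float)
    acc = np.where(union > 0, inter / np.maximum(union, 1), 1.0).mean()
    subset = (Y == Z).all(axis=1).mean()
    precision = np.where(nz > 0, inter / np.maximum(nz, 1), 0.0).mean()
    recall = np.where(ny > 0, inter / np.maximum(ny, 1), 0.0).mean()
    f = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return {
        "accuracy": float(acc),
        "subset_accuracy": float(subset),
        "precision": float(precision),
        "recall": float(recall),
        "f_measure": float(f),
    }


def per_aoi_accuracy(Z: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Per-label agreement rate (the per-AOI prediction accuracies)."""
    Z = np.asarray(Z)
    Y = np.asarray(Y)
    return (Z == Y).mean(axis=0).astype(float)


@dataclass
class EvalReport:
    """Cross-validated metric table for one model configuration.

    ``per_fold`` maps metric name to the K fold values; ``mean``/``sd``
    weight folds equally.  ``per_aoi`` holds the mean per-AOI accuracy and
    ``time_per_window_s`` the mean test-scoring time per window.
    """

    model: str
    per_fold: dict[str, list[float]]
    per_aoi: np.ndarray
    time_per_window_s: float = float("nan")

    @property
    def mean(self) -> dict[str, float]:
        return {k: float(np.nanmean(v)) for k, v in self.per_fold.items()}

    @property
    def sd(self) -> dict[str, float]:
        return {k: float(np.nanstd(v)) for k, v in self.per_fold.items()}

    def to_row(self) -> dict[str, float]:
        row: dict[str, float] = {"model": self.model}
        names = {
            "macro_auc": "AUC",
            "subset_accuracy": "Exact",
            "f_measure": "Fscore",
            "accuracy": "Acc",
            "precision": "Pre",
            "recall": "Recall",
        }
        for key, col in names.items():
            if key in self.per_fold:
                row[col] = self.mean[key]
                row[f"{col}_sd"] = self.sd[key]
        for j, v in enumerate(self.per_aoi, start=1):
            row[f"AOI {j}"] = float(v)
        row["time_per_window_s"] = self.time_per_window_s
        return row
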