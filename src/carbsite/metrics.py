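"""Losses and evaluation metrics for the residue and protein tasks.

Residue-level segmentation is heavily imbalanced (~95% of residues do not
bind), so training minimizes one minus the soft Dice–Sørensen coefficient;
the protein-level classifier uses binary cross entropy.  Evaluation reports
the hard Dice coefficient 2TP/(2TP+FP+FN) and the Matthews correlation
coefficient per protein (averaged across proteins, not pooled), and
balanced accuracy / TPR / TNR for protein-level binder classification.

TPR and TNR are the standard per-class recalls TP/(TP+FN) and TN/(TN+FP).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np

__all__ = [
    "ConfusionCounts",
    "dice_coefficient",
    "soft_dice",
    "dice_loss",
    "bce_loss",
    "confusion",
    "mcc",
    "bacc_tpr_tnr",
    "evaluate_residue_predictions",
    "evaluate_protein_predictions",
]

_EPS = np.finfo(float).eps


class UndefinedMetricError(ValueError):
    """A metric is undefined for the given counts (e.g. an empty class)."""


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN of a binary decision over scored items."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(pred: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> ConfusionCounts:
    """Threshold probabilities (call = 1 iff p >= threshold) and count."""
    pred = np.asarray(pred, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if pred.shape != labels.shape:
        raise ValueError("pred and labels must have equal length")
    call = (pred >= threshold).astype(int)
    return ConfusionCounts(
        tp=int(np.sum((call == 1) & (labels == 1))),
        fp=int(np.sum((call == 1) & (labels == 0))),
        tn=int(np.sum((call == 0) & (labels == 0))),
        fn=int(np.sum((call == 0) & (labels == 1))),
    )


def dice_coefficient(pred: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> float:
    """Hard Dice coefficient 2TP/(2TP+FP+FN) of thresholded predictions.

    Defined as 0 (with a warning) when neither predictions nor labels
    contain a positive.
    """
    c = confusion(pred, labels, threshold)
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        warnings.warn("Dice undefined (no positives anywhere); returning 0", stacklevel=2)
        return 0.0
    return 2.0 * c.tp / denom


def soft_dice(pred_soft, labels):
    """Differentiable Dice: counts replaced by sums of products.

    Equals the hard coefficient when predictions are exactly binary.
    """
    labels = anp.asarray(labels, dtype=float) if isinstance(labels, np.ndarray) else labels
    inter = anp.sum(pred_soft * labels)
    denom = anp.sum(pred_soft) + anp.sum(labels)
    return 2.0 * inter / (denom + _EPS)


def dice_loss(pred_soft, labels):
    """Training loss L = 1 - d with d the soft Dice coefficient."""
    return 1.0 - soft_dice(pred_soft, labels)


def bce_loss(pred, label):
    """Binary cross entropy -[y log p + (1-y) log(1-p)], clamped at eps.

    ``pred`` may be a scalar or vector; vectors return the batch mean.
    """
    p = anp.clip(pred, _EPS, 1.0 - _EPS)
    y = np.asarray(label, dtype=float)
    ll = -(y * anp.log(p) + (1.0 - y) * anp.log(1.0 - p))
    return anp.mean(ll)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def bacc_tpr_tnr(c: ConfusionCounts) -> tuple[float, float, float]:
    """(balanced accuracy, TPR, TNR); errors if either class is absent."""
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("no positive items: TPR undefined")
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("no negative items: TNR undefined")
    tpr = c.tp / (c.tp + c.fn)
    tnr = c.tn / (c.tn + c.fp)
    return (tpr + tnr) / 2.0, tpr, tnr


def evaluate_residue_predictions(
    per_protein: list[tuple[str, np.ndarray, np.ndarray]], threshold: float = 0.5
) -> dict:
    """Per-protein Dice/MCC plus their unweighted means.

    ``per_protein`` holds (id, probabilities, labels) triples.  Averaging is
    across proteins — metrics are computed per target and then averaged,
    never pooled over concatenated residues.
    """
    rows = []
    for pid, probs, labels in per_protein:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = dice_coefficient(probs, labels, threshold)
        rows.append({"id": pid, "dice": d, "mcc": mcc(confusion(probs, labels, threshold))})
    return {
        "per_protein": rows,
        "mean_dice": float(np.mean([r["dice"] for r in rows])) if rows else float("nan"),
        "mean_mcc": float(np.mean([r["mcc"] for r in rows])) if rows else float("nan"),
    }


def evaluate_protein_predictions(
    probs: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> dict:
    """Protein-level confusion, BACC, TPR, TNR at the given threshold."""
    c = confusion(probs, labels, threshold)
    bacc, tpr, tnr = bacc_tpr_tnr(c)
    return {"confusion": c, "bacc": bacc, "tpr": tpr, "tnr": tnr}
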