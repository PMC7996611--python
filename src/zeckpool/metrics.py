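"""Segmentation quality metrics: boundary precision/recall, F-measure, Dice loss.

Boundary matching is radius-based: a predicted boundary pixel counts as a
true positive when a ground-truth boundary pixel lies within the match
tolerance (Euclidean pixel radius), and symmetrically for missed truth
pixels.  Tolerance 0 reduces to exact pixel overlap.

The F-measure is the alpha-weighted combination F = PR / (aP + (1-a)R);
a = 0.5 gives the harmonic mean.

The Dice loss is one minus a smoothed Sorensen-Dice index,
1 - 2*sum(P_i T_i) / (sum(P_i) + sum(T_i) + eps), with the smoothing term
in the denominator only — so a perfect match still has a small nonzero
loss, and two empty masks score exactly 1.0.  ``symmetric_epsilon`` adds
eps to the numerator as well (the common variant in which empty-vs-empty
scores 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "MatchPolicy",
    "DegenerateMetricWarning",
    "boundary_precision_recall",
    "f_measure",
    "dice_loss",
]


class DegenerateMetricWarning(UserWarning):
    """A metric was evaluated on a degenerate input (e.g. an empty mask)."""


@dataclass(frozen=True)
class MatchPolicy:
    """Boundary match tolerance in pixels (Euclidean radius >= 0)."""

    tolerance: int = 0

    def __post_init__(self):
        if self.tolerance < 0:
            raise ValueError(f"tolerance must be >= 0, got {self.tolerance}")


def _as_binary(mask: np.ndarray, name: str) -> np.ndarray:
    mask = np.asarray(mask)
    values = np.unique(mask)
    if not np.all(np.isin(values, (0, 1))):
        raise ValueError(f"{name} mask must be binary (0/1), found values {values[:5]}")
    return mask.astype(bool)


def _distance_to(mask: np.ndarray) -> np.ndarray:
    """Euclidean distance from each pixel to the nearest True pixel."""
    if not mask.any():
        return np.full(mask.shape, np.inf)
    return ndimage.distance_transform_edt(~mask)


def boundary_precision_recall(
    pred: np.ndarray, truth: np.ndarray, policy: MatchPolicy | None = None
) -> tuple[float, float]:
    """Boundary precision P = TP/(TP+FP) and recall R = TP/(TP+FN).

    A predicted pixel is a true positive iff some truth pixel lies within
    ``policy.tolerance`` (Euclidean); a truth pixel is recalled iff some
    predicted pixel lies within the same radius.  Empty prediction yields
    P = 0, empty truth yields R = 0, each with a DegenerateMetricWarning.
    """
    if policy is None:
        policy = MatchPolicy()
    pred = _as_binary(pred, "prediction")
    truth = _as_binary(truth, "ground_truth")
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")

    if not pred.any():
        warnings.warn("prediction mask is empty; precision defined as 0",
                      DegenerateMetricWarning, stacklevel=2)
        precision = 0.0
    else:
        matched_pred = _distance_to(truth)[pred] <= policy.tolerance
        precision = float(matched_pred.mean())
    if not truth.any():
        warnings.warn("ground-truth mask is empty; recall defined as 0",
                      DegenerateMetricWarning, stacklevel=2)
        recall = 0.0
    else:
        matched_truth = _distance_to(pred)[truth] <= policy.tolerance
        recall = float(matched_truth.mean())
    return precision, recall


def f_measure(precision: float, recall: float, alpha: float = 0.5) -> float:
    """Alpha-weighted F-measure PR / (aP + (1-a)R); 0 when P = R = 0."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError(f"P and R must be in [0, 1], got ({precision}, {recall})")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    denom = alpha * precision + (1.0 - alpha) * recall
    if denom == 0.0:
        warnings.warn("F-measure undefined at P = R = 0; reported as 0",
                      DegenerateMetricWarning, stacklevel=2)
        return 0.0
    return precision * recall / denom


def dice_loss(
    pred: np.ndarray,
    truth: np.ndarray,
    epsilon: float = 1.0,
    symmetric_epsilon: bool = False,
) -> float:
    """Smoothed Dice loss 1 - 2*sum(P*T) / (sum(P) + sum(T) + eps).

    ``pred`` may be a soft (probabilistic) map; ``truth`` is typically
    binary.  With ``symmetric_epsilon`` the smoothing term is added to the
    numerator too, making the loss 0 for two empty masks.
    """
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if epsilon < 0:
        raise ValueError(f"epsilon must be >= 0, got {epsilon}")
    overlap = float((pred * truth).sum())
    total = float(pred.sum() + truth.sum())
    num = 2.0 * overlap + (epsilon if symmetric_epsilon else 0.0)
    denom = total + epsilon
    if denom == 0.0:  # only reachable with epsilon = 0 and two empty masks
        warnings.warn("Dice loss undefined for empty masks with epsilon = 0",
                      DegenerateMetricWarning, stacklevel=2)
        return 0.0 if symmetric_epsilon else 1.0
    return 1.0 - num / denom
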