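"""Soft dice loss for binary segmentation.

The loss is ``1 - (2*sum(p*g) + eps) / (sum(p) + sum(g) + eps)`` pooled
over everything passed in (a patch, a field, or a whole mini-batch). The
smoothing term ``eps`` keeps the loss defined when both prediction and
truth are empty and damps the gradient on near-empty patches.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dice_loss", "dice_loss_grad", "dice_coefficient"]


def _check(pred: np.ndarray, truth: np.ndarray) -> None:
    if pred.shape != truth.shape:
        raise ValueError(
            f"shape mismatch: prediction {pred.shape} vs truth {truth.shape}"
        )


def dice_loss(pred: np.ndarray, truth: np.ndarray, eps: float = 1.0) -> float:
    """Dice loss of a probability map against a binary mask, in [0, 1]."""
    _check(pred, truth)
    p = np.asarray(pred, dtype=np.float64)
    g = np.asarray(truth, dtype=np.float64)
    num = 2.0 * float((p * g).sum()) + eps
    den = float(p.sum()) + float(g.sum()) + eps
    return 1.0 - num / den


def dice_loss_grad(pred: np.ndarray, truth: np.ndarray, eps: float = 1.0) -> np.ndarray:
    """Analytic gradient d(dice_loss)/d(pred), same shape as ``pred``."""
    _check(pred, truth)
    p = np.asarray(pred, dtype=np.float64)
    g = np.asarray(truth, dtype=np.float64)
    inter = 2.0 * float((p * g).sum()) + eps
    den = float(p.sum()) + float(g.sum()) + eps
    grad = -(2.0 * g * den - inter) / den**2
    return grad.astype(np.float32)


def dice_coefficient(pred: np.ndarray, truth: np.ndarray, eps: float = 0.0) -> float:
    """Dice similarity of two masks/maps: ``1 - dice_loss`` at the same eps."""
    return 1.0 - dice_loss(pred, truth, eps=eps)
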