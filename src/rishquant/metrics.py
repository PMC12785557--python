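"""Pixel-level segmentation evaluation: Dice, IoU, precision, recall.

Empty-mask conventions (the degenerate denominators): when both masks
are empty all four metrics are 1 (a correct all-background prediction);
an empty prediction against a non-empty truth scores precision 1 (no
false positives), recall 0, DSC = IoU = 0; the mirrored case swaps
precision and recall.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = ["SegMetrics", "evaluate", "evaluate_batch"]


@dataclass(frozen=True)
class SegMetrics:
    dsc: float
    iou: float
    precision: float
    recall: float
    tp: int
    fp: int
    fn: int
    tn: int

    def as_dict(self) -> dict[str, float]:
        return {
            "dsc": self.dsc,
            "iou": self.iou,
            "precision": self.precision,
            "recall": self.recall,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
        }


def _from_counts(tp: int, fp: int, fn: int, tn: int) -> SegMetrics:
    dsc = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 1.0
    iou = tp / (tp + fp + fn) if (tp + fp + fn) else 1.0
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    return SegMetrics(dsc, iou, precision, recall, tp, fp, fn, tn)


def _as_binary(mask: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(mask)
    vals = np.unique(m)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{name} mask must be binary (0/1); got values {vals[:5]}")
    return m.astype(bool)


def evaluate(pred: np.ndarray, truth: np.ndarray) -> SegMetrics:
    """Compare two binary masks of identical shape pixelwise."""
    p = _as_binary(pred, "predicted")
    t = _as_binary(truth, "truth")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(p.size - tp - fp - fn)
    return _from_counts(tp, fp, fn, tn)


def evaluate_batch(
    pairs: Sequence[tuple[np.ndarray, np.ndarray]] | Iterable[tuple[np.ndarray, np.ndarray]],
) -> dict:
    """Evaluate several (pred, truth) pairs.

    Returns per-pair metrics plus two labeled aggregates: ``macro``
    (unweighted mean of the per-pair metrics) and ``micro`` (metrics of
    the pooled tp/fp/fn/tn counts, equivalent to evaluating one large
    concatenated image).
    """
    per_pair = [evaluate(p, t) for p, t in pairs]
    if not per_pair:
        raise ValueError("evaluate_batch needs at least one (pred, truth) pair")
    macro = {
        k: float(np.mean([getattr(m, k) for m in per_pair]))
        for k in ("dsc", "iou", "precision", "recall")
    }
    pooled = _from_counts(
        sum(m.tp for m in per_pair),
        sum(m.fp for m in per_pair),
        sum(m.fn for m in per_pair),
        sum(m.tn for m in per_pair),
    )
    return {"per_pair": per_pair, "macro": macro, "micro": pooled}
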