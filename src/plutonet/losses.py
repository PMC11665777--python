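"""Dice-form losses, the consistency objective, and segmentation metrics.

The supervised loss is the squared-denominator Dice form

    Ls = 1 - 2*sum(Pm*Pt) / (sum(Pm^2) + sum(Pt^2) + eps)

and the consistency loss applies the same divergence between the two
decoder outputs, Lc = DiceForm(Pm, Pa).  The training objective is
L = Ls + alpha*Lc; with alpha = 0 training degenerates to the
consistency-free ablation arm.  Both losses are bounded in [0, 1],
symmetric in their arguments, and differentiable for eps > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .nn import Tensor

DEFAULT_EPS = 1e-6
DEFAULT_ALPHA = 1.0


@dataclass
class MetricReport:
    dice: float
    iou: float
    precision: float
    recall: float
    auc: float
    threshold: float = 0.5

    def as_row(self) -> dict:
        return {"dice": self.dice, "iou": self.iou, "auc": self.auc,
                "precision": self.precision, "recall": self.recall}


def _pair(p, t):
    p = p if isinstance(p, Tensor) else Tensor(p)
    t = t if isinstance(t, Tensor) else Tensor(t)
    if p.data.shape != t.data.shape:
        raise ValueError(f"shape mismatch: {p.data.shape} vs {t.data.shape}")
    return p, t


def _dice_form(p: Tensor, t: Tensor, epsilon: float) -> Tensor:
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    axes = tuple(range(1, p.data.ndim))
    inter = (p * t).sum(axis=axes)
    denom = p.square().sum(axis=axes) + t.square().sum(axis=axes) + epsilon
    return (1.0 - (2.0 * inter) / denom).mean()


def dice_loss(p, t, epsilon: float = DEFAULT_EPS) -> Tensor:
    """Supervised Dice-form loss against a binary mask, batch-averaged."""
    p, t = _pair(p, t)
    return _dice_form(p, t, epsilon)


def consistency_loss(pm, pa, epsilon: float = DEFAULT_EPS) -> Tensor:
    """Dice-form divergence between the two decoder outputs (symmetric)."""
    pm, pa = _pair(pm, pa)
    return _dice_form(pm, pa, epsilon)


def total_loss(ls, lc, alpha: float = DEFAULT_ALPHA):
    """L = Ls + alpha * Lc."""
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    return ls + alpha * lc


def evaluate(p, t, threshold: float = 0.5) -> MetricReport:
    """Confusion-matrix metrics at `threshold` plus rank-based AUC.

    Degenerate cells follow a fixed convention: when a denominator is zero,
    the metric is 1 if the other marginal is empty too (nothing to find,
    nothing found) and 0 otherwise.  AUC is computed pixel-level over the
    pooled input; it is 1.0 (vacuously) when only one class is present.
    """
    p = np.asarray(p, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    if p.size == 0:
        raise ValueError("empty input")
    if p.shape != t.shape:
        raise ValueError("shape mismatch")
    pb = (p >= threshold)
    tb = (t >= 0.5)
    tp = float(np.sum(pb & tb))
    fp = float(np.sum(pb & ~tb))
    fn = float(np.sum(~pb & tb))

    def _safe(num, den, empty_other):
        if den == 0:
            return 1.0 if empty_other == 0 else 0.0
        return num / den

    dice = _safe(2 * tp, 2 * tp + fp + fn, fp + fn)
    iou = _safe(tp, tp + fp + fn, fp + fn)
    precision = _safe(tp, tp + fp, tp + fn)
    recall = _safe(tp, tp + fn, tp + fp)
    labels = tb.ravel()
    if labels.all() or not labels.any():
        auc = 1.0
    else:
        auc = float(roc_auc_score(labels, p.ravel()))
    return MetricReport(dice=dice, iou=iou, precision=precision,
                        recall=recall, auc=auc, threshold=threshold)
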