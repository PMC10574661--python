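"""Evaluation metrics for classification (Q, MCC) and regression (R², RMSE)."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN counts; positives are the highly active class (1)."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Exact confusion counts for binary labels (1 = high, 0 = weak)."""
    yt = np.asarray(y_true).astype(int)
    yp = np.asarray(y_pred).astype(int)
    if yt.shape != yp.shape:
        raise ValueError("length mismatch")
    return ConfusionCounts(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
    )


def q_accuracy(c: ConfusionCounts) -> float:
    """Predictive accuracy Q = 100 · (TP + TN) / (TP + TN + FP + FN)."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    return 100.0 * (c.tp + c.tn) / c.total


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient.

    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)); if any factor
    of the denominator is zero the coefficient is defined as 0.
    """
    if c.total == 0:
        raise ValueError("empty confusion counts")
    denom = ((c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn))
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def r2(y, y_hat) -> float:
    """Coefficient of determination 1 − Σ(y−ŷ)² / Σ(y−ȳ)²."""
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    if y.shape != y_hat.shape:
        raise ValueError("length mismatch")
    if len(y) < 2:
        raise ValueError("need at least two observations")
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("constant response: R^2 undefined")
    return float(1.0 - np.sum((y - y_hat) ** 2) / ss_tot)


def rmse(y, y_hat) -> float:
    """Root mean squared error √(Σ(y−ŷ)²/n)."""
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    if y.shape != y_hat.shape:
        raise ValueError("length mismatch")
    if len(y) == 0:
        raise ValueError("empty vectors")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))
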