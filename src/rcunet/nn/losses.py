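"""Pixel-wise binary cross-entropy for segmentation.

The per-image loss is the SUM over pixels of
``-(y log p + (1-y) log(1-p))`` and the batch loss is the arithmetic mean of
the per-image sums. Predicted probabilities are clamped into
``(eps, 1-eps)`` before the logarithms. A ``reduction="mean"`` switch
averages over pixels instead of summing, for users who prefer
size-independent loss magnitudes.
"""

from __future__ import annotations

import numpy as np

CLAMP_EPS = 1e-7


def cross_entropy(y_true: np.ndarray, y_pred: np.ndarray,
                  eps: float = CLAMP_EPS, reduction: str = "sum") -> float:
    """Cross-entropy of one image: pixel sum (or mean) of the binary terms.

    Parameters
    ----------
    y_true : binary ground-truth mask (any shape)
    y_pred : predicted probabilities, same shape
    """
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"shape mismatch: mask {y_true.shape} vs prediction {y_pred.shape}")
    p = np.clip(y_pred, eps, 1.0 - eps)
    terms = -(y_true * np.log(p) + (1.0 - y_true) * np.log(1.0 - p))
    if reduction == "sum":
        return float(terms.sum())
    if reduction == "mean":
        return float(terms.mean())
    raise ValueError(f"unknown reduction {reduction!r}")


def batch_loss(y_true: np.ndarray, y_pred: np.ndarray,
               eps: float = CLAMP_EPS, reduction: str = "sum") -> float:
    """Mean over the batch of per-image cross-entropies.

    ``y_true``/``y_pred`` are stacked along axis 0; the batch must be
    non-empty.
    """
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"shape mismatch: masks {y_true.shape} vs predictions {y_pred.shape}")
    if y_true.shape[0] < 1:
        raise ValueError("empty batch")
    n = y_true.shape[0]
    return float(sum(cross_entropy(y_true[i], y_pred[i], eps, reduction)
                     for i in range(n)) / n)


def batch_loss_grad(y_true: np.ndarray, y_pred: np.ndarray,
                    eps: float = CLAMP_EPS,
                    reduction: str = "sum") -> np.ndarray:
    """Gradient of :func:`batch_loss` w.r.t. the predicted probabilities.

    Pixels whose prediction sits outside the clamp interval contribute zero
    gradient (the clamp is flat there).
    """
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    n = y_true.shape[0]
    p = np.clip(y_pred, eps, 1.0 - eps)
    g = (p - y_true) / (p * (1.0 - p)) / n
    g[(y_pred < eps) | (y_pred > 1.0 - eps)] = 0.0
    if reduction == "mean":
        g /= np.prod(y_true.shape[1:])
    return g
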