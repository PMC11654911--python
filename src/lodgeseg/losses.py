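"""Focal + Dice composite loss for imbalanced 4-class lodging segmentation.

Lodged (L) and half-lodged (HL) canopy cover far fewer pixels than background
and upright crop, so plain cross-entropy is dominated by the easy majority
classes.  The focal term -(1-pt)^gamma * log(pt) down-weights well-classified
pixels (gamma = 2 by default); the Dice term 1 - 2*sum(p*y)/(sum(p)+sum(y))
scores region overlap per class, insensitive to class frequency.  The training
loss is a configurable weighted sum, 1:1 by default.

``segmentation_loss_and_grad`` is the training-path entry point: it takes raw
logits and integer labels and returns the scalar loss together with its exact
analytic gradient with respect to the logits (softmax folded in).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "focal_loss",
    "dice_loss",
    "combined_loss",
    "one_hot",
    "softmax",
    "segmentation_loss_and_grad",
]

_PT_EPS = 1e-12
_DICE_EPS = 1e-6


def focal_loss(pt: np.ndarray, gamma: float = 2.0) -> float:
    """Mean of -(1-pt)^gamma * log(pt) over pixels.

    ``pt`` is the predicted probability of each pixel's true class; gamma = 0
    reduces to cross-entropy.
    """
    pt = np.asarray(pt, dtype=float)
    if np.any(pt < 0) or np.any(pt > 1):
        raise ValueError("pt values must lie in [0, 1]")
    pt = np.clip(pt, _PT_EPS, 1.0)
    return float(np.mean(-((1.0 - pt) ** gamma) * np.log(pt)))


def dice_loss(
    pred: np.ndarray,
    target: np.ndarray,
    class_axis: int | None = None,
    eps: float = _DICE_EPS,
) -> float:
    """1 - 2*sum(p*y)/(sum(p)+sum(y)), averaged over classes.

    With ``class_axis=None`` the arrays are treated as one binary mask/score
    map; otherwise the loss is averaged over the classes along that axis.
    """
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {target.shape}")
    if class_axis is None:
        inter = float(np.sum(pred * target))
        denom = float(np.sum(pred) + np.sum(target))
        return 1.0 - (2.0 * inter + eps) / (denom + eps)
    pred = np.moveaxis(pred, class_axis, 0)
    target = np.moveaxis(target, class_axis, 0)
    k = pred.shape[0]
    losses = []
    for c in range(k):
        inter = float(np.sum(pred[c] * target[c]))
        denom = float(np.sum(pred[c]) + np.sum(target[c]))
        losses.append(1.0 - (2.0 * inter + eps) / (denom + eps))
    return float(np.mean(losses))


def combined_loss(
    pred: np.ndarray,
    target: np.ndarray,
    class_axis: int = 1,
    w_focal: float = 1.0,
    w_dice: float = 1.0,
    gamma: float = 2.0,
) -> float:
    """w_f * Focal + w_d * Dice on class probabilities vs. one-hot labels."""
    if w_focal < 0 or w_dice < 0:
        raise ValueError("loss weights must be nonnegative")
    pt = np.sum(
        np.asarray(pred, dtype=float) * np.asarray(target, dtype=float), axis=class_axis
    )
    return w_focal * focal_loss(pt, gamma) + w_dice * dice_loss(
        pred, target, class_axis=class_axis
    )


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """(B, H, W) integer labels -> (B, K, H, W) one-hot float32."""
    labels = np.asarray(labels)
    out = np.zeros((labels.shape[0], n_classes, *labels.shape[1:]), dtype=np.float32)
    for c in range(n_classes):
        out[:, c] = labels == c
    return out


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def segmentation_loss_and_grad(
    logits: np.ndarray,
    labels: np.ndarray,
    w_focal: float = 1.0,
    w_dice: float = 1.0,
    gamma: float = 2.0,
) -> tuple[float, np.ndarray]:
    """Combined loss and its exact gradient w.r.t. the logits.

    logits: (B, K, H, W); labels: (B, H, W) integers in [0, K).  The gradient
    is assembled from d(loss)/d(probabilities) pushed through the softmax
    Jacobian: dz = p * (g - sum_c g_c p_c).
    """
    if w_focal < 0 or w_dice < 0:
        raise ValueError("loss weights must be nonnegative")
    b, k, h, w = logits.shape
    p = softmax(logits.astype(np.float64), axis=1)
    y = one_hot(labels, k).astype(np.float64)
    n_pix = b * h * w

    pt = np.clip(np.sum(p * y, axis=1), _PT_EPS, 1.0)  # (B, H, W)
    one_m = 1.0 - pt
    focal = float(np.mean(-(one_m**gamma) * np.log(pt)))
    # d(focal)/d(pt), already averaged over pixels
    dfocal_dpt = (gamma * one_m ** (gamma - 1.0) * np.log(pt) - one_m**gamma / pt) / n_pix
    g = w_focal * dfocal_dpt[:, None] * y  # focal reaches p only through pt

    inter = np.sum(p * y, axis=(0, 2, 3))  # per class
    sums = np.sum(p, axis=(0, 2, 3)) + np.sum(y, axis=(0, 2, 3))
    num = 2.0 * inter + _DICE_EPS
    den = sums + _DICE_EPS
    dice = float(np.mean(1.0 - num / den))
    # d(dice)/d(p_c) = (-2*y/den_c + num_c/den_c^2) / K
    g = g + w_dice * (
        -2.0 * y / den[None, :, None, None] + (num / den**2)[None, :, None, None]
    ) / k

    gp = np.sum(g * p, axis=1, keepdims=True)
    dlogits = (p * (g - gp)).astype(np.float32)
    loss = w_focal * focal + w_dice * dice
    return loss, dlogits
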