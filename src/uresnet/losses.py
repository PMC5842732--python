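"""Training objectives over per-voxel class probabilities.

Four candidate losses with a shared interface, each defined as a sum over
all N voxels of a batch of patches (per-voxel means are for reporting
only).  ``probs`` are softmax outputs, ``onehot`` the one-hot encoded
reference labels; both are flattened internally to (N, C).

* ``cross_entropy``            -- classical categorical cross-entropy.
* ``weighted_cross_entropy``   -- per-class voxel weights to counter the
  extreme background/lesion imbalance.
* ``bootstrapped_cross_entropy`` -- drops the contribution of voxels whose
  true-class probability already exceeds a threshold tau, focusing the
  optimization on hard examples.
* ``dice_loss``                -- one minus the soft (pseudo) Dice
  coefficient averaged over classes; probabilities are used directly,
  without thresholding.

Each loss has a companion ``*_grad`` returning dPsi/dprobs with the shape
of ``probs``, used by the training engine (chained through the softmax).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: floor inside logarithms of the cross-entropy family
LOG_FLOOR = 1e-12

#: smoothing constant in the soft-Dice denominator
DICE_EPS = 1e-7

LOSS_KINDS = ("cross_entropy", "weighted_ce", "bootstrapped_ce", "dice")


@dataclass
class LossConfig:
    """Selects and parametrizes a training objective."""

    kind: str = "cross_entropy"
    class_weights: tuple[float, ...] | None = None  # weighted_ce
    tau: float = 0.8  # bootstrapped_ce
    epsilon: float = DICE_EPS  # dice

    def __post_init__(self) -> None:
        if self.kind not in LOSS_KINDS:
            raise ValueError(f"kind must be one of {LOSS_KINDS}")
        if self.class_weights is not None and any(w <= 0 for w in self.class_weights):
            raise ValueError("class weights must be positive")
        if not 0.0 < self.tau <= 1.0:
            raise ValueError("tau must lie in (0, 1]")


def _flatten(probs: np.ndarray, onehot: np.ndarray, class_axis: int):
    if probs.shape != onehot.shape:
        raise ValueError(f"probs shape {probs.shape} != labels shape {onehot.shape}")
    p = np.moveaxis(np.asarray(probs, dtype=np.float64), class_axis, -1)
    y = np.moveaxis(np.asarray(onehot, dtype=np.float64), class_axis, -1)
    c = p.shape[-1]
    return p.reshape(-1, c), y.reshape(-1, c)


def _unflatten(grad_flat, probs, class_axis):
    g = grad_flat.reshape(np.moveaxis(probs, class_axis, -1).shape)
    return np.moveaxis(g, -1, class_axis)


def cross_entropy(probs, onehot, *, class_axis: int = -1) -> float:
    """Psi = -sum_n y_n log f(Theta, x_n), summed over all voxels."""
    p, y = _flatten(probs, onehot, class_axis)
    return float(-(y * np.log(np.maximum(p, LOG_FLOOR))).sum())


def cross_entropy_grad(probs, onehot, *, class_axis: int = -1) -> np.ndarray:
    p, y = _flatten(probs, onehot, class_axis)
    g = -y / np.maximum(p, LOG_FLOOR)
    return _unflatten(g, probs, class_axis)


def weighted_cross_entropy(probs, onehot, weights, *, class_axis: int = -1) -> float:
    """Cross-entropy with per-class voxel weights omega(y_n)."""
    p, y = _flatten(probs, onehot, class_axis)
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != (p.shape[1],):
        raise ValueError("weights must have one entry per class")
    wn = y @ w  # weight of each voxel's true class
    return float(-(wn * (y * np.log(np.maximum(p, LOG_FLOOR))).sum(axis=1)).sum())


def weighted_cross_entropy_grad(probs, onehot, weights, *, class_axis: int = -1):
    p, y = _flatten(probs, onehot, class_axis)
    w = np.asarray(weights, dtype=np.float64)
    wn = y @ w
    g = -(wn[:, None] * y) / np.maximum(p, LOG_FLOOR)
    return _unflatten(g, probs, class_axis)


def bootstrapped_cross_entropy(probs, onehot, tau: float, *, class_axis: int = -1) -> float:
    """Online bootstrapped cross-entropy.

    Voxels whose true-class probability exceeds ``tau`` are dropped from the
    sum (phi_n = 1 -> zero contribution); the remainder contribute the
    ordinary -log of their true-class probability.
    """
    p, y = _flatten(probs, onehot, class_axis)
    p_true = (p * y).sum(axis=1)
    keep = p_true <= tau
    return float(-np.log(np.maximum(p_true[keep], LOG_FLOOR)).sum())


def bootstrapped_cross_entropy_grad(probs, onehot, tau: float, *, class_axis: int = -1):
    p, y = _flatten(probs, onehot, class_axis)
    p_true = (p * y).sum(axis=1)
    keep = (p_true <= tau).astype(np.float64)
    g = -(keep / np.maximum(p_true, LOG_FLOOR))[:, None] * y
    return _unflatten(g, probs, class_axis)


def dice_loss(probs, onehot, epsilon: float = DICE_EPS, *, class_axis: int = -1) -> float:
    """1 minus the class-averaged soft Dice coefficient.

    A class absent from both the labels and the prediction mass contributes
    Dice 1 (loss 0 for that class): perfect agreement on absence.
    """
    p, y = _flatten(probs, onehot, class_axis)
    num = 2.0 * (y * p).sum(axis=0)
    den = p.sum(axis=0) + y.sum(axis=0)
    dice = np.where(den > epsilon, num / (den + epsilon), 1.0)
    return float(1.0 - dice.mean())


def dice_loss_grad(probs, onehot, epsilon: float = DICE_EPS, *, class_axis: int = -1):
    p, y = _flatten(probs, onehot, class_axis)
    c = p.shape[1]
    num = 2.0 * (y * p).sum(axis=0)
    den = p.sum(axis=0) + y.sum(axis=0) + epsilon
    present = (den - epsilon) > epsilon
    # d/dp_{n,c} [num_c/den_c] = (2 y_{n,c} den_c - num_c) / den_c^2
    g = -(2.0 * y * den[None, :] - num[None, :]) / (den[None, :] ** 2) / c
    g = np.where(present[None, :], g, 0.0)
    return _unflatten(g, probs, class_axis)


def loss_and_grad(cfg: LossConfig, probs, onehot, *, class_axis: int = -1):
    """Dispatch (value, dPsi/dprobs) for the configured loss."""
    if cfg.kind == "cross_entropy":
        return (
            cross_entropy(probs, onehot, class_axis=class_axis),
            cross_entropy_grad(probs, onehot, class_axis=class_axis),
        )
    if cfg.kind == "weighted_ce":
        w = cfg.class_weights
        if w is None:
            raise ValueError("weighted_ce requires class_weights")
        return (
            weighted_cross_entropy(probs, onehot, w, class_axis=class_axis),
            weighted_cross_entropy_grad(probs, onehot, w, class_axis=class_axis),
        )
    if cfg.kind == "bootstrapped_ce":
        return (
            bootstrapped_cross_entropy(probs, onehot, cfg.tau, class_axis=class_axis),
            bootstrapped_cross_entropy_grad(probs, onehot, cfg.tau, class_axis=class_axis),
        )
    return (
        dice_loss(probs, onehot, cfg.epsilon, class_axis=class_axis),
        dice_loss_grad(probs, onehot, cfg.epsilon, class_axis=class_axis),
    )


def inverse_frequency_weights(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Default omega: inverse class frequency, normalized to mean 1.

    Classes absent from ``labels`` receive the mean weight of the present
    classes so the normalization stays well-defined.
    """
    counts = np.bincount(np.asarray(labels).ravel(), minlength=n_classes).astype(float)
    present = counts > 0
    inv = np.zeros(n_classes)
    inv[present] = 1.0 / counts[present]
    if not present.all():
        inv[~present] = inv[present].mean() if present.any() else 1.0
    return inv / inv.mean()
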