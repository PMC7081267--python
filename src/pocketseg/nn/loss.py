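"""The continuous-Dice training objective.

For a predicted probability field y and a binary target t on the same
lattice the objective is the negative smoothed Dice coefficient

    C(y, t) = -(2 Σ y·t + ε) / (Σ (y + t) + ε)

with ε a smoothing factor (default 0.01).  C is bounded in [-1, 0); it
equals -1 at perfect overlap and, through ε, also in the limit where both
fields are identically zero — so empty-pocket negative examples are not
penalized when the model correctly predicts nothing.
"""

from __future__ import annotations

import numpy as np

DEFAULT_EPSILON = 0.01


def _check(y: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    if y.shape != t.shape:
        raise ValueError(f"shape mismatch: y {y.shape} vs t {t.shape}")
    return y, t


def dice_loss(y: np.ndarray, t: np.ndarray, epsilon: float = DEFAULT_EPSILON) -> float:
    """Negative smoothed Dice coefficient of one (y, t) pair."""
    y, t = _check(y, t)
    num = 2.0 * np.sum(y * t) + epsilon
    den = np.sum(y + t) + epsilon
    return float(-num / den)


def dice_loss_batch(y: np.ndarray, t: np.ndarray, epsilon: float = DEFAULT_EPSILON) -> float:
    """Mean per-sample Dice loss over a batch (axis 0 indexes samples)."""
    y, t = _check(y, t)
    axes = tuple(range(1, y.ndim))
    num = 2.0 * np.sum(y * t, axis=axes) + epsilon
    den = np.sum(y + t, axis=axes) + epsilon
    return float(np.mean(-num / den))


def dice_loss_batch_grad(
    y: np.ndarray, t: np.ndarray, epsilon: float = DEFAULT_EPSILON
) -> np.ndarray:
    """dL/dy of the batch-mean Dice loss; same shape as y."""
    y, t = _check(y, t)
    axes = tuple(range(1, y.ndim))
    num = 2.0 * np.sum(y * t, axis=axes, keepdims=True) + epsilon
    den = np.sum(y + t, axis=axes, keepdims=True) + epsilon
    n = y.shape[0]
    # d(-num/den)/dy_i = (num - 2 t_i den) / den^2
    return ((num - 2.0 * t * den) / den**2 / n).astype(np.float32)
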