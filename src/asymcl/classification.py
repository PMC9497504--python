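"""Binary classification losses for the fine-tuning stage.

Cross-entropy and focal loss on an estimated probability ``p`` of class 1
against a ground truth ``y`` in {0, 1}.  The focal loss down-weights
well-classified samples by ``(1 - p_t)**gamma`` where ``p_t`` is the
probability assigned to the true class, which keeps the gradient signal on
hard (often minority-class) examples.

Both losses accept scalars or vectors and return the mean over samples.
Probabilities are clamped to ``[eps, 1 - eps]`` with ``eps = 1e-12`` before
any logarithm, so a maximally wrong prediction yields a large finite loss
rather than infinity.
"""

from __future__ import annotations

import numpy as np

__all__ = ["binary_cross_entropy", "focal_loss", "focal_loss_grad_p"]

_EPS = 1e-12


def _validate(p: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.atleast_1d(np.asarray(p, dtype=float))
    y = np.atleast_1d(np.asarray(y))
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: p {p.shape} vs y {y.shape}")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("ground-truth labels must be in {0, 1}")
    return np.clip(p, _EPS, 1.0 - _EPS), y.astype(float)


def binary_cross_entropy(p, y) -> float:
    """Mean binary cross-entropy ``-y log p - (1 - y) log(1 - p)``."""
    p, y = _validate(p, y)
    return float(np.mean(-y * np.log(p) - (1.0 - y) * np.log1p(-p)))


def focal_loss(p, y, gamma: float = 2.0) -> float:
    """Mean focal loss ``-y (1-p)^g log p - (1-y) p^g log(1-p)``.

    Reduces to :func:`binary_cross_entropy` at ``gamma = 0``.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    p, y = _validate(p, y)
    pos = (1.0 - p) ** gamma * np.log(p)
    neg = p**gamma * np.log1p(-p)
    return float(np.mean(-y * pos - (1.0 - y) * neg))


def focal_loss_grad_p(p, y, gamma: float = 2.0) -> np.ndarray:
    """d(mean focal loss)/dp, elementwise; supports gamma = 0 (plain CE).

    Used by the training loop to push gradients into the classifier logits.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    p, y = _validate(p, y)
    m = p.size
    lp = np.log(p)
    l1p = np.log1p(-p)
    if gamma == 0.0:
        d = -y / p + (1.0 - y) / (1.0 - p)
    else:
        d_pos = -gamma * (1.0 - p) ** (gamma - 1.0) * lp + (1.0 - p) ** gamma / p
        d_neg = gamma * p ** (gamma - 1.0) * l1p - p**gamma / (1.0 - p)
        d = -y * d_pos - (1.0 - y) * d_neg
    return d / m
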