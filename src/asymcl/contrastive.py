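"""Supervised contrastive losses for imbalanced classification.

Implements the pairwise machinery and four batch-level losses over a set of
l2-normalized embeddings ``z_1..z_n`` with integer class labels:

* CL   -- supervised contrastive loss: pulls same-class pairs together by
  maximising the softmax pair probability ``p_ij`` of each positive pair.
* FCL  -- focal contrastive loss: each positive log-term is down-weighted by
  ``(1 - p_ij)`` so easy (already-close) pairs contribute less.
* ACL  -- asymmetric contrastive loss: adds an explicit negative-pair term
  ``log(1 - p_ij)`` averaged over each anchor's negatives, weighted by
  ``eta >= 0``.  An anchor that has no positive partner in the mini-batch
  (the typical fate of a minority-class sample under heavy imbalance) still
  contributes through this term.
* AFCL -- asymmetric focal contrastive loss: ACL whose positive term carries
  the focusing exponent ``(1 - p_ij)**gamma``; the negative term is left
  unmodified because ``p_ij`` is typically small for large batches.

All four are special cases of one (eta, gamma) family::

    L = -sum_i [ L_i^+ + eta * L_i^- ]
    L_i^+ = (1/|P_i|) sum_{j in P_i} (1 - p_ij)^gamma * log p_ij
    L_i^- = (1/|N_i|) sum_{j in N_i} log(1 - p_ij)

with ``p_ij = exp(z_i.z_j / tau) / sum_{k != i} exp(z_i.z_k / tau)``.
CL = (eta=0, gamma=0), FCL = (eta=0, gamma=1), ACL = (gamma=0); the shared
code path makes these reductions exact in floating point.

Every loss also exposes its analytic gradient with respect to the embedding
matrix, so the module is self-contained for gradient-based training without
an autodiff framework.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FeatureBatch",
    "ContrastiveConfig",
    "PairProbabilities",
    "l2_normalize",
    "l2_normalize_backward",
    "cosine_similarity_matrix",
    "pair_probabilities",
    "positive_negative_partition",
    "contrastive_loss",
    "focal_contrastive_loss",
    "asymmetric_contrastive_loss",
    "asymmetric_focal_contrastive_loss",
    "contrastive_loss_value_and_grad",
]

#: default temperature for all contrastive losses
DEFAULT_TAU = 0.07

_NORM_TOL = 1e-6
#: clamp so log(1 - p) stays finite when one similarity dominates the row
_ONE_MINUS_P_FLOOR = 1e-12


def l2_normalize(features: np.ndarray) -> np.ndarray:
    """Scale each row of ``features`` to unit Euclidean norm.

    Raises
    ------
    ValueError
        If any row is (numerically) the zero vector, whose direction is
        undefined.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"expected a 2-d feature matrix, got ndim={X.ndim}")
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    if np.any(norms < 1e-12):
        bad = np.flatnonzero(norms.ravel() < 1e-12)
        raise ValueError(f"zero-norm feature row(s) at indices {bad.tolist()}")
    return X / norms


def l2_normalize_backward(v: np.ndarray, dz: np.ndarray) -> np.ndarray:
    """Backpropagate through row-wise l2 normalization ``z = v / |v|``.

    ``dL/dv = (dL/dz - z (z . dL/dz)) / |v|`` per row.
    """
    r = np.linalg.norm(v, axis=1, keepdims=True)
    z = v / r
    return (dz - z * np.sum(z * dz, axis=1, keepdims=True)) / r


@dataclass(frozen=True)
class FeatureBatch:
    """A mini-batch of unit-norm embeddings with integer class labels.

    Rows of ``embeddings`` must be l2-normalized (within 1e-6); use
    :meth:`from_raw` to normalize arbitrary feature vectors on entry.
    """

    embeddings: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        Z = np.asarray(self.embeddings, dtype=float)
        y = np.asarray(self.labels)
        object.__setattr__(self, "embeddings", Z)
        object.__setattr__(self, "labels", y)
        if Z.ndim != 2:
            raise ValueError("embeddings must be an n x d matrix")
        n, d = Z.shape
        if n < 2:
            raise ValueError("a contrastive batch needs at least 2 samples")
        if d < 1:
            raise ValueError("embedding dimension must be >= 1")
        if y.shape != (n,):
            raise ValueError(f"labels must have shape ({n},), got {y.shape}")
        norms = np.linalg.norm(Z, axis=1)
        if np.any(np.abs(norms - 1.0) > _NORM_TOL):
            raise ValueError(
                "embedding rows must be unit-norm (within 1e-6); "
                "use FeatureBatch.from_raw to normalize"
            )

    @classmethod
    def from_raw(cls, features: np.ndarray, labels: np.ndarray) -> "FeatureBatch":
        """Build a batch from unnormalized features, applying l2 normalization."""
        return cls(l2_normalize(features), np.asarray(labels))

    @property
    def n(self) -> int:
        return self.embeddings.shape[0]

    @property
    def d(self) -> int:
        return self.embeddings.shape[1]


@dataclass(frozen=True)
class ContrastiveConfig:
    """Loss-variant selector with its hyperparameters.

    Parameters
    ----------
    variant : {"cl", "fcl", "acl", "afcl"}
    tau : float
        Temperature dividing the cosine similarities; smaller values sharpen
        the pair-probability softmax.  Default 0.07.
    eta : float
        Weight of the negative-pair term (ACL/AFCL).  Large batches make
        ``p_ij`` small and hence the negative term small, so useful values
        are large (the reference grid is {0, 60, 120, 180, 240, 300}).
    gamma : float
        Focusing exponent on ``(1 - p_ij)`` in the positive term (AFCL).
    reduction : {"mean", "sum"}
        ``sum`` is the literal sum over anchors; ``mean`` divides by the
        batch size, decoupling the learning rate from the batch size.
        Default ``mean``.
    """

    variant: str = "afcl"
    tau: float = DEFAULT_TAU
    eta: float = 0.0
    gamma: float = 0.0
    reduction: str = "mean"

    def __post_init__(self) -> None:
        if self.variant not in ("cl", "fcl", "acl", "afcl"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.reduction not in ("mean", "sum"):
            raise ValueError("reduction must be 'mean' or 'sum'")

    @property
    def effective_eta(self) -> float:
        return self.eta if self.variant in ("acl", "afcl") else 0.0

    @property
    def effective_gamma(self) -> float:
        if self.variant == "cl":
            return 0.0
        if self.variant == "fcl":
            return 1.0
        if self.variant == "acl":
            return 0.0
        return self.gamma

    def value_and_grad(self, batch: FeatureBatch) -> tuple[float, np.ndarray]:
        """Loss value and its gradient w.r.t. the embeddings."""
        return contrastive_loss_value_and_grad(
            batch,
            tau=self.tau,
            eta=self.effective_eta,
            gamma=self.effective_gamma,
            reduction=self.reduction,
        )

    def value(self, batch: FeatureBatch) -> float:
        return self.value_and_grad(batch)[0]


@dataclass(frozen=True)
class PairProbabilities:
    """Softmax pair probabilities ``p_ij`` (diagonal undefined, stored as NaN)."""

    probs: np.ndarray
    log_probs: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return self.probs.shape[0]


def cosine_similarity_matrix(batch: FeatureBatch) -> np.ndarray:
    """Pairwise cosine similarities ``z_i . z_j`` of a unit-norm batch.

    Symmetric with unit diagonal; entries lie in [-1, 1] up to rounding.
    """
    S = batch.embeddings @ batch.embeddings.T
    # rounding can push |z_i.z_j| infinitesimally past 1
    return np.clip(S, -1.0, 1.0)


def _log_pair_probabilities(Z: np.ndarray, tau: float) -> tuple[np.ndarray, np.ndarray]:
    """Masked log-softmax of similarities/tau.  Returns (log p, p).

    The diagonal (self-similarity) is excluded from each row's normalization
    by masking to -inf before the max-shift, so ``p`` has an exact zero
    diagonal and ``log p`` a -inf diagonal.
    """
    n = Z.shape[0]
    S = (Z @ Z.T) / tau
    eye = np.eye(n, dtype=bool)
    S = np.where(eye, -np.inf, S)
    m = np.max(S, axis=1, keepdims=True)
    E = np.exp(S - m)  # diagonal exp(-inf) = 0
    sumE = np.sum(E, axis=1, keepdims=True)
    logp = S - (m + np.log(sumE))
    p = E / sumE
    return logp, p


def pair_probabilities(batch: FeatureBatch, tau: float = DEFAULT_TAU) -> PairProbabilities:
    """Temperature-scaled softmax probabilities that i and j share a class.

    Each row is a softmax over the other ``n - 1`` samples, computed with a
    max-shifted exponent for stability.  Off-diagonal entries are in (0, 1)
    and sum to 1 per row; the diagonal is undefined and returned as NaN.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    logp, p = _log_pair_probabilities(batch.embeddings, tau)
    probs = p.copy()
    np.fill_diagonal(probs, np.nan)
    return PairProbabilities(probs=probs, log_probs=logp)


def positive_negative_partition(
    labels: np.ndarray,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-anchor index sets (P_i, N_i).

    ``P_i`` holds the indices j != i with ``labels[j] == labels[i]`` and
    ``N_i`` the rest; together they partition the anchor's candidate set.
    """
    y = np.asarray(labels)
    n = y.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to form pairs")
    same = y[:, None] == y[None, :]
    out = []
    for i in range(n):
        others = np.arange(n) != i
        out.append((np.flatnonzero(same[i] & others), np.flatnonzero(~same[i])))
    return out


def _masks(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(labels)
    same = y[:, None] == y[None, :]
    eye = np.eye(y.shape[0], dtype=bool)
    return same & ~eye, ~same


def _value_and_grad_arrays(
    Z: np.ndarray,
    labels: np.ndarray,
    tau: float,
    eta: float,
    gamma: float,
    reduction: str,
    warn_no_positives: bool,
) -> tuple[float, np.ndarray]:
    """Loss core on raw arrays; callers guarantee sensible rows.

    The training loop feeds eps-safe normalized projections through here so
    that a transiently dead (all-zero) projection row degrades gracefully
    instead of aborting the fit; the public entry point goes through the
    strictly validated :class:`FeatureBatch`.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if eta < 0 or gamma < 0:
        raise ValueError("eta and gamma must be >= 0")
    if reduction not in ("mean", "sum"):
        raise ValueError("reduction must be 'mean' or 'sum'")

    n = Z.shape[0]
    logp, p = _log_pair_probabilities(Z, tau)
    pos, neg = _masks(labels)
    npos = pos.sum(axis=1)
    nneg = neg.sum(axis=1)

    if warn_no_positives and eta == 0.0 and not npos.any():
        warnings.warn(
            "no anchor has a positive partner: the loss is identically 0",
            RuntimeWarning,
            stacklevel=2,
        )

    inv_pos = np.divide(1.0, npos, out=np.zeros(n), where=npos > 0)
    inv_neg = np.divide(1.0, nneg, out=np.zeros(n), where=nneg > 0)

    one_minus_p = 1.0 - p
    if gamma == 0.0:
        w_focus = np.ones_like(p)
    elif gamma == 1.0:
        w_focus = one_minus_p
    else:
        w_focus = one_minus_p**gamma

    # positive term; logp diagonal is -inf but the mask discards it
    with np.errstate(invalid="ignore"):
        pos_terms = np.where(pos, w_focus * logp, 0.0)
    L_pos = pos_terms.sum(axis=1) * inv_pos

    # negative term, clamped away from log(0)
    log1mp = np.log1p(-np.minimum(p, 1.0 - _ONE_MINUS_P_FLOOR))
    L_neg = np.where(neg, log1mp, 0.0).sum(axis=1) * inv_neg

    loss = float(-(L_pos + eta * L_neg).sum())
    scale = 1.0 / n if reduction == "mean" else 1.0
    loss *= scale

    # dL/dp_ij, zero outside P_i / N_i (masked entries may evaluate to
    # inf/nan on the excluded diagonal before np.where discards them)
    W = np.zeros_like(p)
    with np.errstate(invalid="ignore", over="ignore"):
        if npos.any():
            omp = np.maximum(one_minus_p, _ONE_MINUS_P_FLOOR)
            p_safe = np.maximum(p, 1e-300)
            if gamma == 0.0:
                d_pos = 1.0 / p_safe
            else:
                d_pos = -gamma * omp ** (gamma - 1.0) * logp + w_focus / p_safe
            W += np.where(pos, -inv_pos[:, None] * d_pos, 0.0)
        if eta > 0.0 and nneg.any():
            omp = np.maximum(one_minus_p, _ONE_MINUS_P_FLOOR)
            W += np.where(neg, eta * inv_neg[:, None] / omp, 0.0)

    # softmax Jacobian per row: dL/ds_ij = p_ij (W_ij - sum_k W_ik p_ik)
    G = p * (W - np.sum(W * p, axis=1, keepdims=True))
    grad = scale * (G + G.T) @ Z / tau
    return loss, grad


def contrastive_loss_value_and_grad(
    batch: FeatureBatch,
    tau: float = DEFAULT_TAU,
    eta: float = 0.0,
    gamma: float = 0.0,
    reduction: str = "mean",
    *,
    warn_no_positives: bool = True,
) -> tuple[float, np.ndarray]:
    """Unified (eta, gamma) contrastive loss and its embedding gradient.

    Anchors with an empty positive set contribute no positive term; with
    ``eta > 0`` they still contribute their negative term, which is the
    asymmetric losses' point.  Anchors with an empty negative set (single
    class in the batch) contribute only the positive term.
    """
    return _value_and_grad_arrays(
        batch.embeddings, batch.labels, tau, eta, gamma, reduction, warn_no_positives
    )


def contrastive_loss(
    batch: FeatureBatch, tau: float = DEFAULT_TAU, reduction: str = "mean"
) -> float:
    """Supervised contrastive loss (positive pairs only)."""
    return contrastive_loss_value_and_grad(batch, tau, 0.0, 0.0, reduction)[0]


def focal_contrastive_loss(
    batch: FeatureBatch, tau: float = DEFAULT_TAU, reduction: str = "mean"
) -> float:
    """Focal contrastive loss: positive log-terms weighted by (1 - p_ij)."""
    return contrastive_loss_value_and_grad(batch, tau, 0.0, 1.0, reduction)[0]


def asymmetric_contrastive_loss(
    batch: FeatureBatch,
    tau: float = DEFAULT_TAU,
    eta: float = 0.0,
    reduction: str = "mean",
) -> float:
    """Asymmetric contrastive loss: CL plus an eta-weighted negative-pair term."""
    return contrastive_loss_value_and_grad(batch, tau, eta, 0.0, reduction)[0]


def asymmetric_focal_contrastive_loss(
    batch: FeatureBatch,
    tau: float = DEFAULT_TAU,
    eta: float = 0.0,
    gamma: float = 0.0,
    reduction: str = "mean",
) -> float:
    """Asymmetric focal contrastive loss, the full (eta, gamma) family."""
    return contrastive_loss_value_and_grad(batch, tau, eta, gamma, reduction)[0]
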