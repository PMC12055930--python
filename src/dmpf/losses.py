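"""Weighted segmentation losses and their composition.

The three composite losses of the framework are

* supervised: ``(1/N_L)(1/K) sum_i [L_s(W_cdif, p_A_i, y_i) + L_s(W_dis, p_B_i, y_i)]``
  with ``L_s = L_Dice + 0.5 * L_CE``,
* cross-pseudo-supervision: ``(1/(N_L+N_U))(1/K) sum_q [L_CE(W_cdif, p_A_q, yhat_B_q)
  + L_CE(W_dis, p_B_q, yhat_A_q)]`` (pseudo-labels are constants — no
  gradient flows through the model that produced them),
* mixed: ``L_s(W_cdif, p_A_m, y_m_A) + L_s(W_dis, p_B_m, y_m_B)`` on the
  double-mix pairs, averaged over the batch but carrying no 1/K factor
  (it is written without one; see docs/methods.md).

The total combines them with a Gaussian ramp-up on the unsupervised term:
``L = L_sup + L_mix + theta * exp(-5 (1 - min(e/E, 1))^2) * L_cps``.

Every loss returns, on request, its analytic gradient with respect to the
logits, which the numpy network consumes directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "LossWeights", "LossBreakdown",
    "softmax", "weighted_ce", "weighted_dice_loss", "seg_loss",
    "supervised_loss", "cps_loss", "mixed_loss",
    "gaussian_rampup", "total_loss",
]

DICE_SMOOTH = 1e-5


@dataclass(frozen=True)
class LossWeights:
    """A per-category weight vector as consumed by the losses."""

    per_category: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.per_category, dtype=float)
        if np.any(~np.isfinite(w)) or np.any(w < 0):
            raise ValueError("loss weights must be finite and nonnegative")
        object.__setattr__(self, "per_category", w)


@dataclass(frozen=True)
class LossBreakdown:
    supervised: float
    mixed: float
    unsupervised: float
    ramp_factor: float      # theta * ramp(epoch), in [0, theta]
    total: float


def softmax(logits: np.ndarray, axis: int = 0) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _as_weights(weights) -> np.ndarray:
    if isinstance(weights, LossWeights):
        return weights.per_category
    return LossWeights(np.asarray(weights, dtype=float)).per_category


def _check_target(target: np.ndarray, num_classes: int) -> np.ndarray:
    t = np.asarray(target)
    if not np.issubdtype(t.dtype, np.integer):
        if not np.all(t == np.round(t)):
            raise ValueError("target labels must be integers")
        t = t.astype(np.int64)
    if t.min() < 0 or t.max() >= num_classes:
        raise ValueError(f"target labels must lie in [0, {num_classes})")
    return t


def weighted_ce(weights, logits: np.ndarray, target: np.ndarray,
                return_grad: bool = False):
    """Weighted cross-entropy: mean over voxels of
    ``-w[y_j] * log softmax(logits)[y_j, j]``.

    ``logits`` has shape ``(K, *spatial)``; the weight applied at each
    voxel is indexed by that voxel's target label.
    """
    w = _as_weights(weights)
    k = logits.shape[0]
    if w.size != k:
        raise ValueError("weight vector length must equal number of classes")
    t = _check_target(target, k)
    p = softmax(logits, axis=0)
    flat_p = p.reshape(k, -1)
    flat_t = t.reshape(-1)
    n = flat_t.size
    idx = np.arange(n)
    p_true = np.clip(flat_p[flat_t, idx], 1e-12, None)
    wt = w[flat_t]
    loss = float(np.mean(-wt * np.log(p_true)))
    if not return_grad:
        return loss
    onehot = np.zeros_like(flat_p)
    onehot[flat_t, idx] = 1.0
    grad = (wt[None, :] * (flat_p - onehot) / n).reshape(logits.shape)
    return loss, grad


def _soft_dice_per_class(p_flat: np.ndarray, onehot: np.ndarray):
    inter = (p_flat * onehot).sum(axis=1)
    sums = p_flat.sum(axis=1) + onehot.sum(axis=1)
    num = 2.0 * inter + DICE_SMOOTH
    den = sums + DICE_SMOOTH
    return num, den


def weighted_dice_loss(weights, probabilities: np.ndarray, target: np.ndarray,
                       return_grad: bool = False):
    """Weighted soft-Dice loss ``sum_k w_k (1 - Dice_k) / sum_k w_k``.

    ``probabilities`` has shape ``(K, *spatial)`` and must sum to 1 per
    voxel.  Normalising by ``sum w`` decouples the scale of the weight
    vector from the scale of the loss, so weight schemes with different
    magnitudes remain comparable.
    """
    w = _as_weights(weights)
    k = probabilities.shape[0]
    if w.size != k:
        raise ValueError("weight vector length must equal number of classes")
    t = _check_target(target, k)
    p_flat = np.asarray(probabilities, dtype=float).reshape(k, -1)
    if not np.allclose(p_flat.sum(axis=0), 1.0, atol=1e-5):
        raise ValueError("probabilities must sum to 1 per voxel")
    flat_t = t.reshape(-1)
    onehot = np.zeros_like(p_flat)
    onehot[flat_t, np.arange(flat_t.size)] = 1.0
    num, den = _soft_dice_per_class(p_flat, onehot)
    dice = num / den
    w_sum = w.sum()
    if w_sum == 0:
        loss = 0.0
        if return_grad:
            return loss, np.zeros(probabilities.shape)
        return loss
    loss = float(np.sum(w * (1.0 - dice)) / w_sum)
    if not return_grad:
        return loss
    # d Dice_k / d p_{k,j} = (2 t_{k,j} den_k - num_k) / den_k^2
    ddice = (2.0 * onehot * den[:, None] - num[:, None]) / (den[:, None] ** 2)
    grad = (-(w / w_sum)[:, None] * ddice).reshape(probabilities.shape)
    return loss, grad


def _chain_softmax(grad_p: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Backprop a gradient w.r.t. softmax probabilities to the logits."""
    dot = (grad_p * p).sum(axis=0, keepdims=True)
    return p * (grad_p - dot)


def seg_loss(weights, logits: np.ndarray, target: np.ndarray,
             ce_coef: float = 0.5, return_grad: bool = False):
    """``L_s = L_Dice + ce_coef * L_CE`` on one sample, with optional
    gradient w.r.t. the logits."""
    p = softmax(logits, axis=0)
    if return_grad:
        dice_val, dice_grad_p = weighted_dice_loss(weights, p, target, return_grad=True)
        ce_val, ce_grad = weighted_ce(weights, logits, target, return_grad=True)
        grad = _chain_softmax(dice_grad_p, p) + ce_coef * ce_grad
        return dice_val + ce_coef * ce_val, grad
    dice_val = weighted_dice_loss(weights, p, target)
    ce_val = weighted_ce(weights, logits, target)
    return dice_val + ce_coef * ce_val


def _batched(logits: np.ndarray) -> np.ndarray:
    if logits.ndim < 3:
        raise ValueError("expected batched logits (N, K, *spatial)")
    return logits


def supervised_loss(p_A: np.ndarray, p_B: np.ndarray, y: np.ndarray,
                    w_cdif, w_dis, return_grads: bool = False):
    """Supervised CPS loss on the labeled batch.

    ``(1/N)(1/K) sum_i [L_s(W_cdif, p_A_i, y_i) + L_s(W_dis, p_B_i, y_i)]``
    """
    p_A, p_B = _batched(p_A), _batched(p_B)
    n, k = p_A.shape[0], p_A.shape[1]
    scale = 1.0 / (n * k)
    total = 0.0
    g_a = np.zeros_like(p_A) if return_grads else None
    g_b = np.zeros_like(p_B) if return_grads else None
    for i in range(n):
        if return_grads:
            la, ga = seg_loss(w_cdif, p_A[i], y[i], return_grad=True)
            lb, gb = seg_loss(w_dis, p_B[i], y[i], return_grad=True)
            g_a[i] = scale * ga
            g_b[i] = scale * gb
        else:
            la = seg_loss(w_cdif, p_A[i], y[i])
            lb = seg_loss(w_dis, p_B[i], y[i])
        total += la + lb
    total *= scale
    if return_grads:
        return float(total), g_a, g_b
    return float(total)


def cps_loss(p_A: np.ndarray, p_B: np.ndarray,
             y_hat_A: np.ndarray, y_hat_B: np.ndarray,
             w_cdif, w_dis, return_grads: bool = False):
    """Cross-pseudo-supervision loss over the full (labeled+unlabeled) batch.

    Model A is supervised by B's argmax pseudo-labels and vice versa;
    the pseudo-labels are treated as constants.
    """
    p_A, p_B = _batched(p_A), _batched(p_B)
    n, k = p_A.shape[0], p_A.shape[1]
    scale = 1.0 / (n * k)
    total = 0.0
    g_a = np.zeros_like(p_A) if return_grads else None
    g_b = np.zeros_like(p_B) if return_grads else None
    for q in range(n):
        if return_grads:
            la, ga = weighted_ce(w_cdif, p_A[q], y_hat_B[q], return_grad=True)
            lb, gb = weighted_ce(w_dis, p_B[q], y_hat_A[q], return_grad=True)
            g_a[q] = scale * ga
            g_b[q] = scale * gb
        else:
            la = weighted_ce(w_cdif, p_A[q], y_hat_B[q])
            lb = weighted_ce(w_dis, p_B[q], y_hat_A[q])
        total += la + lb
    total *= scale
    if return_grads:
        return float(total), g_a, g_b
    return float(total)


def mixed_loss(p_A_m: np.ndarray, p_B_m: np.ndarray,
               y_m_A: np.ndarray, y_m_B: np.ndarray,
               w_cdif, w_dis, return_grads: bool = False,
               normalize: bool = False):
    """Loss on the double-mix pairs:
    ``L_s(W_cdif, p_A_m, y_m_A) + L_s(W_dis, p_B_m, y_m_B)``,
    averaged over the batch.

    With ``normalize=True`` an additional 1/K factor brings the term onto
    the same scale as the supervised and cross-supervision losses, which
    otherwise it dominates roughly K-fold (the trainer normalises by
    default; the bare form is the written one)."""
    p_A_m, p_B_m = _batched(p_A_m), _batched(p_B_m)
    n = p_A_m.shape[0]
    scale = 1.0 / n
    if normalize:
        scale /= p_A_m.shape[1]
    total = 0.0
    g_a = np.zeros_like(p_A_m) if return_grads else None
    g_b = np.zeros_like(p_B_m) if return_grads else None
    for i in range(n):
        if return_grads:
            la, ga = seg_loss(w_cdif, p_A_m[i], y_m_A[i], return_grad=True)
            lb, gb = seg_loss(w_dis, p_B_m[i], y_m_B[i], return_grad=True)
            g_a[i] = scale * ga
            g_b[i] = scale * gb
        else:
            la = seg_loss(w_cdif, p_A_m[i], y_m_A[i])
            lb = seg_loss(w_dis, p_B_m[i], y_m_B[i])
        total += la + lb
    total *= scale
    if return_grads:
        return float(total), g_a, g_b
    return float(total)


def gaussian_rampup(epoch: int, ramp_epochs: int) -> float:
    """``exp(-5 (1 - min(e/E, 1))^2)``; ~6.7e-3 at epoch 0, 1 from epoch E on."""
    if epoch < 0:
        raise ValueError("epoch must be nonnegative")
    if ramp_epochs <= 0:
        return 1.0
    frac = min(epoch / ramp_epochs, 1.0)
    return float(np.exp(-5.0 * (1.0 - frac) ** 2))


def total_loss(sup: float, mixed: float, cps: float, epoch: int,
               ramp_epochs: int, theta: float) -> LossBreakdown:
    """Combine the three terms with the ramped unsupervised coefficient."""
    if theta < 0:
        raise ValueError("theta must be >= 0")
    ramp = theta * gaussian_rampup(epoch, ramp_epochs)
    return LossBreakdown(
        supervised=float(sup), mixed=float(mixed), unsupervised=float(cps),
        ramp_factor=ramp, total=float(sup + mixed + ramp * cps))
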