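"""Category-wise weight estimators for imbalanced semi-supervised segmentation.

Two weight families are maintained per training iteration:

* **DisW** (distribution weight): derived from per-category voxel counts of
  the batch pseudo-labels.  The voxel-count ratio ``r_k = max_eta(psi_eta) /
  psi_k`` is log-normalised so the rarest category gets weight 1 and the most
  frequent gets 0, then smoothed across iterations with an exponential moving
  average.

* **CDifW** (confidence-difficulty weight): the product of a difficulty
  weight — ``(1 - Dice_k)`` scaled by a population-stability-index style
  statistic of the recent Dice trajectory — and a normalised information
  score ``s_k = (1 - c_k) / max(1 - c)`` built from EMA-smoothed softmax
  confidence on labeled voxels, raised to an exponent ``gamma``.

Both weight vectors include the background as an ordinary category; whether
background may be *sampled* during mixing is decided downstream.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field
from typing import Deque, Optional, Sequence

import numpy as np

__all__ = [
    "InsufficientHistoryError",
    "DisWState",
    "DifficultyTracker",
    "ConfidenceState",
    "CDifWState",
    "compute_disw_instant",
    "update_disw",
    "update_difficulty",
    "compute_difficulty",
    "compute_difficulty_weight",
    "update_confidence",
    "information_score",
    "compute_cdifw",
    "compute_cdisw",
]


class InsufficientHistoryError(RuntimeError):
    """Raised when a difficulty statistic is requested before two Dice
    observations are available for the category."""


# ---------------------------------------------------------------------------
# Distribution weight (DisW)
# ---------------------------------------------------------------------------

def compute_disw_instant(voxel_counts: Sequence[float]) -> np.ndarray:
    """Instantaneous distribution weight from per-category voxel counts.

    ``w_k = log(r_k) / max_rho log(r_rho)`` with ``r_k = max(psi)/psi_k``.
    Zero counts are floored to 1 voxel so every ratio is finite; if all
    counts are equal (every log-ratio zero) the uniform all-ones vector is
    returned.

    Parameters
    ----------
    voxel_counts
        Nonnegative integers, one per category (background included).

    Returns
    -------
    Weights in ``[0, 1]``; the rarest category maps to 1, the most
    frequent to 0.
    """
    psi = np.asarray(voxel_counts, dtype=float)
    if psi.ndim != 1 or psi.size == 0:
        raise ValueError("voxel_counts must be a non-empty 1-D vector")
    if np.any(psi < 0):
        raise ValueError("voxel counts must be nonnegative")
    if not np.any(psi > 0):
        raise ValueError("all-zero voxel counts: no categories present")
    psi = np.where(psi == 0, 1.0, psi)
    r = psi.max() / psi
    log_r = np.log(r)
    denom = log_r.max()
    if denom == 0.0:
        return np.ones_like(psi)
    return log_r / denom


@dataclass
class DisWState:
    """EMA-tracked distribution weights ``W^dis_t``."""

    weights: np.ndarray
    beta: float = 0.99
    iteration: int = 0

    @classmethod
    def initial(cls, num_classes: int, beta: float = 0.99) -> "DisWState":
        # neutral uniform start before any evidence
        return cls(weights=np.ones(num_classes), beta=beta, iteration=0)


def update_disw(state: DisWState, pseudo_labels: np.ndarray,
                num_classes: Optional[int] = None) -> DisWState:
    """EMA update ``W_t = beta * W_{t-1} + (1-beta) * W_hat_t``.

    ``pseudo_labels`` is an integer label array over the concatenated
    labeled+unlabeled batch (any shape); counts are taken over all voxels.
    """
    k = num_classes if num_classes is not None else state.weights.size
    labels = np.asarray(pseudo_labels)
    counts = np.bincount(labels.ravel(), minlength=k)[:k]
    instant = compute_disw_instant(counts)
    new_w = state.beta * state.weights + (1.0 - state.beta) * instant
    return DisWState(weights=new_w, beta=state.beta, iteration=state.iteration + 1)


# ---------------------------------------------------------------------------
# Difficulty from the Dice trajectory
# ---------------------------------------------------------------------------

@dataclass
class DifficultyTracker:
    """Sliding window of per-category Dice scores.

    Keeps the last ``tau + 1`` per-iteration Dice vectors so that the
    difficulty statistic sums log-ratios of consecutive scores over the
    window starting at ``max(t - tau, 0)``.
    """

    num_classes: int
    tau: int = 50
    alpha: float = 0.5
    epsilon: float = 1e-8
    dice_floor: float = 1e-4
    history: Deque[np.ndarray] = field(default_factory=deque)
    iteration: int = 0

    @property
    def window_start(self) -> int:
        return max(self.iteration - self.tau, 0)


def update_difficulty(tracker: DifficultyTracker, dice_now: Sequence[float]) -> DifficultyTracker:
    """Append the current per-category Dice vector; evict entries older
    than the window start."""
    zeta = np.asarray(dice_now, dtype=float)
    if zeta.shape != (tracker.num_classes,):
        raise ValueError(f"expected {tracker.num_classes} Dice values, got shape {zeta.shape}")
    if np.any((zeta < 0) | (zeta > 1)):
        raise ValueError("Dice scores must lie in [0, 1]")
    tracker.history.append(zeta.copy())
    tracker.iteration += 1
    while len(tracker.history) > tracker.tau + 1:
        tracker.history.popleft()
    return tracker


def compute_difficulty(tracker: DifficultyTracker, k: int) -> float:
    """Difficulty ``d_k = ((d^u + eps) / (d^l + eps)) ** alpha``.

    ``d^u`` sums ``ln(zeta_t / zeta_{t-1})`` over window steps where the
    Dice did not improve (un-learning), ``d^l`` over improving steps.
    Improving trajectories give ``d < 1`` (the category is being learned),
    flat trajectories give exactly 1, deteriorating ones ``d > 1``.

    Dice values are floored at ``dice_floor`` before the log-ratio so that
    zero scores early in training stay finite.  A negative base raised to a
    non-integer ``alpha`` is guarded with the absolute value (with a
    warning): this occurs when the un-learning sum is negative, i.e. the
    trajectory is dominated by deterioration, and the magnitude is the
    meaningful quantity.
    """
    hist = [h[k] for h in tracker.history]
    if len(hist) < 2:
        raise InsufficientHistoryError(
            f"category {k}: need >= 2 Dice observations, have {len(hist)}")
    zeta = np.maximum(np.asarray(hist, dtype=float), tracker.dice_floor)
    ratios = np.log(zeta[1:] / zeta[:-1])
    delta = np.diff(np.asarray(hist, dtype=float))
    d_u = ratios[delta <= 0].sum()
    d_l = ratios[delta > 0].sum()
    base = (d_u + tracker.epsilon) / (d_l + tracker.epsilon)
    if base < 0 and float(tracker.alpha) != int(tracker.alpha):
        warnings.warn(
            "difficulty base negative with non-integer alpha; using |base|",
            RuntimeWarning, stacklevel=2)
        base = abs(base)
    return float(base ** tracker.alpha)


def compute_difficulty_weight(tracker: DifficultyTracker) -> np.ndarray:
    """Per-category difficulty weight ``w^dif_k = (1 - zeta_{t,k}) * d_k``
    with ``zeta_{t,k}`` the most recent Dice."""
    if not tracker.history:
        raise InsufficientHistoryError("empty Dice history")
    latest = tracker.history[-1]
    d = np.array([compute_difficulty(tracker, k) for k in range(tracker.num_classes)])
    return (1.0 - latest) * d


# ---------------------------------------------------------------------------
# Confidence and information score
# ---------------------------------------------------------------------------

@dataclass
class ConfidenceState:
    """EMA-smoothed per-category softmax confidence ``c_{t,k}`` on labeled
    voxels, and the information-score exponent ``gamma``."""

    confidence: np.ndarray
    beta: float = 0.99
    gamma: float = 0.2
    iteration: int = 0

    @classmethod
    def initial(cls, num_classes: int, beta: float = 0.99, gamma: float = 0.2) -> "ConfidenceState":
        # chance-level start: uniform softmax has confidence 1/K
        return cls(confidence=np.full(num_classes, 1.0 / num_classes),
                   beta=beta, gamma=gamma, iteration=0)


def update_confidence(state: ConfidenceState, probabilities: np.ndarray,
                      labels: np.ndarray, atol: float = 1e-5) -> ConfidenceState:
    """Batch confidence ``c_hat_k = (1/B) sum_b (1/z_{b,k}) sum_j p_{b,k,j}``
    over voxels *j* whose ground truth is *k*, followed by the EMA update
    ``c_t = beta * c_{t-1} + (1 - beta) * c_hat_t``.

    ``probabilities`` has shape ``(B, K, *spatial)`` and must be softmax
    output (rows summing to 1); ``labels`` has shape ``(B, *spatial)``.
    Samples where a category is absent are excluded from that category's
    batch mean; a category absent from the whole batch keeps its previous
    confidence (no evidence, no update).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    if p.ndim < 3 or p.shape[0] != y.shape[0] or p.shape[2:] != y.shape[1:]:
        raise ValueError("probabilities must be (B, K, *spatial) matching labels (B, *spatial)")
    k_classes = p.shape[1]
    total = p.sum(axis=1)
    if not np.allclose(total, 1.0, atol=atol):
        raise ValueError("probabilities do not sum to 1 per voxel; pass softmax output")

    c_hat = np.full(k_classes, np.nan)
    for k in range(k_classes):
        per_sample = []
        for b in range(y.shape[0]):
            sel = y[b] == k
            z = int(sel.sum())
            if z > 0:
                per_sample.append(p[b, k][sel].sum() / z)
        if per_sample:
            c_hat[k] = float(np.mean(per_sample))

    new_c = state.confidence.copy()
    present = ~np.isnan(c_hat)
    new_c[present] = state.beta * state.confidence[present] + (1.0 - state.beta) * c_hat[present]
    return ConfidenceState(confidence=new_c, beta=state.beta, gamma=state.gamma,
                           iteration=state.iteration + 1)


def information_score(state: ConfidenceState) -> np.ndarray:
    """Normalised information score ``s_k = (1 - c_k) / max_i (1 - c_i)``.

    Values lie in [0, 1] with the least-confident category at exactly 1.
    If every category is fully confident the score degenerates to 0/0 and
    the uniform all-ones vector is returned.
    """
    residual = 1.0 - state.confidence
    m = residual.max()
    if m <= 0.0:
        return np.ones_like(residual)
    return residual / m


# ---------------------------------------------------------------------------
# Combined confidence-difficulty weight (CDifW) and the CDisW ablation
# ---------------------------------------------------------------------------

@dataclass
class CDifWState:
    """Confidence-difficulty weight state: ``w^cdif_k = s_k^gamma * w^dif_k``."""

    difficulty_tracker: DifficultyTracker
    confidence_state: ConfidenceState
    weights: np.ndarray

    @classmethod
    def initial(cls, num_classes: int, tau: int = 50, alpha: float = 0.5,
                beta: float = 0.99, gamma: float = 0.2, epsilon: float = 1e-8,
                dice_floor: float = 1e-4) -> "CDifWState":
        return cls(
            difficulty_tracker=DifficultyTracker(
                num_classes=num_classes, tau=tau, alpha=alpha,
                epsilon=epsilon, dice_floor=dice_floor),
            confidence_state=ConfidenceState.initial(num_classes, beta=beta, gamma=gamma),
            weights=np.ones(num_classes),
        )


def compute_cdifw(state: CDifWState) -> np.ndarray:
    """``w^cdif_k = s_k^gamma * w^dif_k`` from the current difficulty and
    confidence states."""
    s = information_score(state.confidence_state)
    w_dif = compute_difficulty_weight(state.difficulty_tracker)
    return s ** state.confidence_state.gamma * w_dif


def compute_cdisw(disw: np.ndarray, confidence: ConfidenceState) -> np.ndarray:
    """Ablation weight applying the information score to DisW:
    ``w^cdis_k = s_k^gamma * w^dis_k`` (mirrors the CDifW composition)."""
    s = information_score(confidence)
    return s ** confidence.gamma * np.asarray(disw, dtype=float)
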