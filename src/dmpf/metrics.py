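"""Segmentation evaluation: per-category Dice and average surface distance."""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

__all__ = ["dice_per_category", "average_surface_distance", "evaluate_segmentation"]


def dice_per_category(prediction: np.ndarray, truth: np.ndarray,
                      num_classes: int) -> np.ndarray:
    """Dice ``2|P∩T| / (|P|+|T|)`` per category.

    Categories absent from both prediction and truth get NaN (no overlap
    to measure); absent from one side only gives 0.
    """
    out = np.full(num_classes, np.nan)
    for k in range(num_classes):
        p = prediction == k
        t = truth == k
        denom = p.sum() + t.sum()
        if denom == 0:
            continue
        out[k] = 2.0 * np.logical_and(p, t).sum() / denom
    return out


def _surface(mask: np.ndarray) -> np.ndarray:
    """Boundary voxels: mask minus its erosion."""
    eroded = ndimage.binary_erosion(mask, border_value=0)
    return mask & ~eroded


def average_surface_distance(prediction: np.ndarray, truth: np.ndarray,
                             spacing: Sequence[float] = (1.0, 1.0, 1.0)) -> float:
    """Symmetric average surface distance between two binary masks.

    If one mask is empty while the other is not, the volume diagonal is
    returned as a finite worst case; if both are empty the distance is 0.
    """
    prediction = prediction.astype(bool)
    truth = truth.astype(bool)
    if not prediction.any() and not truth.any():
        return 0.0
    diag = float(np.linalg.norm(np.asarray(prediction.shape) * np.asarray(spacing)))
    if not prediction.any() or not truth.any():
        return diag
    sp = _surface(prediction)
    st = _surface(truth)
    if not sp.any() or not st.any():  # solid volume filling the grid
        return 0.0 if np.array_equal(prediction, truth) else diag
    dt_t = ndimage.distance_transform_edt(~st, sampling=spacing)
    dt_p = ndimage.distance_transform_edt(~sp, sampling=spacing)
    d_pt = dt_t[sp]
    d_tp = dt_p[st]
    return float((d_pt.sum() + d_tp.sum()) / (d_pt.size + d_tp.size))


def evaluate_segmentation(prediction: np.ndarray, truth: np.ndarray,
                          num_classes: int,
                          spacing: Sequence[float] = (1.0, 1.0, 1.0),
                          include_background: bool = False
                          ) -> Tuple[np.ndarray, float, float]:
    """Per-category Dice, mean Dice and mean ASD over foreground categories.

    Categories absent from both volumes are excluded from the means.
    """
    dice = dice_per_category(prediction, truth, num_classes)
    start = 0 if include_background else 1
    asd = np.full(num_classes, np.nan)
    for k in range(start, num_classes):
        p = prediction == k
        t = truth == k
        if not p.any() and not t.any():
            continue
        asd[k] = average_surface_distance(p, t, spacing)
    fg_dice = dice[start:]
    fg_asd = asd[start:]
    mean_dice = float(np.nanmean(fg_dice)) if np.any(~np.isnan(fg_dice)) else np.nan
    mean_asd = float(np.nanmean(fg_asd)) if np.any(~np.isnan(fg_asd)) else np.nan
    return dice, mean_dice, mean_asd
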