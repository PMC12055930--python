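"""Weight-guided pseudo-label mixing (the DMP module) and baseline augmentations.

A DMP operation samples a set of categories from the probability
distribution induced by a category-weight vector, marks every voxel whose
pseudo-label falls in that set, and pastes the unlabeled volume (and its
pseudo-label) onto the labeled volume (and its ground truth) at the marked
voxels:

    x_m = x_u * M + x_l * (1 - M),    y_m = y_pseudo * M + y_true * (1 - M)

Rare or difficult categories carry large weights, so their regions are
preferentially transplanted into labeled training samples.  CutMix, CutOut
and ClassMix are provided as unweighted baselines for ablation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "CategorySet", "MixMask", "MixedPair",
    "sample_categories", "build_mask", "mix", "double_mix", "baseline_augment",
    "write_preview",
]


@dataclass(frozen=True)
class CategorySet:
    """Outcome of weighted category sampling."""

    selected: frozenset
    source_weights: np.ndarray
    rng_seed: Optional[int] = None


@dataclass(frozen=True)
class MixMask:
    """Binary paste mask: 1 where unlabeled content replaces labeled."""

    mask: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.mask)
        if not np.isin(m, (0, 1)).all():
            raise ValueError("mask must be binary")


@dataclass(frozen=True)
class MixedPair:
    """A mixed intensity volume with its mixed label map and provenance."""

    image: np.ndarray
    label: np.ndarray
    mask: MixMask
    category_set: CategorySet


def sample_categories(weights: Sequence[float], n_draws: int,
                      rng: np.random.Generator) -> CategorySet:
    """Draw ``n_draws`` categories with replacement, proportional to
    ``weights``; return the set of distinct categories drawn.

    Zero-weight categories are never selected.  Raises ``ValueError`` if
    all weights are zero.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or np.any(w < 0) or np.any(~np.isfinite(w)):
        raise ValueError("weights must be finite and nonnegative")
    total = w.sum()
    if total <= 0:
        raise ValueError("all-zero weight vector: nothing to sample")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    p = w / total
    draws = rng.choice(w.size, size=n_draws, replace=True, p=p)
    return CategorySet(selected=frozenset(int(c) for c in draws), source_weights=w)


def build_mask(pseudo_label: np.ndarray, categories: CategorySet) -> MixMask:
    """Indicator mask of voxels whose pseudo-label is in the selected set."""
    labels = np.asarray(pseudo_label)
    if categories.selected:
        m = np.isin(labels, sorted(categories.selected)).astype(labels.dtype)
    else:
        m = np.zeros_like(labels)
    return MixMask(mask=m)


def mix(x_unlabeled: np.ndarray, y_pseudo: np.ndarray,
        x_labeled: np.ndarray, y_true: np.ndarray, mask: MixMask) -> MixedPair:
    """Hard paste of unlabeled content onto the labeled volume where mask=1."""
    m = mask.mask
    shapes = {x_unlabeled.shape, y_pseudo.shape, x_labeled.shape, y_true.shape, m.shape}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch among mix inputs: {shapes}")
    x_m = np.where(m == 1, x_unlabeled, x_labeled)
    y_m = np.where(m == 1, y_pseudo, y_true)
    return MixedPair(image=x_m, label=y_m,
                     mask=mask, category_set=CategorySet(frozenset(), np.asarray([])))


def _effective_weights(weights: np.ndarray, exclude_background: bool) -> np.ndarray:
    w = np.asarray(weights, dtype=float).copy()
    if exclude_background and w.size > 1 and w[1:].sum() > 0:
        w[0] = 0.0
    return w


def _dmp_single(x_u, x_l, y_true, pseudo, weights, rng, *,
                n_draws=None, exclude_background=True, max_resample=5) -> MixedPair:
    """One DMP operation: sample categories, mask, paste.

    If every sampled category is absent from this pseudo-label (an all-zero
    mask), resampling is attempted ``max_resample`` times, then the
    highest-weight *eligible* category present in the pseudo-label is
    forced.  When no eligible category is present at all — e.g. the
    teacher predicts pure background — the mask is left empty and the
    mixed pair degenerates to the labeled pair, which is benign; forcing
    background there would paste an entire mislabeled volume.
    """
    w = _effective_weights(weights, exclude_background)
    if w.sum() <= 0:
        # no category carries weight (e.g. everything currently solved):
        # degrade to uniform sampling rather than failing
        w = _effective_weights(np.ones_like(w), exclude_background)
    k = w.size
    draws = n_draws if n_draws is not None else k
    present = np.unique(pseudo)
    cat_set = None
    for _ in range(max_resample + 1):
        cand = sample_categories(w, draws, rng)
        if np.isin(sorted(cand.selected), present).any():
            cat_set = cand
            break
    if cat_set is None:
        eligible = [(w[c], c) for c in present if w[c] > 0]
        if eligible:
            cat_set = CategorySet(selected=frozenset({int(max(eligible)[1])}),
                                  source_weights=w)
        else:
            cat_set = CategorySet(selected=frozenset(), source_weights=w)
    mask = build_mask(pseudo, cat_set)
    pair = mix(x_u, pseudo, x_l, y_true, mask)
    return MixedPair(image=pair.image, label=pair.label, mask=mask, category_set=cat_set)


def double_mix(x_unlabeled: np.ndarray, x_labeled: np.ndarray, y_true: np.ndarray,
               pseudo_A: np.ndarray, pseudo_B: np.ndarray,
               w_cdif: np.ndarray, w_dis: np.ndarray,
               rng: np.random.Generator, *, n_draws: Optional[int] = None,
               exclude_background: bool = True,
               max_resample: int = 5) -> Tuple[MixedPair, MixedPair]:
    """Two DMP operations with distinct weight streams.

    Pair A mixes using categories sampled from the confidence-difficulty
    weights and teacher A's pseudo-label; pair B uses the distribution
    weights and teacher B's pseudo-label.
    """
    kwargs = dict(n_draws=n_draws, exclude_background=exclude_background,
                  max_resample=max_resample)
    pair_a = _dmp_single(x_unlabeled, x_labeled, y_true, pseudo_A, w_cdif, rng, **kwargs)
    pair_b = _dmp_single(x_unlabeled, x_labeled, y_true, pseudo_B, w_dis, rng, **kwargs)
    return pair_a, pair_b


def write_preview(pair: MixedPair, out_dir, prefix: str = "preview") -> None:
    """Write a mixed pair as NIfTI triplet (image, label, mask) for QA."""
    from pathlib import Path

    from .io import VolumeRecord, write_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(VolumeRecord(array=np.asarray(pair.image, dtype=float)),
                 out / f"{prefix}_image.nii.gz")
    write_volume(VolumeRecord(array=np.asarray(pair.label, dtype=np.int16)),
                 out / f"{prefix}_label.nii.gz")
    write_volume(VolumeRecord(array=np.asarray(pair.mask.mask, dtype=np.int16)),
                 out / f"{prefix}_mask.nii.gz")


def _random_box(shape, rng, frac_low=0.2, frac_high=0.5):
    """Random axis-aligned box occupying a random fraction of each axis."""
    slices = []
    for n in shape:
        size = int(round(n * rng.uniform(frac_low, frac_high)))
        size = max(size, 1)
        start = int(rng.integers(0, n - size + 1))
        slices.append(slice(start, start + size))
    return tuple(slices)


def baseline_augment(kind: str, x_u: np.ndarray, x_l: np.ndarray,
                     y_pseudo: np.ndarray, y_true: np.ndarray,
                     rng: np.random.Generator) -> MixedPair:
    """Unweighted mixing baselines used in augmentation ablations.

    - ``cutmix``: paste a random box from the unlabeled pair into the labeled pair.
    - ``cutout``: zero a random box of the labeled image (labels unchanged).
    - ``classmix``: select a uniform random half (ceil) of the categories
      present in the pseudo-label and paste them, unweighted.
    """
    if x_u.shape != x_l.shape or y_pseudo.shape != y_true.shape:
        raise ValueError("shape mismatch among augmentation inputs")
    if kind == "cutmix":
        m = np.zeros(x_l.shape, dtype=y_true.dtype)
        m[_random_box(x_l.shape, rng)] = 1
        return mix(x_u, y_pseudo, x_l, y_true, MixMask(mask=m))
    if kind == "cutout":
        m = np.zeros(x_l.shape, dtype=y_true.dtype)
        m[_random_box(x_l.shape, rng)] = 1
        image = np.where(m == 1, 0.0, x_l)
        return MixedPair(image=image, label=y_true.copy(), mask=MixMask(mask=m),
                         category_set=CategorySet(frozenset(), np.asarray([])))
    if kind == "classmix":
        present = np.unique(y_pseudo)
        n_sel = int(np.ceil(present.size / 2))
        chosen = rng.choice(present, size=n_sel, replace=False)
        cat_set = CategorySet(selected=frozenset(int(c) for c in chosen),
                              source_weights=np.ones(int(max(present)) + 1))
        mask = build_mask(y_pseudo, cat_set)
        pair = mix(x_u, y_pseudo, x_l, y_true, mask)
        return MixedPair(image=pair.image, label=pair.label, mask=mask, category_set=cat_set)
    raise ValueError(f"unknown augmentation kind: {kind!r}")
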