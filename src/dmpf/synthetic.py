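"""Imbalanced 3-D phantom generator.

Produces grayscale volumes with integer label maps whose per-category
voxel counts follow a requested, strongly imbalanced profile (decades-
spaced fractions give >= 100x spread between the largest and smallest
foreground category, mirroring the situation in abdominal CT where a large
organ can outweigh a small gland by two to three orders of magnitude).
Shapes are analytic — ellipsoids, tubes, and multi-sphere blobs — so the
ground truth is exact.  A per-category boundary-blur knob makes a
category's intensity transition gradual, which degrades any intensity-
based segmenter on that category and thereby emulates differing boundary
difficulty.

Category 0 is background throughout; foreground categories are 1..K.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .io import VolumeRecord, write_volume

__all__ = ["PhantomSpec", "generate_phantom", "generate_cohort", "generate_dataset"]

SHAPE_FAMILIES = ("ellipsoid", "tube", "blob")


@dataclass
class PhantomSpec:
    """Recipe for one phantom cohort."""

    grid_size: Tuple[int, int, int] = (64, 64, 64)
    target_voxel_fractions: Tuple[float, ...] = (0.2, 0.02, 0.005, 0.001)
    shape_families: Optional[Tuple[str, ...]] = None     # default cycles families
    intensity_means: Optional[Tuple[float, ...]] = None  # background first
    noise_sd: float = 0.05
    boundary_blur: Optional[Tuple[float, ...]] = None    # per foreground category, voxels
    seed: int = 0

    @property
    def n_categories(self) -> int:
        """Number of foreground categories."""
        return len(self.target_voxel_fractions)

    @property
    def num_classes(self) -> int:
        """Total label count including background."""
        return self.n_categories + 1

    def __post_init__(self):
        k = self.n_categories
        if k == 0:
            raise ValueError("invalid spec: need at least one foreground category")
        if sum(self.target_voxel_fractions) > 1.0:
            raise ValueError("invalid spec: fractions must sum to <= 1")
        if any(f <= 0 for f in self.target_voxel_fractions):
            raise ValueError("invalid spec: fractions must be positive")
        n_vox = int(np.prod(self.grid_size))
        if min(self.target_voxel_fractions) * n_vox < 8:
            raise ValueError("invalid spec: smallest structure below 8 voxels; "
                             "enlarge the grid or the fraction")
        if self.shape_families is None:
            fams = tuple(SHAPE_FAMILIES[i % len(SHAPE_FAMILIES)] for i in range(k))
            object.__setattr__(self, "shape_families", fams)
        if any(f not in SHAPE_FAMILIES for f in self.shape_families):
            raise ValueError(f"invalid spec: shape families must be in {SHAPE_FAMILIES}")
        if self.intensity_means is None:
            # background dim, foreground means spread across [0.35, 0.95]
            fg = np.linspace(0.35, 0.95, k)
            object.__setattr__(self, "intensity_means", (0.1, *map(float, fg)))
        if len(self.intensity_means) != k + 1:
            raise ValueError("invalid spec: need one intensity mean per category "
                             "including background")
        if self.boundary_blur is None:
            object.__setattr__(self, "boundary_blur", (0.0,) * k)
        if len(self.boundary_blur) != k:
            raise ValueError("invalid spec: one boundary blur per foreground category")


def _coords(grid):
    return np.meshgrid(*[np.arange(n, dtype=float) for n in grid], indexing="ij")


def _ellipsoid_mask(grid, center, semi_axes):
    xx = _coords(grid)
    q = sum(((x - c) / a) ** 2 for x, c, a in zip(xx, center, semi_axes))
    return q <= 1.0


def _place_ellipsoid(grid, volume, rng):
    r0 = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    ratios = rng.uniform(0.7, 1.4, size=3)
    ratios /= ratios.prod() ** (1.0 / 3.0)
    axes = np.minimum(r0 * ratios, np.asarray(grid) / 2.0 - 1.0)
    center = [rng.uniform(a + 1, n - a - 1) if n - 2 * a - 2 > 0 else n / 2.0
              for a, n in zip(axes, grid)]
    return _ellipsoid_mask(grid, center, axes)


def _place_tube(grid, volume, rng):
    axis = int(rng.integers(0, 3))
    length = 0.5 * grid[axis]
    radius = np.sqrt(volume / (np.pi * length))
    radius = min(radius, min(g for i, g in enumerate(grid) if i != axis) / 2.0 - 1.0)
    xx = _coords(grid)
    others = [i for i in range(3) if i != axis]
    center = [rng.uniform(radius + 1, grid[i] - radius - 1) for i in others]
    lo = rng.uniform(1, grid[axis] - length - 1)
    radial = sum((xx[i] - c) ** 2 for i, c in zip(others, center))
    along = (xx[axis] >= lo) & (xx[axis] <= lo + length)
    return (radial <= radius ** 2) & along


def _place_blob(grid, volume, rng):
    # union of three overlapping spheres around a common centre
    r = (3.0 * (volume / 2.2) / (4.0 * np.pi)) ** (1.0 / 3.0)
    r = min(r, min(grid) / 4.0 - 1.0)
    base = [rng.uniform(2 * r + 1, n - 2 * r - 1) if n - 4 * r - 2 > 0 else n / 2.0
            for n in grid]
    mask = np.zeros(grid, dtype=bool)
    for _ in range(3):
        offset = rng.uniform(-0.8 * r, 0.8 * r, size=3)
        center = np.clip(np.asarray(base) + offset, r + 1, np.asarray(grid) - r - 1)
        mask |= _ellipsoid_mask(grid, center, (r, r, r))
    return mask


_PLACERS = {"ellipsoid": _place_ellipsoid, "tube": _place_tube, "blob": _place_blob}


def generate_phantom(spec: PhantomSpec) -> Tuple[np.ndarray, np.ndarray]:
    """One phantom: float intensity volume in [0, 1] plus integer labels.

    Deterministic under ``spec.seed``.  Categories are drawn largest first
    so a small structure landing on a large one overwrites it; realized
    per-category fractions stay within a factor of two of the request.
    """
    rng = np.random.default_rng(spec.seed)
    grid = tuple(spec.grid_size)
    n_vox = int(np.prod(grid))
    labels = np.zeros(grid, dtype=np.int16)

    order = np.argsort(spec.target_voxel_fractions)[::-1]
    for idx in order:
        frac = spec.target_voxel_fractions[idx]
        family = spec.shape_families[idx]
        target = frac * n_vox
        mask = _PLACERS[family](grid, target, rng)
        labels[mask] = idx + 1

    # piecewise-constant intensity, then per-category boundary smoothing:
    # around a blurred category the intensity transitions gradually, so
    # intensity-driven segmentation of that category becomes ambiguous
    means = np.asarray(spec.intensity_means)
    intensity = means[labels]
    for cat in range(1, spec.num_classes):
        sigma = spec.boundary_blur[cat - 1]
        if sigma <= 0:
            continue
        blurred = ndimage.gaussian_filter(intensity, sigma)
        zone = ndimage.gaussian_filter((labels == cat).astype(float), sigma) > 0.01
        intensity = np.where(zone, blurred, intensity)

    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=grid)
    return np.clip(intensity, 0.0, 1.0), labels


def generate_cohort(spec: PhantomSpec, n_volumes: int
                    ) -> List[Tuple[np.ndarray, np.ndarray]]:
    """``n_volumes`` phantoms with per-volume seeds derived from the spec seed."""
    out = []
    for i in range(n_volumes):
        sub = PhantomSpec(
            grid_size=spec.grid_size,
            target_voxel_fractions=spec.target_voxel_fractions,
            shape_families=spec.shape_families,
            intensity_means=spec.intensity_means,
            noise_sd=spec.noise_sd,
            boundary_blur=spec.boundary_blur,
            seed=(spec.seed * 1000003 + i) % (2 ** 31 - 1),
        )
        out.append(generate_phantom(sub))
    return out


def generate_dataset(spec: PhantomSpec, n_volumes: int, labeled_fraction: float,
                     out_dir, n_val: int = 2, n_test: int = 2) -> dict:
    """Write a phantom cohort as NIfTI plus a JSON manifest.

    ``n_volumes`` training phantoms are split into labeled and unlabeled
    pools (labeled count = floor(n * fraction), minimum 1); ``n_val`` and
    ``n_test`` extra phantoms carry ground truth for evaluation.  Unlabeled
    entries have ``label: null`` and no label file on disk.
    """
    if not 0.0 < labeled_fraction <= 1.0:
        raise ValueError("labeled_fraction must be in (0, 1]")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_labeled = max(1, int(np.floor(n_volumes * labeled_fraction)))
    cohort = generate_cohort(spec, n_volumes + n_val + n_test)

    entries = []
    for i, (vol, lab) in enumerate(cohort):
        if i < n_labeled:
            split = "labeled"
        elif i < n_volumes:
            split = "unlabeled"
        elif i < n_volumes + n_val:
            split = "val"
        else:
            split = "test"
        vname = f"vol_{i:03d}.nii.gz"
        write_volume(VolumeRecord(array=vol), out_dir / vname)
        lname = None
        if split != "unlabeled":
            lname = f"lab_{i:03d}.nii.gz"
            write_volume(VolumeRecord(array=lab), out_dir / lname)
        entries.append({"volume": vname, "label": lname, "split": split})

    manifest = {"num_classes": spec.num_classes, "entries": entries}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
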