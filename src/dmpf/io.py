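"""NIfTI reading/writing and patch geometry utilities.

Volumes are held as :class:`VolumeRecord` objects carrying the raw array,
voxel spacing in millimetres, origin, and an orientation code.  Patch
coordinates are 0-based half-open boxes ordered (width, height, depth);
undersized volumes are reflect-padded so a patch always fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence, Tuple

import nibabel as nib
import numpy as np

__all__ = ["VolumeRecord", "read_volume", "write_volume",
           "grid_patches", "random_patch", "stitch_patches", "pad_to_min_shape"]


@dataclass
class VolumeRecord:
    """A 3-D volume with its geometry."""

    array: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: str = "RAS"
    path: Optional[str] = None
    affine: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.array.ndim != 3:
            raise ValueError("VolumeRecord holds 3-D arrays")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.array.shape


def _affine_from(record: VolumeRecord) -> np.ndarray:
    if record.affine is not None:
        return record.affine
    aff = np.diag(list(record.spacing) + [1.0])
    aff[:3, 3] = record.origin
    return aff


def read_volume(path, as_label: bool = False) -> VolumeRecord:
    """Load a NIfTI volume (.nii / .nii.gz).

    With ``as_label=True`` the voxel data must be integer-valued; a
    ``ValueError`` is raised otherwise (a label map with fractional voxels
    is a format error, typically the result of interpolation).
    """
    path = str(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # malformed header or not a NIfTI
        raise ValueError(f"cannot read NIfTI volume {path!r}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path!r}: expected a 3-D volume, got shape {data.shape}")
    if as_label:
        if not np.all(data == np.round(data)):
            raise ValueError(f"{path!r}: label volume has non-integer voxels")
        data = data.astype(np.int16)
    else:
        data = data.astype(np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    affine = np.asarray(img.affine, dtype=float)
    orientation = "".join(nib.aff2axcodes(affine))
    return VolumeRecord(array=data, spacing=spacing,
                        origin=tuple(affine[:3, 3]), orientation=orientation,
                        path=path, affine=affine)


def write_volume(record: VolumeRecord, path) -> None:
    """Write a record as NIfTI, preserving spacing and orientation."""
    path = str(path)
    data = record.array
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.int16)
    img = nib.Nifti1Image(data, _affine_from(record))
    img.header.set_zooms(record.spacing)
    nib.save(img, path)


def pad_to_min_shape(array: np.ndarray, min_shape: Sequence[int]) -> np.ndarray:
    """Reflect-pad so each axis reaches at least ``min_shape``."""
    pads = []
    for n, m in zip(array.shape, min_shape):
        extra = max(m - n, 0)
        pads.append((extra // 2, extra - extra // 2))
    if any(p != (0, 0) for p in pads):
        return np.pad(array, pads, mode="reflect")
    return array


def grid_patches(shape: Sequence[int], patch_size: Sequence[int],
                 stride: Sequence[int]) -> Iterator[Tuple[slice, slice, slice]]:
    """Sliding-window boxes covering ``shape``.

    Boxes are half-open slices; the final window along each axis is shifted
    back so the volume edge is always covered.
    """
    starts = []
    for n, p, s in zip(shape, patch_size, stride):
        if p > n:
            raise ValueError("patch larger than volume; pad first")
        pos = list(range(0, n - p + 1, s))
        if pos[-1] != n - p:
            pos.append(n - p)
        starts.append(pos)
    for i in starts[0]:
        for j in starts[1]:
            for k in starts[2]:
                yield (slice(i, i + patch_size[0]),
                       slice(j, j + patch_size[1]),
                       slice(k, k + patch_size[2]))


def random_patch(shape: Sequence[int], patch_size: Sequence[int],
                 rng: np.random.Generator) -> Tuple[slice, slice, slice]:
    """A uniformly random in-bounds patch box."""
    out = []
    for n, p in zip(shape, patch_size):
        if p > n:
            raise ValueError("patch larger than volume; pad first")
        start = int(rng.integers(0, n - p + 1))
        out.append(slice(start, start + p))
    return tuple(out)


def stitch_patches(shape: Sequence[int], boxes, patches) -> np.ndarray:
    """Reassemble (possibly overlapping) patches by averaging overlaps."""
    acc = np.zeros(shape, dtype=float)
    count = np.zeros(shape, dtype=float)
    for box, patch in zip(boxes, patches):
        acc[box] += patch
        count[box] += 1.0
    if np.any(count == 0):
        raise ValueError("patches do not cover the volume")
    return acc / count
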