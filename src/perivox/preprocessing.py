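"""Preprocessing chain for MR volumes.

The canonical order is: resample to 1 mm isotropic, tight-crop around the
head, build difference channels (t1c - t1w), clip intensities to the
[0, 99.5] percentile range, then zero-mean (unit-variance) normalization of
the nonzero voxels.  Also hosts the mask utilities shared by the rest of the
pipeline (connected components, volumetry).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .types import (
    AlignmentError,
    BinaryMask,
    SequenceSet,
    VolumeGrid,
    require_same_grid,
)

__all__ = [
    "CropRegion",
    "resample_isotropic",
    "tight_crop",
    "restore_crop",
    "subtract_channel",
    "difference_channel",
    "clip_and_normalize",
    "connected_components",
    "mask_volume_ml",
]


@dataclass(frozen=True)
class CropRegion:
    """Half-open 0-based bounding box plus the shape it was cut from."""

    start: Tuple[int, int, int]
    stop: Tuple[int, int, int]
    full_shape: Tuple[int, int, int]

    @property
    def slices(self) -> Tuple[slice, slice, slice]:
        return tuple(slice(a, b) for a, b in zip(self.start, self.stop))  # type: ignore


def resample_isotropic(
    vol: VolumeGrid, target_mm: float = 1.0, order: Optional[int] = None
) -> VolumeGrid:
    """Resample a volume to an isotropic grid.

    Output shape is ``round(shape * spacing / target_mm)``.  Interpolation is
    trilinear for intensity volumes and nearest-neighbour for binary masks
    (which keeps them binary); pass ``order`` to override.
    """
    if target_mm <= 0:
        raise ValueError(f"target spacing must be positive, got {target_mm}")
    is_mask = isinstance(vol, BinaryMask)
    if order is None:
        order = 0 if is_mask else 1
    spacing = np.asarray(vol.spacing, dtype=float)
    shape = np.asarray(vol.shape)
    out_shape = np.maximum(np.round(shape * spacing / target_mm).astype(int), 1)
    if tuple(out_shape) == tuple(shape) and np.allclose(spacing, target_mm):
        return vol.with_values(vol.values.copy())
    # Corner-aligned sampling: output voxel i sits at physical i * target_mm,
    # i.e. input index i * target_mm / spacing.
    coords = np.meshgrid(
        *[np.arange(n) * target_mm / s for n, s in zip(out_shape, spacing)],
        indexing="ij",
    )
    source = vol.values.astype(float) if is_mask else np.asarray(vol.values, dtype=float)
    out = ndimage.map_coordinates(source, np.stack(coords), order=order, mode="nearest")
    kwargs = dict(spacing=(target_mm,) * 3, origin=vol.origin)
    if is_mask:
        return BinaryMask(out > 0.5, **kwargs)
    return type(vol)(out, **kwargs)


def tight_crop(
    vol: VolumeGrid, background_level: float = 0.0
) -> Tuple[VolumeGrid, CropRegion]:
    """Crop to the minimal bounding box of voxels above ``background_level``."""
    content = vol.values > background_level
    if not content.any():
        raise ValueError("cannot tight-crop an all-background volume")
    start, stop = [], []
    for axis in range(3):
        other = tuple(a for a in range(3) if a != axis)
        profile = content.any(axis=other)
        idx = np.flatnonzero(profile)
        start.append(int(idx[0]))
        stop.append(int(idx[-1]) + 1)
    region = CropRegion(tuple(start), tuple(stop), vol.shape)
    new_origin = tuple(
        o + s * sp for o, s, sp in zip(vol.origin, start, vol.spacing)
    )
    cropped = type(vol)(vol.values[region.slices], vol.spacing, new_origin)
    return cropped, region


def restore_crop(vol: VolumeGrid, region: CropRegion, fill: float = 0.0) -> VolumeGrid:
    """Map a cropped volume/mask/probability map back onto the original grid."""
    if vol.shape != tuple(b - a for a, b in zip(region.start, region.stop)):
        raise AlignmentError("volume shape does not match the crop region")
    full = np.full(region.full_shape, fill, dtype=vol.values.dtype)
    full[region.slices] = vol.values
    orig_origin = tuple(
        o - s * sp for o, s, sp in zip(vol.origin, region.start, vol.spacing)
    )
    return type(vol)(full, vol.spacing, orig_origin)


def subtract_channel(a: VolumeGrid, b: VolumeGrid) -> VolumeGrid:
    """Voxel-wise difference a - b on a shared grid; negatives are preserved."""
    require_same_grid(a, b)
    return VolumeGrid(np.asarray(a.values, float) - np.asarray(b.values, float),
                      a.spacing, a.origin)


def difference_channel(seq: SequenceSet) -> SequenceSet:
    """Append the t1d = t1c - t1w channel to a sequence set."""
    if "t1c" not in seq or "t1w" not in seq:
        missing = {"t1c", "t1w"} - set(seq)
        raise ValueError(f"t1d needs t1c and t1w; missing {sorted(missing)}")
    return seq.replace(t1d=subtract_channel(seq["t1c"], seq["t1w"]))


def clip_and_normalize(
    vol: VolumeGrid,
    clip_pct: Sequence[float] = (0.0, 99.5),
    unit_variance: bool = True,
) -> VolumeGrid:
    """Percentile intensity clipping followed by nonzero-voxel normalization.

    Values are clipped to the [low, high] percentiles of the whole volume
    (zeros included).  Voxels that were exactly zero before normalization stay
    zero; the remaining voxels get their mean subtracted and, when
    ``unit_variance`` and the spread is nonzero, are divided by their standard
    deviation.
    """
    values = np.asarray(vol.values, dtype=float)
    nonzero = values != 0
    if not nonzero.any():
        return VolumeGrid(values.copy(), vol.spacing, vol.origin)
    lo, hi = np.percentile(values, list(clip_pct))
    clipped = np.clip(values, lo, hi)
    fg = clipped[nonzero]
    fg = fg - fg.mean()
    sd = fg.std()
    if unit_variance and sd > 0:
        fg = fg / sd
    out = np.zeros_like(clipped)
    out[nonzero] = fg
    return VolumeGrid(out, vol.spacing, vol.origin)


_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def connected_components(
    mask: BinaryMask, connectivity: int = 26, min_voxels: int = 0
) -> Tuple[np.ndarray, List[int]]:
    """Label the connected components of a mask.

    Returns the labelled array (0 = background, labels 1..K contiguous after
    size filtering) and the per-component voxel counts.  Components smaller
    than ``min_voxels`` are discarded.
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n = ndimage.label(mask.values, structure=structure)
    if n == 0:
        return labels, []
    counts = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero(counts >= max(min_voxels, 1)) + 1
    remap = np.zeros(n + 1, dtype=labels.dtype)
    remap[keep] = np.arange(1, len(keep) + 1)
    return remap[labels], [int(counts[k - 1]) for k in keep]


def mask_volume_ml(mask: BinaryMask) -> float:
    """Mask volume in millilitres: voxel count times voxel volume."""
    return mask.voxel_count * mask.voxel_volume_ml
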