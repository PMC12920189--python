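"""NIfTI I/O for grids, masks and probability maps.

Spacing and origin are taken from / written to the affine; the orientation is
kept axis-aligned (diagonal affine), with the third array axis axial.  Masks
are stored as unsigned 8-bit, probability maps as float32.
"""

from __future__ import annotations

import os
from typing import Union

import nibabel as nib
import numpy as np

from .types import BinaryMask, FormatError, ProbabilityMap, VolumeGrid

__all__ = ["read_volume", "read_mask", "read_probability_map", "write_volume"]


def _grid_from_image(img: nib.Nifti1Image, path: str):
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D image, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise FormatError(f"{path}: non-positive voxel spacing {zooms}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return data, tuple(float(z) for z in zooms), origin


def read_volume(path: Union[str, os.PathLike]) -> VolumeGrid:
    """Read a NIfTI scalar volume."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data, spacing, origin = _grid_from_image(img, str(path))
    return VolumeGrid(np.asarray(data, dtype=np.float64), spacing, origin)


def read_mask(path: Union[str, os.PathLike]) -> BinaryMask:
    """Read a NIfTI binary mask (any nonzero voxel counts as foreground)."""
    vol = read_volume(path)
    return BinaryMask(vol.values != 0, vol.spacing, vol.origin)


def read_probability_map(path: Union[str, os.PathLike]) -> ProbabilityMap:
    vol = read_volume(path)
    return ProbabilityMap(vol.values, vol.spacing, vol.origin)


def write_volume(vol: VolumeGrid, path: Union[str, os.PathLike]) -> None:
    """Write a volume, mask or probability map as NIfTI.

    The affine is diagonal with the voxel spacing on the diagonal and the
    origin in the translation column.
    """
    if isinstance(vol, BinaryMask):
        data = vol.values.astype(np.uint8)
    elif isinstance(vol, ProbabilityMap):
        data = vol.values.astype(np.float32)
    else:
        data = np.asarray(vol.values, dtype=np.float32)
    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
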