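"""NIfTI-1 input/output for SUV volumes and binary masks.

Masks are serialized as uint8 {0, 1}; SUV volumes as float32. Spacing is
carried in the NIfTI header (affine diagonal) and the origin in the affine
translation. Only 3D images are accepted.
"""

from __future__ import annotations

import numpy as np
import nibabel as nib

from .core import BinaryMask, ImageGrid, SUVVolume

__all__ = ["read_suv", "read_mask", "write_suv", "write_mask"]


def _grid_from_image(img) -> ImageGrid:
    if img.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI image, got {img.ndim} dimensions")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return ImageGrid(shape=tuple(int(n) for n in img.shape), spacing=spacing, origin=origin)


def _affine(grid: ImageGrid) -> np.ndarray:
    aff = np.diag(list(grid.spacing) + [1.0])
    aff[:3, 3] = grid.origin
    return aff


def read_suv(path) -> SUVVolume:
    """Read a 3D NIfTI volume as an SUV field (finite, non-negative)."""
    img = nib.load(str(path))
    grid = _grid_from_image(img)
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if np.isnan(data).any():
        raise ValueError(f"{path}: NaN voxels are not a valid SUV volume")
    return SUVVolume(grid, data)


def read_mask(path) -> BinaryMask:
    """Read a 3D NIfTI image as a binary mask (non-zero = true)."""
    img = nib.load(str(path))
    grid = _grid_from_image(img)
    data = np.asarray(img.get_fdata())
    if np.isnan(data).any():
        raise ValueError(f"{path}: NaN voxels are not a valid mask")
    return BinaryMask(grid, data != 0)


def write_suv(volume: SUVVolume, path) -> None:
    img = nib.Nifti1Image(volume.values.astype(np.float32), _affine(volume.grid))
    img.header.set_zooms(volume.grid.spacing)
    nib.save(img, str(path))


def write_mask(mask: BinaryMask, path) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), _affine(mask.grid))
    img.header.set_zooms(mask.grid.spacing)
    nib.save(img, str(path))
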