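"""Pre-processing for the semi-automatic segmentation methods.

The PET volume is trimmed to the prostate bounding box expanded by a
2-voxel margin, and an eligibility mask (the prostate dilated by the same
margin, chessboard metric) restricts where any segmentation operator may
place tumour voxels. Bladder voxels are removed from the eligibility mask
AND zeroed in the SUV data, so they can never contribute to SUVmax, local
means or histograms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import BinaryMask, ImageGrid, SUVVolume

__all__ = ["AnalysisRegion", "crop_to_prostate", "remove_bladder", "embed_mask"]


@dataclass
class AnalysisRegion:
    """A cropped SUV volume plus the mask of voxels eligible for segmentation.

    ``crop_offset`` is the index of the cropped origin in the parent grid;
    ``parent_grid`` is kept so masks produced on the crop can be re-embedded.
    """

    cropped_suv: SUVVolume
    analysis_mask: BinaryMask
    crop_offset: tuple
    parent_grid: ImageGrid

    def __post_init__(self):
        self.cropped_suv.grid.require_compatible(self.analysis_mask.grid)
        self.crop_offset = tuple(int(o) for o in self.crop_offset)

    @property
    def grid(self) -> ImageGrid:
        return self.cropped_suv.grid

    @property
    def slices(self) -> tuple:
        return tuple(
            slice(o, o + n) for o, n in zip(self.crop_offset, self.grid.shape)
        )

    @property
    def suv_max(self) -> float:
        """Maximum SUV over the eligible voxels of the pre-processed region."""
        if self.analysis_mask.empty:
            return 0.0
        return float(self.cropped_suv.values[self.analysis_mask.voxels].max())


def _crop_grid(parent: ImageGrid, offset, shape) -> ImageGrid:
    origin = tuple(
        parent.origin[i] + offset[i] * parent.spacing[i] for i in range(3)
    )
    return ImageGrid(shape=tuple(shape), spacing=parent.spacing, origin=origin)


def crop_to_prostate(
    suv: SUVVolume, prostate: BinaryMask, margin_voxels: int = 2
) -> AnalysisRegion:
    """Trim the PET volume to the prostate with a voxel margin.

    The crop box is the prostate bounding box expanded by ``margin_voxels``
    along every axis, clipped at the grid edges. The eligibility mask is the
    prostate dilated by the same margin (chessboard metric) restricted to the
    crop. Bladder removal is a separate step (:func:`remove_bladder`).
    """
    suv.grid.require_compatible(prostate.grid)
    if margin_voxels < 0:
        raise ValueError("margin_voxels must be >= 0")
    if prostate.empty:
        raise ValueError("prostate mask is empty; cannot define an analysis region")

    idx = np.argwhere(prostate.voxels)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0)  # inclusive
    lo = np.maximum(lo - margin_voxels, 0)
    hi = np.minimum(hi + margin_voxels, np.asarray(prostate.grid.shape) - 1)
    slices = tuple(slice(int(a), int(b) + 1) for a, b in zip(lo, hi))

    if margin_voxels > 0:
        eligible = ndimage.binary_dilation(
            prostate.voxels,
            structure=ndimage.generate_binary_structure(3, 3),
            iterations=margin_voxels,
        )
    else:
        eligible = prostate.voxels

    grid = _crop_grid(suv.grid, lo, [s.stop - s.start for s in slices])
    return AnalysisRegion(
        cropped_suv=SUVVolume(grid, suv.values[slices].copy()),
        analysis_mask=BinaryMask(grid, eligible[slices].copy()),
        crop_offset=tuple(int(a) for a in lo),
        parent_grid=suv.grid,
    )


def remove_bladder(region: AnalysisRegion, bladder: BinaryMask) -> AnalysisRegion:
    """Remove the bladder from an analysis region.

    Bladder voxels are dropped from the eligibility mask and their SUV set to
    0, so window-based operators never see bladder activity. An empty bladder
    (or one disjoint from the crop) is a no-op.
    """
    bladder.grid.require_compatible(region.parent_grid)
    bl = bladder.voxels[region.slices]
    if not bl.any():
        return region
    values = region.cropped_suv.values.copy()
    values[bl] = 0.0
    eligible = region.analysis_mask.voxels & ~bl
    return AnalysisRegion(
        cropped_suv=SUVVolume(region.grid, values),
        analysis_mask=BinaryMask(region.grid, eligible),
        crop_offset=region.crop_offset,
        parent_grid=region.parent_grid,
    )


def embed_mask(region: AnalysisRegion, mask: BinaryMask) -> BinaryMask:
    """Re-embed a mask produced on the cropped grid into the parent grid."""
    region.grid.require_compatible(mask.grid)
    full = np.zeros(region.parent_grid.shape, dtype=bool)
    full[region.slices] = mask.voxels
    return BinaryMask(region.parent_grid, full)
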