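"""Shared spatial data model: image grids, SUV volumes, binary masks and
the histopathology reference annotation, plus elementary mask algebra.

All images in the package live on a regular 3D grid with anisotropic voxel
spacing in millimetres. Voxel indices are 0-based and a voxel is identified
with its centre at ``origin + index * spacing``; every physical distance in
the package is a distance between voxel centres. No operation ever resamples
between grids: cross-mask operations require compatible grids (equal shape
and spacing, origins equal to within a small tolerance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "GridMismatchError",
    "ImageGrid",
    "SUVVolume",
    "BinaryMask",
    "ReferenceAnnotation",
    "volume_ml",
    "mask_algebra",
    "connected_components",
]


class GridMismatchError(ValueError):
    """Raised when an operation mixes images defined on incompatible grids."""


def _as_triple(value, name: str, cast=float) -> tuple:
    t = tuple(cast(v) for v in value)
    if len(t) != 3:
        raise ValueError(f"{name} must have exactly 3 entries, got {len(t)}")
    return t


@dataclass(frozen=True)
class ImageGrid:
    """A regular 3D voxel grid.

    Parameters
    ----------
    shape:
        Number of voxels along each axis, all >= 1.
    spacing:
        Voxel spacing along each axis in mm, all > 0.
    origin:
        Physical coordinate (mm) of the centre of voxel (0, 0, 0).
    """

    shape: tuple = (1, 1, 1)
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "shape", _as_triple(self.shape, "shape", int))
        object.__setattr__(self, "spacing", _as_triple(self.spacing, "spacing"))
        object.__setattr__(self, "origin", _as_triple(self.origin, "origin"))
        if any(n < 1 for n in self.shape):
            raise ValueError(f"all shape entries must be >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacing entries must be > 0, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def compatible(self, other: "ImageGrid", origin_tol_mm: float = 1e-6) -> bool:
        """Two grids are compatible iff shape and spacing are equal and the
        origins agree to within ``origin_tol_mm``."""
        return (
            self.shape == other.shape
            and self.spacing == other.spacing
            and all(abs(a - b) <= origin_tol_mm for a, b in zip(self.origin, other.origin))
        )

    def require_compatible(self, other: "ImageGrid") -> None:
        if not self.compatible(other):
            raise GridMismatchError(
                f"incompatible grids: {self.shape}@{self.spacing} (origin {self.origin}) "
                f"vs {other.shape}@{other.spacing} (origin {other.origin})"
            )

    def voxel_centers(self):
        """Physical coordinates (mm) of voxel centres, one 3D array per axis."""
        axes = [
            self.origin[i] + np.arange(self.shape[i]) * self.spacing[i]
            for i in range(3)
        ]
        return np.meshgrid(*axes, indexing="ij")


@dataclass
class SUVVolume:
    """A 3D standardized-uptake-value field. Values are finite and >= 0."""

    grid: ImageGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"value array shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("SUV values must all be finite")
        if np.any(self.values < 0):
            raise ValueError("SUV values must be >= 0")

    @property
    def suv_max(self) -> float:
        return float(self.values.max())


@dataclass
class BinaryMask:
    """A boolean field on an :class:`ImageGrid` (prostate, bladder, GTV, ...)."""

    grid: ImageGrid
    voxels: np.ndarray

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.voxels.shape} != grid shape {self.grid.shape}"
            )

    @property
    def n_true(self) -> int:
        return int(self.voxels.sum())

    @property
    def empty(self) -> bool:
        return not self.voxels.any()

    def copy(self) -> "BinaryMask":
        return BinaryMask(self.grid, self.voxels.copy())


@dataclass
class ReferenceAnnotation:
    """Histopathology reference on the PET grid.

    ``positive`` carries high-grade (Gleason pattern 4/5) tumour voxels;
    ``exclusion`` carries Gleason pattern 3 voxels, which are adjudicated as
    neither positive nor negative by the evaluation metrics. The two masks
    are voxelwise disjoint and share one grid.
    """

    positive: BinaryMask
    exclusion: BinaryMask

    def __post_init__(self):
        self.positive.grid.require_compatible(self.exclusion.grid)
        if np.any(self.positive.voxels & self.exclusion.voxels):
            raise ValueError("positive and exclusion masks must be disjoint")

    @property
    def grid(self) -> ImageGrid:
        return self.positive.grid


def volume_ml(mask: BinaryMask) -> float:
    """Volume of the true voxels in millilitres (spacing is in mm)."""
    return mask.n_true * mask.grid.voxel_volume_mm3 / 1000.0


_OPS = {
    "and": np.logical_and,
    "or": np.logical_or,
    "minus": lambda a, b: np.logical_and(a, np.logical_not(b)),
}


def mask_algebra(a: BinaryMask, b: BinaryMask, op: str) -> BinaryMask:
    """Voxelwise boolean combination of two masks on compatible grids.

    ``op`` is one of ``"and"``, ``"or"``, ``"minus"``.
    """
    a.grid.require_compatible(b.grid)
    try:
        fn = _OPS[op]
    except KeyError:
        raise ValueError(f"unknown mask operation {op!r}; expected one of {sorted(_OPS)}")
    return BinaryMask(a.grid, fn(a.voxels, b.voxels))


_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def connectivity_structure(connectivity: int = 26) -> np.ndarray:
    """3x3x3 structuring element for 6/18/26-connectivity."""
    try:
        rank = _CONNECTIVITY_RANK[int(connectivity)]
    except KeyError:
        raise ValueError(f"connectivity must be one of 6, 18, 26, got {connectivity}")
    return ndimage.generate_binary_structure(3, rank)


def connected_components(mask: BinaryMask, connectivity: int = 26):
    """Label the connected components of a mask.

    Returns ``(labels, n_components)`` where ``labels`` is an integer array on
    the mask grid with 0 for background and 1..n for the components, which are
    maximal under the requested connectivity. An empty mask yields zero
    components.
    """
    structure = connectivity_structure(connectivity)
    labels, n = ndimage.label(mask.voxels, structure=structure)
    return labels, int(n)
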