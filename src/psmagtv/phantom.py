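"""Synthetic PET phantom and observer simulator.

Generates the inputs every downstream stage needs — an SUV volume with a
prostate, an adjacent hot bladder and one or more intraprostatic lesions,
the corresponding organ masks, a histopathology-style reference annotation
(high-grade lesion plus a Gleason-3 rim that metrics treat as neither
positive nor negative) — and simulated manual delineations from observers
with controllable sensitivity/specificity.

The emulated acquisition is [68Ga]-PSMA PET reconstructed on a
2.34 x 2.34 x 2.78 mm voxel grid with Gaussian post-smoothing; the phantom
models that as a piecewise-constant uptake map convolved with an isotropic
Gaussian point-spread function, followed by signal-dependent Gaussian noise
(a Poisson-like surrogate for iteratively reconstructed PET images).

All randomness flows from one integer seed through independent child
streams (geometry, noise, one per observer), so e.g. adding observers never
perturbs the phantom itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import BinaryMask, ImageGrid, ReferenceAnnotation, SUVVolume

__all__ = [
    "PhantomSpec",
    "ObserverModel",
    "PlacementError",
    "generate_phantom",
    "simulate_observers",
    "child_rng",
]

#: FWHM of a Gaussian = _FWHM_TO_SIGMA * sigma
_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


class PlacementError(RuntimeError):
    """A lesion could not be placed inside the prostate."""


def child_rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic child generator of a master seed.

    Child streams are identified by an integer key path, so independent
    purposes (geometry, noise, observer k) never share a stream.
    """
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in key))
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, uptake and acquisition parameters of one phantom case.

    Uptake defaults follow the ordering bladder > lesion > Gleason-3 rim >
    benign prostate > background, the configuration that reproduces the
    hot-bladder failure mode and the moderate tumour-to-background contrast
    of [68Ga]-PSMA prostate imaging.
    """

    shape: tuple = (96, 96, 48)
    spacing: tuple = (2.34, 2.34, 2.78)
    prostate_radii_mm: tuple = (22.0, 19.0, 17.0)
    bladder_radii_mm: tuple = (18.0, 16.0, 15.0)
    #: standoff between the prostate surface and the hot bladder lumen along
    #: ``bladder_direction`` (bladder wall + neck; keeps the urine pool hot
    #: but physically separated from prostate tissue)
    bladder_gap_mm: float = 8.0
    #: unit-ish direction from prostate centre towards the bladder
    bladder_direction: tuple = (0.0, 0.6, 0.8)
    n_lesions: int = 1
    lesion_radius_range_mm: tuple = (5.0, 8.0)
    gleason3_rim_voxels: int = 1
    background_suv: float = 0.5
    benign_suv: float = 2.0
    lesion_suv: float = 8.0
    rim_suv: float = 4.0
    bladder_suv: float = 20.0
    psf_fwhm_mm: float = 5.0
    noise_scale: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.n_lesions < 1:
            raise ValueError("n_lesions must be >= 1")
        if self.gleason3_rim_voxels < 0:
            raise ValueError("gleason3_rim_voxels must be >= 0")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        lo, hi = self.lesion_radius_range_mm
        if not (0 < lo <= hi):
            raise ValueError("lesion_radius_range_mm must be 0 < lo <= hi")
        for name in ("background_suv", "benign_suv", "lesion_suv", "rim_suv", "bladder_suv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def grid(self) -> ImageGrid:
        return ImageGrid(shape=self.shape, spacing=self.spacing)


@dataclass(frozen=True)
class ObserverModel:
    """Per-voxel performance model of manual delineators.

    Each observer retains a truth voxel with probability ``sensitivity`` and
    marks a non-truth voxel of the decision region with probability
    ``1 - specificity``; both may be scalars or per-observer sequences.
    Specificity is defined over a bounded decision region (e.g. the
    prostate), not the whole volume. ``boundary_jitter_mm`` optionally adds a
    random morphological dilation/erosion of up to that radius; the default
    of 0 keeps empirical per-observer sensitivity/specificity converging to
    the nominal values as the region grows.
    """

    n_observers: int = 4
    sensitivity: object = 0.85
    specificity: object = 0.99
    boundary_jitter_mm: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_observers < 1:
            raise ValueError("n_observers must be >= 1")
        if self.boundary_jitter_mm < 0:
            raise ValueError("boundary_jitter_mm must be >= 0")
        for p in np.atleast_1d(np.asarray(self.sensitivity, dtype=float)):
            if not (0 < p <= 1):
                raise ValueError("sensitivity must lie in (0, 1]")
        for q in np.atleast_1d(np.asarray(self.specificity, dtype=float)):
            if not (0 < q <= 1):
                raise ValueError("specificity must lie in (0, 1]")

    def per_observer(self, which: str) -> np.ndarray:
        vals = np.atleast_1d(np.asarray(getattr(self, which), dtype=float))
        if vals.size == 1:
            return np.full(self.n_observers, float(vals[0]))
        if vals.size != self.n_observers:
            raise ValueError(
                f"{which} must be scalar or length {self.n_observers}, got {vals.size}"
            )
        return vals.astype(float)


def _ellipsoid(grid: ImageGrid, center_mm, radii_mm) -> np.ndarray:
    X, Y, Z = grid.voxel_centers()
    cx, cy, cz = center_mm
    rx, ry, rz = radii_mm
    return ((X - cx) / rx) ** 2 + ((Y - cy) / ry) ** 2 + ((Z - cz) / rz) ** 2 <= 1.0


def _support_radius(radii_mm, direction) -> float:
    # support function of an axis-aligned ellipsoid in a unit direction
    return float(np.sqrt(sum((r * u) ** 2 for r, u in zip(radii_mm, direction))))


def _place_lesions(spec: PhantomSpec, center_mm, rng) -> list:
    """Sample (centre, radius) pairs with each sphere strictly inside the
    prostate ellipsoid. Raises PlacementError after bounded retries."""
    radii = np.asarray(spec.prostate_radii_mm, dtype=float)
    min_r = float(radii.min())
    lesions = []
    for _ in range(spec.n_lesions):
        r = float(rng.uniform(*spec.lesion_radius_range_mm))
        placed = False
        for _attempt in range(200):
            # uniform point in the shrunken normalized ball that guarantees
            # the sphere of radius r fits inside the ellipsoid
            max_norm = 1.0 - r / min_r - 1e-6
            if max_norm <= 0:
                break
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            rho = max_norm * rng.uniform() ** (1.0 / 3.0)
            center = np.asarray(center_mm) + u * rho * radii
            lesions.append((center, r))
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"cannot place a lesion of radius {r:.1f} mm inside prostate radii {tuple(radii)}"
            )
    return lesions


def generate_phantom(spec: PhantomSpec):
    """Generate one phantom case.

    Returns ``(suv, prostate, bladder, reference)`` where ``reference`` is a
    :class:`ReferenceAnnotation` whose positive mask is the union of the
    lesion spheres and whose exclusion mask is a Gleason-3-style rim built by
    dilating the lesions by ``gleason3_rim_voxels`` within the prostate.

    Deterministic for a fixed spec (the seed is part of the spec). The
    noiseless uptake map is convolved with a Gaussian of FWHM
    ``psf_fwhm_mm`` (skipped when <= 0), then voxelwise Gaussian noise with
    standard deviation ``noise_scale * sqrt(blurred value)`` is added and
    negatives are clipped to zero.
    """
    grid = spec.grid
    rng_geo = child_rng(spec.seed, 0)
    rng_noise = child_rng(spec.seed, 1)

    extent = [(n - 1) * s for n, s in zip(grid.shape, grid.spacing)]
    prostate_center = np.array([e / 2.0 for e in extent])
    prostate_vox = _ellipsoid(grid, prostate_center, spec.prostate_radii_mm)
    if not prostate_vox.any():
        raise ValueError("prostate ellipsoid does not cover any voxel of the grid")

    u = np.asarray(spec.bladder_direction, dtype=float)
    u = u / np.linalg.norm(u)
    offset = (
        _support_radius(spec.prostate_radii_mm, u)
        + _support_radius(spec.bladder_radii_mm, u)
        + spec.bladder_gap_mm
    )
    bladder_center = prostate_center + u * offset
    bladder_vox = _ellipsoid(grid, bladder_center, spec.bladder_radii_mm)
    bladder_vox &= ~prostate_vox  # enforce disjointness

    lesions = _place_lesions(spec, prostate_center, rng_geo)
    positive_vox = np.zeros(grid.shape, dtype=bool)
    X, Y, Z = grid.voxel_centers()
    for center, r in lesions:
        positive_vox |= (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2 <= r**2
    positive_vox &= prostate_vox
    if not positive_vox.any():
        raise PlacementError("no lesion covers any voxel at this grid resolution")

    if spec.gleason3_rim_voxels > 0:
        rim = ndimage.binary_dilation(
            positive_vox,
            structure=ndimage.generate_binary_structure(3, 3),
            iterations=spec.gleason3_rim_voxels,
        )
        exclusion_vox = rim & prostate_vox & ~positive_vox
    else:
        exclusion_vox = np.zeros(grid.shape, dtype=bool)

    uptake = np.full(grid.shape, spec.background_suv, dtype=np.float64)
    uptake[prostate_vox] = spec.benign_suv
    uptake[exclusion_vox] = spec.rim_suv
    uptake[positive_vox] = spec.lesion_suv
    uptake[bladder_vox] = spec.bladder_suv

    if spec.psf_fwhm_mm > 0:
        sigma_vox = [
            spec.psf_fwhm_mm / _FWHM_TO_SIGMA / s for s in grid.spacing
        ]
        blurred = ndimage.gaussian_filter(uptake, sigma=sigma_vox, mode="nearest")
    else:
        blurred = uptake

    if spec.noise_scale > 0:
        noise = rng_noise.standard_normal(grid.shape)
        values = blurred + spec.noise_scale * np.sqrt(np.clip(blurred, 0, None)) * noise
        values = np.clip(values, 0.0, None)
    else:
        values = blurred

    suv = SUVVolume(grid, values)
    prostate = BinaryMask(grid, prostate_vox)
    bladder = BinaryMask(grid, bladder_vox)
    reference = ReferenceAnnotation(
        positive=BinaryMask(grid, positive_vox),
        exclusion=BinaryMask(grid, exclusion_vox),
    )
    return suv, prostate, bladder, reference


def simulate_observers(truth: BinaryMask, region: BinaryMask, model: ObserverModel):
    """Simulate manual delineations of ``truth`` by independent observers.

    Each observer retains every truth voxel independently with probability
    ``sensitivity`` and adds every voxel of ``region minus truth``
    independently with probability ``1 - specificity``, then (optionally)
    applies a random boundary dilation/erosion of radius up to
    ``boundary_jitter_mm``. Returns a list of ``n_observers`` masks on the
    truth grid.
    """
    truth.grid.require_compatible(region.grid)
    if truth.empty:
        raise ValueError("truth mask is empty: there is no lesion to delineate")
    if np.any(truth.voxels & ~region.voxels):
        raise ValueError("truth must be contained in the decision region")

    p = model.per_observer("sensitivity")
    q = model.per_observer("specificity")
    truth_idx = truth.voxels
    neg_idx = region.voxels & ~truth.voxels
    n_truth = int(truth_idx.sum())
    n_neg = int(neg_idx.sum())

    masks = []
    for j in range(model.n_observers):
        rng = child_rng(model.seed, 2, j)
        vox = np.zeros(truth.grid.shape, dtype=bool)
        vox[truth_idx] = rng.uniform(size=n_truth) < p[j]
        if n_neg:
            vox[neg_idx] = rng.uniform(size=n_neg) < (1.0 - q[j])
        if model.boundary_jitter_mm > 0:
            r_mm = float(rng.uniform(0, model.boundary_jitter_mm))
            iters = int(r_mm / min(truth.grid.spacing))
            if iters >= 1:
                op = ndimage.binary_dilation if rng.uniform() < 0.5 else ndimage.binary_erosion
                vox = op(vox, structure=ndimage.generate_binary_structure(3, 1), iterations=iters)
        masks.append(BinaryMask(truth.grid, vox))
    return masks
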