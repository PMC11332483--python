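"""Semi-automatic GTV segmentation operators.

Four families, all operating on a pre-processed :class:`AnalysisRegion`:

* absolute SUV thresholds (SUV > 2 ... SUV > 4.5),
* relative thresholds at a fraction of SUVmax (SUVmax20% ... SUVmax50%),
* adaptive local-mean thresholding with a sensitivity parameter S,
* multi-level Otsu thresholding (2 or 3 thresholds, top class = GTV).

Threshold comparisons are strict (">"): a voxel is tumour only when its
uptake exceeds the cut, so a threshold above the regional maximum legally
yields an empty GTV (a recorded outcome, not an error). The absolute and
relative families keep, by default, only the connected component containing
the SUVmax voxel; the adaptive and Otsu families apply no component
filtering by default. Both behaviours are switchable via the component
policy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import BinaryMask, SUVVolume, connectivity_structure
from .preprocess import AnalysisRegion

__all__ = [
    "SegmentationConfig",
    "SegmentationResult",
    "DegenerateHistogramError",
    "absolute_threshold",
    "relative_threshold",
    "select_component",
    "adaptive_threshold",
    "otsu_multilevel",
    "segment_all",
]


class DegenerateHistogramError(ValueError):
    """The masked intensity histogram cannot support the requested classes."""


@dataclass(frozen=True)
class SegmentationConfig:
    """The full battery of method variants run by ``segment_all``."""

    absolute_thresholds: tuple = (2.0, 2.5, 3.0, 3.5, 4.0, 4.5)
    relative_fractions: tuple = (0.20, 0.30, 0.40, 0.50)
    sensitivity: float = 0.0
    otsu_n_thresholds: tuple = (2, 3)
    otsu_bins: int = 128
    #: component policy for the absolute/relative families
    component_policy: str = "max-component"

    def __post_init__(self):
        if any(t <= 0 for t in self.absolute_thresholds):
            raise ValueError("absolute thresholds must be > 0")
        if any(not (0 < f < 1) for f in self.relative_fractions):
            raise ValueError("relative fractions must lie in (0, 1)")
        if not (0 <= self.sensitivity <= 0.5):
            raise ValueError("sensitivity S must lie in [0, 0.5]")
        if self.otsu_bins < max(self.otsu_n_thresholds) + 1:
            raise ValueError("otsu_bins must be >= n_thresholds + 1")


@dataclass
class SegmentationResult:
    """A GTV on the cropped grid plus the realized cut values."""

    gtv: BinaryMask
    method_label: str
    derived_thresholds: tuple = ()

    @property
    def empty(self) -> bool:
        """True when no GTV was generated (legal outcome at high cuts)."""
        return self.gtv.empty


def _format_suv(t: float) -> str:
    return f"{t:g}"


def select_component(raw: BinaryMask, suv: SUVVolume, policy: str = "max-component") -> BinaryMask:
    """Apply a connected-component policy to a raw threshold mask.

    ``max-component`` keeps only the 26-connected component containing the
    voxel of maximum SUV within the raw mask (ties broken by lowest
    lexicographic index); ``all`` and ``none`` return the mask unchanged. An
    empty mask is returned unchanged under every policy.
    """
    raw.grid.require_compatible(suv.grid)
    if policy in ("all", "none"):
        return raw
    if policy != "max-component":
        raise ValueError(f"unknown component policy {policy!r}")
    if raw.empty:
        return raw
    labels, n = ndimage.label(raw.voxels, structure=connectivity_structure(26))
    if n == 1:
        return raw
    vals = np.where(raw.voxels, suv.values, -np.inf)
    # argmax of C-ordered flat array = lowest lexicographic index among ties
    seed_idx = np.unravel_index(int(np.argmax(vals)), vals.shape)
    keep = labels == labels[seed_idx]
    return BinaryMask(raw.grid, keep)


def absolute_threshold(
    region: AnalysisRegion, t: float, component_policy: str = "max-component"
) -> SegmentationResult:
    """Segment voxels of the eligibility mask with SUV strictly above ``t``."""
    if t <= 0:
        raise ValueError("threshold must be > 0")
    raw = BinaryMask(
        region.grid, region.analysis_mask.voxels & (region.cropped_suv.values > t)
    )
    gtv = select_component(raw, region.cropped_suv, component_policy)
    return SegmentationResult(
        gtv=gtv, method_label=f"SUV > {_format_suv(t)}", derived_thresholds=(float(t),)
    )


def relative_threshold(
    region: AnalysisRegion, fraction: float, component_policy: str = "max-component"
) -> SegmentationResult:
    """Segment at ``fraction`` of the SUVmax of the pre-processed region."""
    if not (0 < fraction < 1):
        raise ValueError("fraction must lie in (0, 1)")
    if region.analysis_mask.empty:
        raise ValueError("analysis mask is empty")
    suvmax = region.suv_max
    if suvmax <= 0:
        raise ValueError("SUVmax of the analysis region is 0; relative threshold is degenerate")
    t = fraction * suvmax
    result = absolute_threshold(region, t, component_policy)
    return SegmentationResult(
        gtv=result.gtv,
        method_label=f"SUVmax{int(round(fraction * 100))}%",
        derived_thresholds=(float(t),),
    )


def _local_mean_slice(slice_vals: np.ndarray, window: int) -> np.ndarray:
    """Box-filter mean over a square in-plane window with replicate padding.

    The slice is centred on its mean before filtering so that a constant
    slice yields its exact value back (the box filter is then applied to an
    exactly-zero array), preserving the strict-comparison contract.
    """
    offset = float(slice_vals.mean())
    centred = slice_vals - offset
    m = offset + ndimage.uniform_filter(centred, size=window, mode="nearest")
    # SUV is non-negative, so the exact local mean is too; clamp float noise
    return np.maximum(m, 0.0)


def default_adaptive_window(shape_2d) -> int:
    """Conventional local-mean window: side = 2*floor(max(dims)/16) + 1."""
    return 2 * (max(int(shape_2d[0]), int(shape_2d[1])) // 16) + 1


def adaptive_threshold(
    region: AnalysisRegion, sensitivity: float = 0.0, window: int | None = None
) -> SegmentationResult:
    """Adaptive local-mean thresholding with sensitivity S in [0, 0.5].

    Each axial slice is processed in 2D (PET axial resolution differs from
    in-plane): the local mean m(x) is a box-filter mean over a square window
    (side ``2*floor(max(in-plane dims)/16) + 1`` unless given), and a voxel
    is tumour iff SUV(x) > m(x) * (1 + 0.3*(0.5 - S)). S = 0.5 thresholds at
    the local mean exactly; decreasing S raises the cut, so masks are nested
    and non-decreasing in S. The result is intersected with the eligibility
    mask.
    """
    if not (0 <= sensitivity <= 0.5):
        raise ValueError("sensitivity S must lie in [0, 0.5]")
    nx, ny, nz = region.grid.shape
    w = int(window) if window is not None else default_adaptive_window((nx, ny))
    if w < 1 or w % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    scale = 1.0 + 0.3 * (0.5 - sensitivity)
    vox = np.zeros(region.grid.shape, dtype=bool)
    values = region.cropped_suv.values
    for k in range(nz):
        sl = values[:, :, k]
        m = _local_mean_slice(sl, w)
        vox[:, :, k] = sl > m * scale
    vox &= region.analysis_mask.voxels
    return SegmentationResult(
        gtv=BinaryMask(region.grid, vox),
        method_label="Adaptive",
        derived_thresholds=(float(scale),),
    )


# relative tolerance for declaring two between-class variances tied
_OTSU_TIE_RTOL = 1e-10


def _between_class_variance(counts_prefix, moment_prefix, boundaries) -> float:
    """Between-class variance of a histogram partition given prefix sums."""
    total = counts_prefix[-1]
    mu = moment_prefix[-1] / total
    var = 0.0
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        w = counts_prefix[b] - counts_prefix[a]
        if w <= 0:
            continue
        m = (moment_prefix[b] - moment_prefix[a]) / w
        var += (w / total) * (m - mu) ** 2
    return var


def otsu_multilevel(
    region: AnalysisRegion, n_thresholds: int = 2, bins: int = 128
) -> SegmentationResult:
    """Multi-level Otsu thresholding of the masked SUV histogram.

    The histogram uses ``bins`` uniform bins on [0, SUVmax] over the
    eligibility-mask voxels only. All increasing tuples of bin boundaries are
    searched exhaustively for the maximum between-class variance
    sum_k w_k (mu_k - mu)^2; near-ties (relative 1e-10) are broken toward
    the lowest tuple. The GTV is the top intensity class; the realized
    thresholds are reported in SUV units (bin upper edges).
    """
    if n_thresholds not in (2, 3):
        raise ValueError("n_thresholds must be 2 or 3")
    if bins < n_thresholds + 1:
        raise ValueError("bins must be >= n_thresholds + 1")
    values = region.cropped_suv.values[region.analysis_mask.voxels]
    if np.unique(values).size < n_thresholds + 1:
        raise DegenerateHistogramError(
            f"need at least {n_thresholds + 1} distinct masked values for "
            f"{n_thresholds + 1} classes"
        )
    suvmax = float(values.max())
    if suvmax <= 0:
        raise DegenerateHistogramError("masked volume is identically zero")

    bin_width = suvmax / bins
    bin_idx = np.minimum((values / bin_width).astype(np.int64), bins - 1)
    counts = np.bincount(bin_idx, minlength=bins).astype(np.float64)
    centers = (np.arange(bins) + 0.5) * bin_width

    P = np.concatenate(([0.0], np.cumsum(counts)))           # prefix counts
    M = np.concatenate(([0.0], np.cumsum(counts * centers)))  # prefix moments
    total = P[-1]
    mu = M[-1] / total

    combos = np.array(
        list(itertools.combinations(range(1, bins), n_thresholds)), dtype=np.int64
    )
    bounds = np.hstack(
        [
            np.zeros((combos.shape[0], 1), dtype=np.int64),
            combos,
            np.full((combos.shape[0], 1), bins, dtype=np.int64),
        ]
    )
    objective = np.zeros(combos.shape[0])
    for k in range(n_thresholds + 1):
        w = P[bounds[:, k + 1]] - P[bounds[:, k]]
        m = M[bounds[:, k + 1]] - M[bounds[:, k]]
        with np.errstate(invalid="ignore", divide="ignore"):
            mk = np.where(w > 0, m / np.where(w > 0, w, 1.0), 0.0)
        objective += np.where(w > 0, (w / total) * (mk - mu) ** 2, 0.0)

    best = float(objective.max())
    tol = _OTSU_TIE_RTOL * max(1.0, abs(best))
    # combos are generated in lexicographic order: first near-max wins
    winner = int(np.flatnonzero(objective >= best - tol)[0])
    cut_bins = tuple(int(c) for c in combos[winner])

    edges = np.linspace(0.0, suvmax, bins + 1)
    derived = tuple(float(edges[c]) for c in cut_bins)

    all_idx = np.minimum(
        (region.cropped_suv.values / bin_width).astype(np.int64), bins - 1
    )
    vox = region.analysis_mask.voxels & (all_idx >= cut_bins[-1])
    return SegmentationResult(
        gtv=BinaryMask(region.grid, vox),
        method_label=f"Otsu{n_thresholds}",
        derived_thresholds=derived,
    )


def segment_all(region: AnalysisRegion, config: SegmentationConfig | None = None):
    """Run the full battery of semi-automatic method variants.

    Returns the results in report order: absolute thresholds (ascending),
    relative fractions (ascending), adaptive, then multi-level Otsu.
    """
    cfg = config or SegmentationConfig()
    results = []
    for t in cfg.absolute_thresholds:
        results.append(absolute_threshold(region, t, cfg.component_policy))
    for f in cfg.relative_fractions:
        results.append(relative_threshold(region, f, cfg.component_policy))
    results.append(adaptive_threshold(region, cfg.sensitivity))
    for n in cfg.otsu_n_thresholds:
        results.append(otsu_multilevel(region, n, cfg.otsu_bins))
    return results
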