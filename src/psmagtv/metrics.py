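"""Exclusion-aware volumetric metrics against the histopathology reference.

The reference distinguishes high-grade positive voxels (Gleason 4/5) from
Gleason-3 voxels that are adjudicated as neither positive nor negative:
before any overlap count the prediction is stripped of exclusion voxels, so
they are neither credited nor penalized. Coverage and the volume ratio use
the raw positive mask (exclusion never intersects positive).

Conventions for empty predictions: metrics whose denominator is the
prediction (FDR) and boundary distances (HD95) are *missing*; overlap and
coverage are 0, and the volume ratio is 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import BinaryMask, ReferenceAnnotation, volume_ml

__all__ = [
    "MetricRecord",
    "dice",
    "hd95",
    "coverage",
    "fdr",
    "volume_ratio",
    "evaluate_case",
]


@dataclass
class MetricRecord:
    """All per-case, per-method evaluation metrics. ``None`` marks missing."""

    case_id: str
    method_label: str
    dsc: float
    hd95_mm: float | None
    coverage: float
    fdr: float | None
    volume_ratio: float
    gtv_ml: float
    reference_ml: float
    empty_gtv: bool


def _pred_minus_exclusion(pred: BinaryMask, ref: ReferenceAnnotation) -> np.ndarray:
    pred.grid.require_compatible(ref.grid)
    return pred.voxels & ~ref.exclusion.voxels


def dice(pred: BinaryMask, ref: ReferenceAnnotation) -> float:
    """Exclusion-adjusted Dice: 2|P' & pos| / (|P'| + |pos|), P' = pred minus
    exclusion. Returns 0 when both P' and the positive mask are empty."""
    p = _pred_minus_exclusion(pred, ref)
    tp = int(np.sum(p & ref.positive.voxels))
    denom = int(p.sum()) + ref.positive.n_true
    if denom == 0:
        return 0.0
    return 2.0 * tp / denom


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with at least one 6-neighbour outside the mask; the grid
    edge counts as outside."""
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    return mask & ~eroded


def _directed_p95(source_boundary, target_boundary, spacing) -> float:
    """95th percentile of centre-to-centre distances from each source
    boundary voxel to the nearest target boundary voxel."""
    dt = ndimage.distance_transform_edt(~target_boundary, sampling=spacing)
    d = dt[source_boundary]
    return float(np.percentile(d, 95))


def hd95(pred: BinaryMask, ref_positive: BinaryMask, percentile: float = 95) -> float | None:
    """95th-percentile Hausdorff distance in mm, or ``None`` if either mask
    is empty.

    Boundary voxels are mask voxels with a 6-neighbour outside the mask; the
    statistic is the max of the two directed 95th percentiles (linear
    interpolation of order statistics) of Euclidean centre distances,
    computed with an exact anisotropic distance transform.
    """
    pred.grid.require_compatible(ref_positive.grid)
    if pred.empty or ref_positive.empty:
        return None
    spacing = pred.grid.spacing

    # crop to the union bounding box (+1) for speed; distances between the
    # boundary sets are unaffected because both sets lie inside the crop
    both = pred.voxels | ref_positive.voxels
    idx = np.argwhere(both)
    lo = np.maximum(idx.min(axis=0) - 1, 0)
    hi = np.minimum(idx.max(axis=0) + 1, np.asarray(pred.grid.shape) - 1)
    sl = tuple(slice(int(a), int(b) + 1) for a, b in zip(lo, hi))

    # boundaries are computed on the full grid first so that voxels at the
    # image edge keep counting as boundary, then cropped
    bp = _boundary(pred.voxels)[sl]
    br = _boundary(ref_positive.voxels)[sl]
    d_pr = _directed_p95(bp, br, spacing)
    d_rp = _directed_p95(br, bp, spacing)
    return max(d_pr, d_rp)


def coverage(pred: BinaryMask, ref_positive: BinaryMask) -> float:
    """Fraction of the reference positive volume covered by the prediction."""
    pred.grid.require_compatible(ref_positive.grid)
    if ref_positive.empty:
        raise ValueError("reference positive mask is empty; coverage is undefined")
    tp = int(np.sum(pred.voxels & ref_positive.voxels))
    return tp / ref_positive.n_true


def fdr(pred: BinaryMask, ref: ReferenceAnnotation) -> float | None:
    """Volumetric false discovery rate |P' minus pos| / |P'| with P' = pred
    minus exclusion; ``None`` when P' is empty."""
    p = _pred_minus_exclusion(pred, ref)
    n = int(p.sum())
    if n == 0:
        return None
    fp = int(np.sum(p & ~ref.positive.voxels))
    return fp / n


def volume_ratio(pred: BinaryMask, ref_positive: BinaryMask) -> float:
    """GTV volume over the reference positive volume (0 for an empty GTV)."""
    pred.grid.require_compatible(ref_positive.grid)
    if ref_positive.empty:
        raise ValueError("reference positive mask is empty; volume ratio is undefined")
    return volume_ml(pred) / volume_ml(ref_positive)


def evaluate_case(
    pred: BinaryMask,
    ref: ReferenceAnnotation,
    case_id: str = "",
    method_label: str = "",
) -> MetricRecord:
    """Evaluate one predicted GTV against the reference annotation."""
    pred.grid.require_compatible(ref.grid)
    empty = pred.empty
    return MetricRecord(
        case_id=case_id,
        method_label=method_label,
        dsc=dice(pred, ref),
        hd95_mm=None if empty else hd95(pred, ref.positive),
        coverage=coverage(pred, ref.positive),
        fdr=None if empty else fdr(pred, ref),
        volume_ratio=volume_ratio(pred, ref.positive),
        gtv_ml=volume_ml(pred),
        reference_ml=volume_ml(ref.positive),
        empty_gtv=empty,
    )
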