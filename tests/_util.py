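"""Shared builders for the test suite."""

import numpy as np

from psmagtv.core import BinaryMask, ImageGrid, ReferenceAnnotation, SUVVolume
from psmagtv.preprocess import AnalysisRegion

PET_SPACING = (2.34, 2.34, 2.78)


def grid(shape, spacing=(1.0, 1.0, 1.0)):
    return ImageGrid(shape=shape, spacing=spacing)


def mask_from(g, voxels):
    return BinaryMask(g, np.asarray(voxels, dtype=bool))


def region_from(values, analysis=None, spacing=(1.0, 1.0, 1.0)):
    """AnalysisRegion over a raw value array (full-grid eligibility unless given)."""
    values = np.asarray(values, dtype=float)
    g = ImageGrid(shape=values.shape, spacing=spacing)
    if analysis is None:
        analysis = np.ones(values.shape, dtype=bool)
    return AnalysisRegion(
        cropped_suv=SUVVolume(g, values),
        analysis_mask=BinaryMask(g, np.asarray(analysis, dtype=bool)),
        crop_offset=(0, 0, 0),
        parent_grid=g,
    )


def reference_from(g, positive, exclusion=None):
    if exclusion is None:
        exclusion = np.zeros(g.shape, dtype=bool)
    return ReferenceAnnotation(
        positive=mask_from(g, positive), exclusion=mask_from(g, exclusion)
    )


def random_blob_mask(g, rng, p_sphere=1.0, sprinkle=0.0):
    """A random sphere (plus optional sprinkled voxels) as a boolean array."""
    shape = g.shape
    vox = np.zeros(shape, dtype=bool)
    if rng.uniform() < p_sphere:
        c = [rng.integers(1, n - 1) for n in shape]
        r = rng.integers(1, max(2, min(shape) // 3))
        idx = np.indices(shape)
        d2 = sum((idx[i] - c[i]) ** 2 for i in range(3))
        vox |= d2 <= r**2
    if sprinkle > 0:
        vox |= rng.uniform(size=shape) < sprinkle
    return vox
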