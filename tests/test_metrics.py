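"""Exclusion-aware evaluation metrics."""

import numpy as np
import pytest

from psmagtv.metrics import coverage, dice, evaluate_case, fdr, hd95, volume_ratio

from _oracles import brute_hd95
from _util import PET_SPACING, grid, mask_from, reference_from


def _line_setup(n=20):
    g = grid((n, 1, 1))
    return g, np.zeros(g.shape, bool)


class TestDice:
    def test_perfect_prediction(self):
        g, z = _line_setup()
        pos = z.copy()
        pos[3:9] = True
        ref = reference_from(g, pos)
        assert dice(mask_from(g, pos), ref) == 1.0

    def test_disjoint_prediction(self):
        g, z = _line_setup()
        pos = z.copy()
        pos[0:4] = True
        pred = z.copy()
        pred[10:14] = True
        assert dice(mask_from(g, pred), reference_from(g, pos)) == 0.0

    def test_exclusion_adjusted_hand_value(self):
        # |pred| = 10 with 4 in exclusion and 3 in positive; |positive| = 9:
        # P' has 6 voxels, 3 true positive -> DSC = 2*3 / (6+9) = 0.4
        g, z = _line_setup()
        pred = z.copy()
        pred[0:10] = True
        excl = z.copy()
        excl[6:10] = True
        pos = z.copy()
        pos[0:3] = True
        pos[12:18] = True
        ref = reference_from(g, pos, excl)
        assert dice(mask_from(g, pred), ref) == pytest.approx(0.4)

    def test_matches_brute_force_on_random_triples(self, rng):
        g = grid((8, 8, 8))
        for _ in range(30):
            pred = rng.uniform(size=g.shape) < 0.3
            pos = rng.uniform(size=g.shape) < 0.2
            excl = (rng.uniform(size=g.shape) < 0.2) & ~pos
            ref = reference_from(g, pos, excl)
            p = pred & ~excl
            tp = np.sum(p & pos)
            expected = 0.0 if (p.sum() + pos.sum()) == 0 else 2 * tp / (p.sum() + pos.sum())
            assert dice(mask_from(g, pred), ref) == pytest.approx(expected)


class TestHd95:
    def test_identical_masks_give_zero(self):
        g = grid((8, 8, 8), spacing=PET_SPACING)
        vox = np.zeros(g.shape, bool)
        vox[2:5, 2:5, 2:5] = True
        assert hd95(mask_from(g, vox), mask_from(g, vox)) == 0.0

    def test_single_voxel_pair_distance(self):
        g = grid((8, 8, 8), spacing=PET_SPACING)
        a = np.zeros(g.shape, bool)
        b = np.zeros(g.shape, bool)
        a[2, 3, 3] = True
        b[3, 3, 3] = True  # one index apart along x
        assert hd95(mask_from(g, a), mask_from(g, b)) == pytest.approx(2.34)

    def test_empty_mask_is_missing(self):
        g = grid((5, 5, 5))
        empty = mask_from(g, np.zeros(g.shape, bool))
        full = mask_from(g, np.ones(g.shape, bool))
        assert hd95(empty, full) is None
        assert hd95(full, empty) is None

    def test_matches_brute_force_at_anisotropic_spacing(self, rng):
        from _util import random_blob_mask

        g = grid((12, 12, 9), spacing=PET_SPACING)
        for _ in range(15):
            a = random_blob_mask(g, rng, sprinkle=0.02)
            b = random_blob_mask(g, rng, sprinkle=0.02)
            if not (a.any() and b.any()):
                continue
            got = hd95(mask_from(g, a), mask_from(g, b))
            assert got == pytest.approx(brute_hd95(a, b, PET_SPACING), abs=1e-9)

    def test_p100_at_least_p95(self, rng):
        from psmagtv.metrics import _boundary, _directed_p95

        g = grid((10, 10, 10), spacing=PET_SPACING)
        a = np.zeros(g.shape, bool)
        a[2:6, 2:6, 2:6] = True
        b = np.zeros(g.shape, bool)
        b[5:9, 5:9, 5:9] = True
        ba, bb = _boundary(a), _boundary(b)
        from scipy import ndimage

        dt = ndimage.distance_transform_edt(~bb, sampling=PET_SPACING)
        d = dt[ba]
        assert np.percentile(d, 100) >= np.percentile(d, 95)


class TestCoverageFdrVolumeRatio:
    def test_coverage_values(self):
        g, z = _line_setup()
        pos = z.copy()
        pos[0:8] = True
        sup = z.copy()
        sup[0:12] = True
        part = z.copy()
        part[0:6] = True
        assert coverage(mask_from(g, sup), mask_from(g, pos)) == 1.0
        assert coverage(mask_from(g, z), mask_from(g, pos)) == 0.0
        assert coverage(mask_from(g, part), mask_from(g, pos)) == pytest.approx(0.75)
        with pytest.raises(ValueError):
            coverage(mask_from(g, part), mask_from(g, z))

    def test_fdr_values(self):
        g, z = _line_setup()
        pos = z.copy()
        pos[0:5] = True
        # pred: 12 voxels, 5 in positive, 2 in exclusion, 5 elsewhere -> 5/10
        pred = z.copy()
        pred[0:12] = True
        excl = z.copy()
        excl[5:7] = True
        ref = reference_from(g, pos, excl)
        assert fdr(mask_from(g, pred), ref) == pytest.approx(0.5)
        sub = z.copy()
        sub[0:3] = True
        assert fdr(mask_from(g, sub), ref) == 0.0
        far = z.copy()
        far[15:18] = True
        assert fdr(mask_from(g, far), ref) == 1.0
        assert fdr(mask_from(g, z), ref) is None

    def test_volume_ratio_counts(self):
        g, z = _line_setup(40)
        pos = z.copy()
        pos[0:20] = True
        pred = z.copy()
        pred[0:30] = True
        assert volume_ratio(mask_from(g, pred), mask_from(g, pos)) == pytest.approx(1.5)
        assert volume_ratio(mask_from(g, pos), mask_from(g, pos)) == 1.0
        assert volume_ratio(mask_from(g, z), mask_from(g, pos)) == 0.0


class TestEvaluateCase:
    def test_perfect_prediction_record(self):
        g = grid((10, 10, 10), spacing=PET_SPACING)
        pos = np.zeros(g.shape, bool)
        pos[3:7, 3:7, 3:7] = True
        ref = reference_from(g, pos)
        rec = evaluate_case(mask_from(g, pos), ref, "c1", "perfect")
        assert rec.dsc == 1.0
        assert rec.hd95_mm == 0.0
        assert rec.coverage == 1.0
        assert rec.fdr == 0.0
        assert rec.volume_ratio == 1.0
        assert not rec.empty_gtv

    def test_empty_prediction_contract(self):
        g = grid((6, 6, 6))
        pos = np.zeros(g.shape, bool)
        pos[2:4, 2:4, 2:4] = True
        ref = reference_from(g, pos)
        rec = evaluate_case(mask_from(g, np.zeros(g.shape, bool)), ref, "c1", "empty")
        assert rec.empty_gtv
        assert rec.dsc == 0.0
        assert rec.coverage == 0.0
        assert rec.volume_ratio == 0.0
        assert rec.fdr is None
        assert rec.hd95_mm is None

    def test_record_composes_single_metric_calls(self, rng):
        g = grid((8, 8, 8), spacing=PET_SPACING)
        pred = rng.uniform(size=g.shape) < 0.3
        pos = rng.uniform(size=g.shape) < 0.2
        pos[4, 4, 4] = True
        excl = (rng.uniform(size=g.shape) < 0.1) & ~pos
        ref = reference_from(g, pos, excl)
        pm = mask_from(g, pred)
        rec = evaluate_case(pm, ref, "c", "m")
        assert rec.dsc == dice(pm, ref)
        assert rec.hd95_mm == hd95(pm, ref.positive)
        assert rec.coverage == coverage(pm, ref.positive)
        assert rec.fdr == fdr(pm, ref)
        assert rec.volume_ratio == volume_ratio(pm, ref.positive)

    def test_coverage_monotone_along_nested_predictions(self, rng):
        g = grid((8, 8, 8))
        pos = rng.uniform(size=g.shape) < 0.25
        pos[4, 4, 4] = True
        small = (rng.uniform(size=g.shape) < 0.2)
        big = small | (rng.uniform(size=g.shape) < 0.3)
        assert coverage(mask_from(g, small), mask_from(g, pos)) <= coverage(
            mask_from(g, big), mask_from(g, pos)
        )
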