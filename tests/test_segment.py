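"""Threshold, adaptive and multi-level Otsu segmentation operators."""

import numpy as np
import pytest

from psmagtv.core import BinaryMask, SUVVolume
from psmagtv.segment import (
    DegenerateHistogramError,
    absolute_threshold,
    adaptive_threshold,
    default_adaptive_window,
    otsu_multilevel,
    relative_threshold,
    select_component,
)

from _oracles import brute_otsu_thresholds
from _util import grid, mask_from, region_from


class TestAbsoluteThreshold:
    def test_strict_comparison(self):
        region = region_from(np.array([[[1.0, 3.0, 5.0]]]))
        res = absolute_threshold(region, 4.0, component_policy="none")
        assert np.array_equal(res.gtv.voxels, [[[False, False, True]]])
        res3 = absolute_threshold(region, 3.0, component_policy="none")
        assert np.array_equal(res3.gtv.voxels, [[[False, False, True]]])

    def test_threshold_above_maximum_gives_flagged_empty(self):
        region = region_from(np.full((3, 3, 3), 2.0))
        res = absolute_threshold(region, 4.5)
        assert res.empty
        assert res.gtv.n_true == 0

    def test_restricted_to_analysis_mask(self, rng):
        vals = rng.uniform(0, 10, (6, 6, 6))
        analysis = np.zeros(vals.shape, bool)
        analysis[:3] = True
        res = absolute_threshold(region_from(vals, analysis), 1.0, "none")
        assert not np.any(res.gtv.voxels & ~analysis)

    def test_nesting_under_max_component(self, rng):
        for _ in range(20):
            vals = rng.uniform(0, 6, (8, 8, 8))
            region = region_from(vals)
            prev = None
            for t in (4.5, 4.0, 3.0, 2.0):
                cur = absolute_threshold(region, t, "max-component").gtv.voxels
                if prev is not None:
                    assert np.all(~prev | cur)  # higher cut nested in lower
                prev = cur


class TestRelativeThreshold:
    def test_equivalent_to_absolute_at_fraction_of_suvmax(self, rng):
        vals = rng.uniform(0, 10, (8, 8, 8))
        region = region_from(vals)
        rel = relative_threshold(region, 0.4)
        ab = absolute_threshold(region, 0.4 * region.suv_max)
        assert np.array_equal(rel.gtv.voxels, ab.gtv.voxels)
        assert rel.derived_thresholds == ab.derived_thresholds

    def test_label_and_fraction_nesting(self, rng):
        vals = rng.uniform(0, 10, (8, 8, 8))
        region = region_from(vals)
        low = relative_threshold(region, 0.2)
        high = relative_threshold(region, 0.5)
        assert low.method_label == "SUVmax20%"
        assert np.all(~high.gtv.voxels | low.gtv.voxels)

    def test_all_zero_region_raises(self):
        with pytest.raises(ValueError):
            relative_threshold(region_from(np.zeros((3, 3, 3))), 0.4)


class TestSelectComponent:
    def _mask_and_suv(self, vals):
        vals = np.asarray(vals, dtype=float)
        g = grid(vals.shape)
        return mask_from(g, vals > 0), SUVVolume(g, vals)

    def test_keeps_component_of_suvmax(self):
        vals = np.zeros((7, 1, 1))
        vals[0:2] = 3.0   # component A
        vals[4:7] = 5.0   # component B holds the maximum
        raw, suv = self._mask_and_suv(vals)
        kept = select_component(raw, suv, "max-component")
        expected = np.zeros((7, 1, 1), bool)
        expected[4:7] = True
        assert np.array_equal(kept.voxels, expected)

    def test_single_component_unchanged(self):
        vals = np.zeros((5, 1, 1))
        vals[1:4] = 2.0
        raw, suv = self._mask_and_suv(vals)
        for policy in ("max-component", "all", "none"):
            assert np.array_equal(select_component(raw, suv, policy).voxels, raw.voxels)

    def test_tie_broken_by_lexicographic_index(self):
        vals = np.zeros((7, 1, 1))
        vals[0] = 5.0
        vals[6] = 5.0  # same maximal SUV, separate components
        raw, suv = self._mask_and_suv(vals)
        kept = select_component(raw, suv, "max-component")
        expected = np.zeros((7, 1, 1), bool)
        expected[0] = True
        assert np.array_equal(kept.voxels, expected)

    def test_empty_mask_returned_unchanged(self):
        g = grid((3, 3, 3))
        raw = mask_from(g, np.zeros(g.shape, bool))
        suv = SUVVolume(g, np.zeros(g.shape))
        assert select_component(raw, suv, "max-component").empty


class TestAdaptiveThreshold:
    @pytest.mark.parametrize("s", [0.0, 0.25, 0.5])
    def test_constant_slice_gives_empty_mask(self, s):
        region = region_from(np.full((9, 9, 2), 3.7))
        assert adaptive_threshold(region, s, window=3).empty

    def test_sensitivity_half_thresholds_at_local_mean(self, rng):
        vals = rng.uniform(1, 5, (9, 9, 1))
        region = region_from(vals)
        res = adaptive_threshold(region, 0.5, window=3)
        from scipy import ndimage

        sl = vals[:, :, 0]
        m = sl.mean() + ndimage.uniform_filter(sl - sl.mean(), 3, mode="nearest")
        assert np.array_equal(res.gtv.voxels[:, :, 0], sl > m)

    def test_single_hot_voxel_hand_example(self):
        # hot voxel 10 on zero background, window 3, S = 0:
        # local mean at the hot voxel is 10/9; 10 > (10/9)*1.15 keeps it,
        # its zero-valued neighbours all fail the strict comparison
        vals = np.zeros((7, 7, 1))
        vals[3, 3, 0] = 10.0
        res = adaptive_threshold(region_from(vals), 0.0, window=3)
        expected = np.zeros((7, 7, 1), bool)
        expected[3, 3, 0] = True
        assert np.array_equal(res.gtv.voxels, expected)

    def test_monotone_in_sensitivity(self, rng):
        vals = rng.gamma(2.0, 1.5, (12, 12, 4))
        region = region_from(vals)
        prev = None
        for s in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
            cur = adaptive_threshold(region, s).gtv.voxels
            if prev is not None:
                assert np.all(~prev | cur)
            prev = cur

    def test_default_window_rule(self):
        assert default_adaptive_window((23, 21)) == 3
        assert default_adaptive_window((96, 96)) == 13
        assert default_adaptive_window((10, 10)) == 1


class TestOtsuMultilevel:
    def test_three_well_separated_clusters(self, rng):
        vals = np.concatenate(
            [np.full(100, 1.0), np.full(100, 5.0), np.full(100, 9.0)]
        )
        rng.shuffle(vals)
        region = region_from(vals.reshape(10, 10, 3))
        res = otsu_multilevel(region, n_thresholds=2, bins=16)
        t1, t2 = res.derived_thresholds
        assert 1.0 < t1 < 5.0
        assert 5.0 < t2 < 9.0
        assert np.array_equal(res.gtv.voxels, vals.reshape(10, 10, 3) == 9.0)

    def test_exactly_three_distinct_values(self):
        vals = np.array([0.5] * 9 + [2.0] * 9 + [6.0] * 9).reshape(3, 3, 3)
        res = otsu_multilevel(region_from(vals), n_thresholds=2, bins=12)
        assert np.array_equal(res.gtv.voxels, vals == 6.0)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(10):
            vals = rng.gamma(2.0, 1.5, (8, 8, 6))
            analysis = rng.uniform(size=vals.shape) < 0.8
            region = region_from(vals, analysis)
            for n in (2, 3):
                bins = int(rng.integers(n + 2, 25))
                res = otsu_multilevel(region, n, bins)
                bw = vals[analysis].max() / bins
                got = tuple(int(round(t / bw)) for t in res.derived_thresholds)
                assert got == brute_otsu_thresholds(vals[analysis], n, bins)

    def test_cross_check_against_skimage_on_separable_data(self, rng):
        from skimage.filters import threshold_multiotsu

        vals = np.concatenate(
            [rng.normal(1, 0.05, 200), rng.normal(5, 0.05, 200), rng.normal(9, 0.05, 200)]
        )
        vals = np.clip(vals, 0, None)
        region = region_from(vals.reshape(20, 10, 3))
        res = otsu_multilevel(region, 2, bins=64)
        sk = threshold_multiotsu(vals, classes=3)
        assert np.array_equal(
            res.gtv.voxels, (vals > sk[-1]).reshape(20, 10, 3)
        )

    def test_degenerate_histogram_raises(self):
        with pytest.raises(DegenerateHistogramError):
            otsu_multilevel(region_from(np.full((3, 3, 3), 2.0)), 2, 16)

    def test_gtv_respects_analysis_mask(self, rng):
        vals = rng.uniform(0, 10, (8, 8, 8))
        analysis = np.zeros(vals.shape, bool)
        analysis[2:6] = True
        res = otsu_multilevel(region_from(vals, analysis), 2, 32)
        assert not np.any(res.gtv.voxels & ~analysis)
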