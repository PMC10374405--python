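"""Agreement metrics: overlap and distance identities, mapping-value stats, ICC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.ndimage import binary_dilation

from cardiomapseg import geometry as G
from cardiomapseg import metrics as M


def mask_of(labels):
    return G.SegmentationMask(np.asarray(labels, np.uint8))


def random_mask_pair(rng, shape=(24, 24)):
    a = rng.integers(0, 3, shape).astype(np.uint8)
    b = rng.integers(0, 3, shape).astype(np.uint8)
    return mask_of(a), mask_of(b)


def circle_points(r, n=2000, center=(0.0, 0.0)):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + r * np.cos(t), center[1] + r * np.sin(t)])


class TestOverlap:
    def test_identical_masks_score_one(self):
        labels = np.zeros((10, 10), np.uint8)
        labels[2:8, 2:8] = 2
        labels[4:6, 4:6] = 1
        m = mask_of(labels)
        assert M.dice(m, m, "endocardial") == 1.0
        assert M.dice(m, m, "epicardial") == 1.0
        assert M.iou(m, m, "epicardial") == 1.0

    def test_disjoint_regions_score_zero(self):
        a = np.zeros((10, 10), np.uint8)
        b = np.zeros((10, 10), np.uint8)
        a[1:3, 1:3] = 1
        b[6:8, 6:8] = 1
        assert M.dice(mask_of(a), mask_of(b), "endocardial") == 0.0
        assert M.iou(mask_of(a), mask_of(b), "endocardial") == 0.0

    def test_both_empty_is_flagged_nan_not_one(self):
        empty = mask_of(np.zeros((6, 6), np.uint8))
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(M.dice(empty, empty, "endocardial"))
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(M.iou(empty, empty, "epicardial"))

    def test_dice_iou_identity_fuzzed(self):
        rng = np.random.default_rng(0)
        checked = 0
        for _ in range(1000):
            a, b = random_mask_pair(rng)
            for region in ("endocardial", "epicardial"):
                d = M.dice(a, b, region)
                j = M.iou(a, b, region)
                assert d == pytest.approx(2 * j / (1 + j), abs=1e-12)
                checked += 1
        assert checked == 2000

    def test_ring_more_sensitive_than_disk_to_same_shift(self):
        ys, xs = np.mgrid[0:48, 0:48]
        rr = np.hypot(xs - 24, ys - 24)
        ring = np.where((rr >= 8) & (rr <= 12), 2, 0).astype(np.uint8)
        disk = np.where(rr <= 12, 1, 0).astype(np.uint8)
        ring_dice = M.dice(mask_of(ring), mask_of(np.roll(ring, 1, axis=1)), "epicardial")
        disk_dice = M.dice(mask_of(disk), mask_of(np.roll(disk, 1, axis=1)), "endocardial")
        assert ring_dice < disk_dice

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            M.dice(mask_of(np.zeros((4, 4))), mask_of(np.zeros((5, 5))), "endocardial")


class TestDistances:
    def test_identical_point_sets_zero(self):
        pts = circle_points(10)
        assert M.hausdorff_mm(pts, pts) == 0.0
        assert M.mean_surface_distance_mm(pts, pts) == 0.0

    def test_concentric_circles_exact_gap(self):
        a, b = circle_points(10), circle_points(12)
        assert M.hausdorff_mm(a, b, (1.5, 1.5)) == pytest.approx(3.0, rel=0.01)
        assert M.mean_surface_distance_mm(a, b, (1.5, 1.5)) == pytest.approx(3.0, rel=0.01)

    def test_single_outlier_sets_the_hausdorff(self):
        base = circle_points(10)
        outlier = np.vstack([base, [[15.0, 0.0]]])  # 5 px beyond the circle
        assert M.hausdorff_mm(base, outlier, (1.5, 1.5)) == pytest.approx(7.5, rel=1e-6)

    def test_anisotropic_spacing_scales_per_axis(self):
        a = np.array([[0.0, 0.0]])
        below = np.array([[0.0, 1.0]])   # one row down
        beside = np.array([[1.0, 0.0]])  # one column right
        spacing = (2.0, 1.0)  # (row, col) mm
        assert M.hausdorff_mm(a, below, spacing) == pytest.approx(2.0)
        assert M.hausdorff_mm(a, beside, spacing) == pytest.approx(1.0)

    def test_symmetry_and_hd_dominates_msd_fuzzed(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            a = rng.uniform(0, 30, (rng.integers(3, 30), 2))
            b = rng.uniform(0, 30, (rng.integers(3, 30), 2))
            hd_ab = M.hausdorff_mm(a, b)
            hd_ba = M.hausdorff_mm(b, a)
            msd = M.mean_surface_distance_mm(a, b)
            assert hd_ab == pytest.approx(hd_ba, abs=1e-12)
            assert msd == pytest.approx(M.mean_surface_distance_mm(b, a), abs=1e-12)
            assert hd_ab >= msd - 1e-12

    def test_empty_contour_rejected(self):
        with pytest.raises(ValueError):
            M.hausdorff_mm(np.zeros((0, 2)), circle_points(5))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        a=st.lists(st.tuples(st.floats(0, 50), st.floats(0, 50)), min_size=3, max_size=15),
        b=st.lists(st.tuples(st.floats(0, 50), st.floats(0, 50)), min_size=3, max_size=15),
    )
    def test_distance_axioms_hold_for_arbitrary_point_sets(self, a, b):
        pa, pb = np.asarray(a), np.asarray(b)
        hd = M.hausdorff_mm(pa, pb)
        msd = M.mean_surface_distance_mm(pa, pb)
        assert hd >= 0 and msd >= 0
        assert hd >= msd - 1e-9
        assert hd == pytest.approx(M.hausdorff_mm(pb, pa), abs=1e-9)
        # adding a copy of an existing point never changes either metric
        pa2 = np.vstack([pa, pa[:1]])
        assert M.hausdorff_mm(pa2, pb) == pytest.approx(hd, abs=1e-9)


class TestMappingValues:
    def test_uniform_myocardium(self):
        labels = np.zeros((10, 10), np.uint8)
        labels[2:8, 2:8] = 2
        stats = M.myocardial_value_stats(np.full((10, 10), 1000.0), mask_of(labels))
        assert stats.median_ms == 1000.0
        assert stats.iqr_ms == 0.0

    def test_phantom_myocardial_t1_excludes_blood(self, cohort):
        sl = cohort[0].slices[0]
        stats = M.myocardial_value_stats(sl.fitted_t1, sl.mask)
        assert abs(stats.median_ms - 1000.0) < 20.0

    def test_over_dilated_mask_inflates_the_median(self, cohort):
        sl = cohort[0].slices[0]
        labels = sl.mask.labels.copy()
        grown = binary_dilation(labels == 2, iterations=2)
        labels[grown & (labels == 1)] = 2  # bleeds into the bright blood pool
        inflated = M.myocardial_value_stats(sl.fitted_t1, mask_of(labels))
        baseline = M.myocardial_value_stats(sl.fitted_t1, sl.mask)
        assert inflated.median_ms > baseline.median_ms

    def test_empty_myocardium_flagged(self):
        with pytest.warns(UserWarning, match="undefined"):
            stats = M.myocardial_value_stats(np.ones((4, 4)), mask_of(np.zeros((4, 4))))
        assert np.isnan(stats.median_ms)


class TestICC:
    def test_identical_raters_give_unity(self):
        rng = np.random.default_rng(0)
        col = rng.normal(1000, 50, 30)
        icc, lo, hi = M.icc_average_raters(np.column_stack([col, col, col]))
        assert icc == pytest.approx(1.0, abs=1e-9)

    def test_variance_components_recover_expected_icc(self):
        # ICC(2,k) = sb^2 / (sb^2 + sw^2/k); sb=1, sw=1/sqrt(3), k=3 -> 0.9
        rng = np.random.default_rng(3)
        truth = rng.normal(0, 1.0, 100)
        ratings = truth[:, None] + rng.normal(0, 1 / np.sqrt(3.0), (100, 3))
        icc, lo, hi = M.icc_average_raters(ratings)
        assert lo <= 0.9 <= hi

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(4)
        icc, lo, hi = M.icc_average_raters(rng.normal(0, 1, (200, 3)))
        assert abs(icc) < 0.35
        assert lo <= 0.0

    def test_constant_ratings_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            icc, *_ = M.icc_average_raters(np.full((10, 3), 7.0))
        assert np.isnan(icc)

    def test_shape_contracts(self):
        with pytest.raises(ValueError):
            M.icc_average_raters(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            M.icc_average_raters(np.full((10, 1), 1.0))


class TestBestAchievableHd:
    def test_circle_floor_below_pixel_diagonal(self):
        epi = G.ellipse_contour((32, 32), 20, 20, n_points=360)
        endo = G.ellipse_contour((32, 32), 12, 12, n_points=360)
        result = M.best_achievable_hd(epi, endo, (64, 64))
        assert max(result.values()) <= 1.5 * np.sqrt(2.0)

    def test_degenerate_tiny_region_is_flagged(self):
        # the cavity rasterizes to a couple of pixels: no closed boundary
        # loop can be fitted, and the failure names the structure
        epi = G.ellipse_contour((8, 8), 3.0, 3.0, n_points=90)
        endo = G.ellipse_contour((8, 8), 0.4, 0.4, n_points=90)
        with pytest.raises((G.GeometryError, ValueError)):
            M.best_achievable_hd(epi, endo, (16, 16))


class TestAggregateReport:
    def _record(self, sid, pos, dice_val):
        return M.MetricsRecord(sample_id=sid, comparison="m", dice_endo=dice_val,
                               dice_epi=dice_val, iou_endo=dice_val, iou_epi=dice_val,
                               hd_mm=1.0, msd_mm=0.5, slice_position=pos, map_kind="T1map")

    def test_single_record_reports_itself(self):
        table = M.aggregate_report([self._record("a", "basal", 0.9)], "slice_position")
        assert len(table) == 1
        assert table.loc[0, "dice_endo_mean"] == pytest.approx(0.9)

    def test_two_groups_two_rows_and_oracle_means(self):
        records = [self._record("a", "basal", 0.9), self._record("b", "basal", 0.7),
                   self._record("c", "apical", 0.5)]
        table = M.aggregate_report(records, "slice_position").set_index("slice_position")
        assert len(table) == 2
        assert table.loc["basal", "dice_endo_mean"] == pytest.approx((0.9 + 0.7) / 2)
        assert table.loc["apical", "dice_endo_count"] == 1
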