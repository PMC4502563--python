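"""Per-cell quantification: background, segmentation, ratio, colocalization."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from clutraffic.exceptions import (
    CoverageError,
    DegenerateThresholdError,
    ParameterError,
)
from clutraffic.imaging import (
    CellMeasurement,
    QuantConfig,
    estimate_background,
    exclude_low_signal,
    golgi_enrichment_ratio,
    measurements_to_frame,
    pearson_colocalization,
    quantify_image,
    segment_golgi,
)


def disk_roi(shape, center, r):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= r**2


class TestBackground:
    def test_constant_image(self):
        img = np.full((60, 60), 5.0)
        roi = disk_roi(img.shape, (30, 30), 10)
        assert estimate_background(img, [roi]) == (5.0, 0.0)

    def test_zero_outside_roi(self):
        roi = disk_roi((60, 60), (30, 30), 12)
        img = np.where(roi, 100.0, 0.0)
        mean, sd = estimate_background(img, [roi])
        assert mean == 0.0 and sd == 0.0

    def test_gaussian_background_moments_recovered(self, rng):
        img = rng.normal(100.0, 10.0, size=(120, 120))
        roi = disk_roi(img.shape, (60, 60), 20)
        mean, sd = estimate_background(img, [roi])
        assert abs(mean - 100.0) < 1.0
        assert abs(sd - 10.0) < 1.0

    def test_insufficient_background_coverage(self):
        img = np.zeros((20, 20))
        roi = np.ones_like(img, dtype=bool)
        with pytest.raises(CoverageError):
            estimate_background(img, [roi])


class TestGolgiSegmentation:
    def test_bimodal_roi_recovers_high_region(self):
        roi = np.zeros((80, 80), dtype=bool)
        roi[10:70, 10:70] = True
        img = np.full(roi.shape, 10.0)
        high = np.zeros_like(roi)
        high[30:50, 30:55] = True  # 500 px
        img[high] = 200.0
        seg = segment_golgi(img, roi, min_object_px=20)
        np.testing.assert_array_equal(seg.mask, high)
        assert 10.0 < seg.threshold_value < 200.0

    def test_small_component_filtered_out(self):
        roi = np.zeros((60, 60), dtype=bool)
        roi[5:55, 5:55] = True
        img = np.full(roi.shape, 10.0)
        img[20:22, 20:25] = 200.0  # 10 px < min_object_px
        seg = segment_golgi(img, roi, min_object_px=20)
        assert not seg.mask.any()

    def test_constant_channel_raises_degenerate_threshold(self):
        roi = disk_roi((50, 50), (25, 25), 15)
        with pytest.raises(DegenerateThresholdError):
            segment_golgi(np.full((50, 50), 7.0), roi, 20)

    def test_dice_overlap_against_truth_masks(self, default_scene):
        """Otsu + size filter recovers the Golgi truth with Dice >= 0.8."""
        for cid in default_scene.cell_ids:
            roi = default_scene.cell_mask(cid)
            seg = segment_golgi(default_scene.channels["golgi"], roi, 20)
            truth = default_scene.truth.golgi == cid
            dice = 2 * (seg.mask & truth).sum() / (seg.mask.sum() + truth.sum())
            assert dice >= 0.8


class TestEnrichmentRatio:
    def test_uniform_signal_gives_ratio_one(self):
        roi = disk_roi((60, 60), (30, 30), 20)
        golgi = disk_roi((60, 60), (30, 30), 6)
        img = np.where(roi, 7.0, 0.0)
        ratio, _ = golgi_enrichment_ratio(img, roi, golgi, 0.0)
        assert ratio == pytest.approx(1.0)

    def test_toy_values(self):
        roi = np.zeros((1, 10), dtype=bool)
        roi[0, :10] = True
        golgi = np.zeros_like(roi)
        golgi[0, :4] = True
        img = np.where(golgi, 10.0, 2.0)
        ratio, mean_out = golgi_enrichment_ratio(img, roi, golgi, 1.0)
        assert ratio == pytest.approx((10 - 1) / (2 - 1))
        assert mean_out == pytest.approx(1.0)

    def test_empty_golgi_mask_yields_nan_ratio(self):
        roi = disk_roi((40, 40), (20, 20), 12)
        ratio, mean_out = golgi_enrichment_ratio(
            np.full((40, 40), 5.0), roi, np.zeros_like(roi), 1.0
        )
        assert math.isnan(ratio) and mean_out == pytest.approx(4.0)

    def test_nonpositive_denominator_yields_nan(self):
        roi = disk_roi((40, 40), (20, 20), 12)
        golgi = disk_roi((40, 40), (20, 20), 4)
        img = np.where(golgi, 50.0, 2.0)
        ratio, _ = golgi_enrichment_ratio(img, roi, golgi, 5.0)
        assert math.isnan(ratio)

    def test_shift_invariance_with_reestimated_background(self, rng):
        """Adding a constant to the image and to the background estimate
        leaves the ratio unchanged to 1e-9."""
        roi = disk_roi((80, 80), (40, 40), 25)
        golgi = disk_roi((80, 80), (40, 40), 8)
        img = rng.uniform(50, 200, (80, 80))
        r0, _ = golgi_enrichment_ratio(img, roi, golgi, 10.0)
        r1, _ = golgi_enrichment_ratio(img + 37.5, roi, golgi, 10.0 + 37.5)
        assert r1 == pytest.approx(r0, abs=1e-9)

    @given(k=st.floats(min_value=0.01, max_value=1000.0))
    def test_scale_equivariance(self, k):
        rng = np.random.default_rng(7)
        roi = disk_roi((60, 60), (30, 30), 18)
        golgi = disk_roi((60, 60), (30, 30), 6)
        img = rng.uniform(20, 100, (60, 60))
        r0, _ = golgi_enrichment_ratio(img, roi, golgi, 5.0)
        r1, _ = golgi_enrichment_ratio(img * k, roi, golgi, 5.0 * k)
        assert r1 == pytest.approx(r0, rel=1e-9)

    def test_seeded_scenes_order_ratio_by_enrichment(self, default_scene):
        from clutraffic.imaging import quantify_image

        df = measurements_to_frame(quantify_image(default_scene))
        med = df.groupby("genotype")["golgi_ratio"].median()
        assert med["wt"] > med["p.R338W"]
        assert med["wt"] > med["p.I360N"]


class TestExclusion:
    def mk(self, mean_outside):
        return CellMeasurement(1, "wt", 1.0, mean_outside, 0.5)

    def test_zero_cutoff_excludes_nothing(self):
        ms = exclude_low_signal([self.mk(v) for v in (0.0, 1.0, 5.0)], 0.0)
        assert not any(m.excluded for m in ms)

    def test_all_below_cutoff_all_excluded(self):
        ms = exclude_low_signal([self.mk(v) for v in (1.0, 2.0)], 10.0)
        assert all(m.excluded for m in ms)

    def test_mixed_list_flags_exactly_the_low_cells(self):
        values = [5.0, 0.5, 7.0, 0.9, 3.0, 0.1, 4.0, 6.0, 8.0, 2.0]
        ms = exclude_low_signal([self.mk(v) for v in values], 1.0)
        expected = [v < 1.0 for v in values]
        assert [m.excluded for m in ms] == expected
        assert [m.mean_outside for m in ms] == values  # order preserved


class TestPearson:
    def test_identity_and_anticorrelation(self, rng):
        roi = disk_roi((50, 50), (25, 25), 15)
        a = rng.uniform(0, 100, (50, 50))
        assert pearson_colocalization(a, a, roi) == pytest.approx(1.0)
        assert pearson_colocalization(a, a.max() - a, roi) == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self, rng):
        roi = np.ones((100, 100), dtype=bool)
        a = rng.normal(size=(100, 100))
        b = 0.4 * a + rng.normal(size=(100, 100))
        r = pearson_colocalization(a, b, roi)
        av, bv = a[roi], b[roi]
        manual = ((av - av.mean()) * (bv - bv.mean())).sum() / np.sqrt(
            ((av - av.mean()) ** 2).sum() * ((bv - bv.mean()) ** 2).sum()
        )
        assert r == pytest.approx(manual, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        roi = np.ones((20, 20), dtype=bool)
        a = rng.uniform(0, 10, (20, 20))
        b = rng.uniform(0, 10, (20, 20))
        r_ab = pearson_colocalization(a, b, roi)
        r_ba = pearson_colocalization(b, a, roi)
        assert r_ab == r_ba
        assert -1.0 <= r_ab <= 1.0

    def test_constant_channel_is_undefined(self):
        roi = np.ones((10, 10), dtype=bool)
        assert math.isnan(pearson_colocalization(np.ones((10, 10)), np.eye(10), roi))


class TestBatch:
    def test_one_record_per_cell_with_consistent_flags(self, default_scene):
        ms = quantify_image(default_scene, config=QuantConfig(cutoff=50.0))
        assert len(ms) == len(default_scene.cell_ids)
        for m in ms:
            assert m.excluded == (m.mean_outside < 50.0)

    def test_empty_roi_list_gives_empty_output(self, default_scene):
        ms = quantify_image(
            channels=default_scene.channels, cell_rois={}, config=QuantConfig()
        )
        assert ms == []

    def test_rerun_is_identical(self, default_scene):
        a = measurements_to_frame(quantify_image(default_scene))
        b = measurements_to_frame(quantify_image(default_scene))
        assert a.equals(b)

    def test_requires_inputs(self):
        with pytest.raises(ParameterError):
            quantify_image()
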