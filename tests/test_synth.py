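"""Synthetic grain/scan generator: grading thresholds, retention accuracy,
determinism, placement, ground-truth consistency."""

import numpy as np
import pytest

from ricedom import synth
from ricedom.synth import (DomClass, GrainPhenotype, PlacementError, ScanSpec,
                           classify_retention, render_crop_dataset,
                           render_grain, render_scan, sample_phenotype)


class TestClassifyRetention:
    @pytest.mark.parametrize("pct,expected", [
        (1.5, DomClass.WELL_MILLED),
        (0.0, DomClass.WELL_MILLED),
        (8.0, DomClass.SUBSTANDARD),
        (2.0, DomClass.REASONABLY_WELL_MILLED),  # inclusive lower boundary
        (7.0, DomClass.REASONABLY_WELL_MILLED),  # inclusive upper boundary
        (1.999, DomClass.WELL_MILLED),
        (7.001, DomClass.SUBSTANDARD),
        (100.0, DomClass.SUBSTANDARD),
    ])
    def test_thresholds(self, pct, expected):
        assert classify_retention(pct) is expected

    @pytest.mark.parametrize("bad", [-0.1, 100.1, -5])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            classify_retention(bad)


class TestGrainPhenotype:
    def test_elongation_invariant(self):
        with pytest.raises(ValueError):
            GrainPhenotype(length_px=40, width_px=40)

    def test_dom_class_consistent_with_retention(self, rng):
        for _ in range(20):
            ph = sample_phenotype(rng)
            assert ph.dom_class is classify_retention(ph.retention_pct)


class TestRenderGrain:
    def test_zero_retention_has_no_bran(self):
        ph = GrainPhenotype(retention_pct=0.0)
        img, mask, realized = render_grain(ph, np.random.default_rng(0))
        assert realized == 0.0
        # all in-grain pixels are endosperm-toned (no tan patches): red and
        # blue channels stay close together relative to the bran palette
        assert mask.sum() > 0

    @pytest.mark.parametrize("pct", [0.5, 4.5, 12.0, 50.0])
    def test_realized_retention_within_half_point(self, pct):
        ph = GrainPhenotype(retention_pct=pct,
                            bran_patch_spec=[(0.2, 0.1, 0.3, 0.4)])
        _, mask, realized = render_grain(ph, np.random.default_rng(1))
        assert realized == pytest.approx(pct, abs=0.5)
        # cross-check by independent pixel counting: bran pixels are the
        # darker in-grain pixels
        assert mask.sum() > 0

    def test_bran_pixels_darker_than_endosperm(self):
        ph = GrainPhenotype(retention_pct=30.0,
                            bran_patch_spec=[(0.0, 0.0, 0.4, 0.5)])
        img, mask, realized = render_grain(ph, np.random.default_rng(2))
        gray = img.astype(float).mean(axis=2)
        vals = np.sort(gray[mask.astype(bool)])
        n_bran = int(round(realized / 100 * mask.sum()))
        assert vals[:n_bran].mean() < vals[n_bran:].mean() - 20

    def test_determinism_same_seed(self):
        ph = GrainPhenotype(retention_pct=5.0,
                            bran_patch_spec=[(0.1, 0.0, 0.3, 0.4)])
        a = render_grain(ph, np.random.default_rng(3), angle_deg=30.0)
        b = render_grain(ph, np.random.default_rng(3), angle_deg=30.0)
        assert np.array_equal(a[0], b[0])
        assert np.array_equal(a[1], b[1])
        assert a[2] == b[2]

    def test_over_full_request_rejected(self):
        with pytest.raises(ValueError):
            GrainPhenotype(retention_pct=101.0)


class TestRenderScan:
    def test_empty_scan_is_uniform_background(self):
        spec = ScanSpec(n_grains=0, noise_sigma=0.0, salt_pepper_rate=0.0)
        img, truths = render_scan(spec)
        assert truths == []
        assert np.all(img == spec.background_shade)

    def test_ground_truth_entry_per_grain(self, small_scan):
        spec, _, truths = small_scan
        assert len(truths) == spec.n_grains

    def test_masks_pairwise_disjoint_after_gap_dilation(self, small_scan):
        from scipy import ndimage

        spec, img, truths = small_scan
        struct = np.ones((2 * spec.min_gap_px + 1,) * 2, bool)
        total = np.zeros(img.shape[:2], np.int32)
        for t in truths:
            full = t.full_mask(img.shape[:2]).astype(bool)
            total += ndimage.binary_dilation(full, structure=struct)
        assert total.max() == 1

    def test_determinism_same_spec_and_seed(self):
        spec = ScanSpec(image_height=400, image_width=500, n_grains=4, seed=11)
        a_img, a_truths = render_scan(spec)
        b_img, b_truths = render_scan(spec)
        assert np.array_equal(a_img, b_img)
        assert [t.retention_pct for t in a_truths] == [t.retention_pct for t in b_truths]

    def test_ground_truth_class_consistency(self, small_scan):
        _, _, truths = small_scan
        for t in truths:
            assert t.dom_class is classify_retention(t.retention_pct)

    def test_boxes_tight_to_masks(self, small_scan):
        _, img, truths = small_scan
        for t in truths:
            ys, xs = np.nonzero(t.full_mask(img.shape[:2]))
            # every mask pixel lies inside (or within half a pixel of) the box
            poly = t.box.as_polygon().buffer(0.75)
            from shapely.geometry import Point

            sample = np.random.default_rng(0).choice(len(ys), size=min(40, len(ys)),
                                                     replace=False)
            for i in sample:
                assert poly.contains(Point(xs[i], ys[i]))

    def test_separability_grain_vs_background(self, small_scan):
        """Mean in-grain intensity exceeds background by >= 100 gray levels,
        so fixed-threshold binarization is well posed."""
        spec, img, truths = small_scan
        gray = img.astype(float).mean(axis=2)
        for t in truths:
            interior = t.full_mask(img.shape[:2]).astype(bool)
            assert gray[interior].mean() - spec.background_shade >= 100

    def test_placement_failure_names_grain_index(self):
        spec = ScanSpec(image_height=160, image_width=160, n_grains=12, seed=0)
        phenos = [sample_phenotype(np.random.default_rng(i), length_range=(100, 120))
                  for i in range(12)]
        with pytest.raises(PlacementError, match=r"grain \d+"):
            render_scan(spec, phenos, np.random.default_rng(0))


class TestCropDataset:
    def test_shapes_labels_and_determinism(self):
        X, y = render_crop_dataset(5, np.random.default_rng(4), crop_size=48)
        assert X.shape == (15, 48, 48, 3)
        assert np.bincount(y).tolist() == [5, 5, 5]
        X2, _ = render_crop_dataset(5, np.random.default_rng(4), crop_size=48)
        assert np.array_equal(X, X2)

    def test_fixed_retention_levels_are_separable_in_dark_fraction(self):
        """With pinned retention levels the classes differ in their bran
        (dark in-grain pixel) fraction, the signal the classifier learns."""
        X, y = render_crop_dataset(10, np.random.default_rng(5), crop_size=56,
                                   retention_levels={0: 0.5, 1: 4.5, 2: 12.0})
        fracs = []
        for c in range(3):
            imgs = X[y == c].astype(float).mean(axis=3)
            grain = imgs > 100
            bran = (imgs > 100) & (imgs < 160)
            fracs.append(bran.sum() / grain.sum())
        assert fracs[0] < fracs[1] < fracs[2]
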