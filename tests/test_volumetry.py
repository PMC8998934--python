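"""Threshold volumetry: voxel arithmetic, component selection, ground truth."""

import numpy as np
import pytest

from t2flux import (
    ROISpec,
    auto_rois,
    compute_t2_map,
    measure_volume,
    segment_roi,
    truncate_voxel_volume,
    voxel_volume,
)


class TestVoxelVolume:
    def test_default_geometry_full_precision_and_truncated(self):
        v = voxel_volume(20.0, 20.0, 256, 256, 0.8)
        assert v == 0.0048828125
        assert truncate_voxel_volume(v) == 0.0048  # truncation, not rounding

    @pytest.mark.parametrize(
        "args,expected",
        [((256.0, 256.0, 256, 256, 1.0), 1.0), ((10.0, 20.0, 100, 200, 0.5), 0.005)],
    )
    def test_other_geometries(self, args, expected):
        assert voxel_volume(*args) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_argument_rejected(self):
        with pytest.raises(ValueError):
            voxel_volume(20.0, 0.0, 256, 256, 0.8)


class TestSegmentRoi:
    def make_roi(self, lo=0.5, hi=1.5, box=(0, 0, 10, 10)):
        return ROISpec(0, *box, lower_threshold=lo, upper_threshold=hi)

    def test_single_block_retained(self):
        img = np.zeros((10, 10))
        img[2:5, 2:5] = 1.0
        mask = segment_roi(img, self.make_roi())
        assert mask.sum() == 9
        assert mask[2:5, 2:5].all()

    def test_largest_of_two_components_kept(self):
        img = np.zeros((10, 10))
        img[1, 1:6] = 1.0  # 5-pixel run
        img[8, 1:4] = 1.0  # 3-pixel run, not 8-connected to the first
        mask = segment_roi(img, self.make_roi())
        assert mask.sum() == 5
        assert mask[1, 1:6].all()
        assert not mask[8].any()

    def test_diagonal_pixels_are_one_component(self):
        # 8-connectivity joins corner-adjacent pixels into one structure
        img = np.zeros((6, 6))
        img[np.arange(4), np.arange(4)] = 1.0
        img[5, 5] = 1.0  # separate single pixel
        mask = segment_roi(img, self.make_roi(box=(0, 0, 6, 6)))
        assert mask.sum() == 4

    def test_empty_band_warns_and_returns_empty(self):
        img = np.zeros((10, 10))
        with pytest.warns(UserWarning, match="no pixels"):
            mask = segment_roi(img, self.make_roi(lo=5.0, hi=6.0))
        assert not mask.any()

    def test_band_is_closed_on_both_ends(self):
        img = np.array([[0.5, 1.5, 0.4, 1.6]])
        mask = segment_roi(img, ROISpec(0, 0, 0, 1, 4, 0.5, 1.5))
        assert mask.tolist() == [[True, True, False, False]]

    def test_tie_broken_toward_box_center(self):
        img = np.zeros((9, 9))
        img[4, 3:5] = 1.0  # 2 px near center
        img[0, 0:2] = 1.0  # 2 px at corner
        mask = segment_roi(img, self.make_roi(box=(0, 0, 9, 9)))
        assert mask[4, 3:5].all() and not mask[0].any()

    def test_determinism_bit_exact(self):
        rng = np.random.default_rng(5)
        img = rng.uniform(size=(20, 20))
        roi = ROISpec(0, 2, 2, 18, 18, 0.4, 0.9)
        assert np.array_equal(segment_roi(img, roi), segment_roi(img, roi))

    def test_box_outside_image_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            segment_roi(np.zeros((5, 5)), self.make_roi(box=(0, 0, 10, 10)))

    def test_nan_pixels_never_in_band(self):
        img = np.full((4, 4), np.nan)
        img[1, 1] = 1.0
        mask = segment_roi(img, self.make_roi(box=(0, 0, 4, 4)))
        assert mask.sum() == 1


class TestMeasureVolume:
    def test_thousand_pixels_default_voxel(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask.ravel()[:1000] = True
        vm = measure_volume({0: [mask]}, 0.0048828125)
        assert vm.total_pixels == 1000
        assert vm.volume_mm3 == pytest.approx(4.8828125, rel=1e-12)

    def test_no_masks_zero_volume(self):
        vm = measure_volume({}, 0.0048828125)
        assert vm.total_pixels == 0
        assert vm.volume_mm3 == 0.0

    def test_overlapping_rois_deduplicated_with_warning(self):
        a = np.zeros((10, 10), dtype=bool)
        b = np.zeros((10, 10), dtype=bool)
        a[0, 0:10] = True  # 10 px
        b[0, 6:10] = b[1, 0:4] = True  # 8 px, 4 shared with a
        with pytest.warns(UserWarning, match="overlap"):
            vm = measure_volume({0: [a, b]}, 1.0)
        assert vm.total_pixels == 14
        assert vm.per_roi_pixels == [10, 8]

    def test_counts_sum_across_slices(self):
        m1 = np.ones((4, 4), dtype=bool)
        m2 = np.zeros((4, 4), dtype=bool)
        m2[0, 0] = True
        vm = measure_volume({0: [m1], 3: [m2]}, 2.0)
        assert vm.total_pixels == 17
        assert vm.volume_mm3 == 34.0

    def test_more_than_five_rois_rejected(self):
        masks = [np.zeros((4, 4), dtype=bool)] * 6
        with pytest.raises(ValueError, match="5-ROI"):
            measure_volume({0: masks}, 1.0)


class TestPhantomGroundTruthRecovery:
    def test_noiseless_recovery_within_boundary_error(self, noiseless_phantom, small_spec):
        """Thresholds bracketing the tumor class recover the true volume."""
        lm, stack = noiseless_phantom
        t2map = compute_t2_map(stack, mask=lm.labels > 0)
        rois = auto_rois(t2map.t2_ms, lm.tissue_mask("tumor"), 57.5, 96.5)
        masks = {}
        for roi in rois:
            masks.setdefault(roi.slice_index, []).append(
                segment_roi(t2map.t2_ms[roi.slice_index], roi)
            )
        vm = measure_volume(masks, small_spec.voxel_volume_mm3)
        # noiseless: every tumor voxel fits to exactly 68 ms, so recovery is exact
        assert vm.volume_mm3 == pytest.approx(lm.ground_truth_tumor_volume_mm3, rel=1e-12)

    def test_volume_monotone_in_band_width(self, noiseless_phantom, small_spec):
        """Nested threshold bands around one component never shrink the volume."""
        lm, stack = noiseless_phantom
        t2map = compute_t2_map(stack, mask=lm.labels > 0)
        sl = int(np.argwhere(lm.tissue_mask("tumor"))[0][0])
        volumes = []
        for half_width in (2.0, 6.0, 12.0, 20.0):
            roi = ROISpec(sl, 0, 0, *t2map.t2_ms.shape[1:], 68.0 - half_width, 68.0 + half_width)
            mask = segment_roi(t2map.t2_ms[sl], roi)
            volumes.append(int(mask.sum()))
        assert volumes == sorted(volumes)
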