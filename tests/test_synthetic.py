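import numpy as np
import pytest
from scipy import ndimage

import tileseg as ts
from tileseg.synthetic import ScanPhantomConfig, SceneConfig


SMALL_SCAN = ScanPhantomConfig(shape=(48, 48, 20), blob_radius_range=(4, 8), seed=2)


class TestScanPhantom:
    def test_shapes_and_channels(self):
        vol, mask = ts.make_brats_like_scan(SMALL_SCAN)
        assert vol.shape == (48, 48, 20, 4)
        assert mask.shape == (48, 48, 20)
        assert set(np.unique(mask)) <= {0, 1}

    def test_background_outside_support_is_exactly_zero(self):
        vol, mask = ts.make_brats_like_scan(SMALL_SCAN)
        corner = vol[:4, :4, :2, :]
        assert np.all(corner == 0)
        assert np.any(vol != 0)
        # mask lies inside the support (where the volume is non-zero)
        assert np.all(vol[..., 0][mask > 0] != 0)

    def test_mask_non_empty_with_blobs_and_empty_without(self):
        vol, mask = ts.make_brats_like_scan(SMALL_SCAN)
        assert mask.sum() > 0
        cfg0 = ScanPhantomConfig(shape=(48, 48, 20), blob_radius_range=(4, 8), n_blobs=0, seed=2)
        _, empty = ts.make_brats_like_scan(cfg0)
        assert empty.sum() == 0

    def test_seed_determinism(self):
        v1, m1 = ts.make_brats_like_scan(SMALL_SCAN)
        v2, m2 = ts.make_brats_like_scan(SMALL_SCAN)
        assert np.array_equal(v1, v2) and np.array_equal(m1, m2)

    def test_oversized_blob_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            ScanPhantomConfig(shape=(16, 16, 8), blob_radius_range=(4, 10))


class TestPreprocess:
    def test_nonzero_moments_after_normalization(self):
        vol, _ = ts.make_brats_like_scan(SMALL_SCAN)
        out = ts.preprocess_scan(vol)
        for ch in range(out.shape[-1]):
            nz = out[..., ch] != 0
            assert abs(out[..., ch][nz].mean()) < 1e-6
            assert abs(out[..., ch][nz].std() - 1.0) < 1e-6

    def test_zero_background_preserved_exactly(self):
        vol, _ = ts.make_brats_like_scan(SMALL_SCAN)
        out = ts.preprocess_scan(vol)
        for ch in range(out.shape[-1]):
            assert np.array_equal(vol[..., ch] == 0, out[..., ch] == 0)

    def test_all_zero_channel_left_untouched_with_warning(self):
        vol = np.zeros((8, 8, 2))
        vol[..., 0] = np.random.default_rng(0).random((8, 8))
        with pytest.warns(UserWarning, match="channel 1"):
            out = ts.preprocess_scan(vol)
        assert np.all(out[..., 1] == 0)

    def test_extreme_outlier_clipped_to_percentile(self):
        rng = np.random.default_rng(1)
        vol = rng.uniform(1, 2, size=(20, 20, 1))
        vol[0, 0, 0] = 1e6
        hi = np.percentile(vol[..., 0], 98.0)
        out = ts.preprocess_scan(vol)
        # the outlier lands at the value the percentile maps to after z-scoring
        nz = vol[..., 0] != 0
        clipped = np.minimum(vol[..., 0], hi)
        expected = (hi - clipped[nz].mean()) / clipped[nz].std()
        assert out[0, 0, 0] == pytest.approx(expected)

    def test_idempotent_on_normalized_unclipped_data(self):
        # two-valued channel: the 98th percentile equals the max, so clipping
        # is a no-op, and the data is already zero-mean unit-sd on non-zeros
        raw = np.zeros((10, 10, 1))
        raw[:5, :, 0] = 1.0
        raw[5:, :, 0] = 3.0
        once = ts.preprocess_scan(raw)
        twice = ts.preprocess_scan(once)
        assert np.allclose(once, twice, atol=1e-6)


class TestSliceScan:
    def test_slice_count_equals_depth(self):
        vol, mask = ts.make_brats_like_scan(SMALL_SCAN)
        pairs = ts.slice_scan(vol, mask)
        assert len(pairs) == 20
        assert pairs[0][0].shape == (48, 48, 4)
        assert pairs[0][1].shape == (48, 48)

    def test_restacking_inverts_slicing(self):
        vol, mask = ts.make_brats_like_scan(SMALL_SCAN)
        pairs = ts.slice_scan(vol, mask)
        assert np.array_equal(ts.stack_slices([m for _, m in pairs]), mask)

    def test_depth_one_volume(self):
        pairs = ts.slice_scan(np.zeros((4, 4, 1, 2)), np.zeros((4, 4, 1), np.uint8))
        assert len(pairs) == 1

    def test_mismatched_mask_rejected(self):
        with pytest.raises(ValueError, match="match"):
            ts.slice_scan(np.zeros((4, 4, 3, 2)), np.zeros((4, 4, 2), np.uint8))


class TestSplitByUnit:
    def test_study_scale_split_sizes(self):
        units = [f"scan{i:03d}" for i in range(335)]
        split = ts.split_by_unit(units, (270 / 335, 30 / 335, 35 / 335), seed=0)
        assert split.sizes == (270, 30, 35)

    def test_floor_allocation_small(self):
        split = ts.split_by_unit(list(range(10)), (0.7, 0.2, 0.1), seed=1)
        assert split.sizes == (7, 2, 1)

    def test_partition_no_unit_in_two_splits(self):
        units = list(range(50))
        split = ts.split_by_unit(units, (0.7, 0.2, 0.1), seed=3)
        seen = split.units("train") + split.units("validation") + split.units("test")
        assert sorted(seen) == sorted(str(u) for u in units)

    def test_seed_changes_assignment_not_sizes(self):
        units = list(range(40))
        a = ts.split_by_unit(units, seed=0)
        b = ts.split_by_unit(units, seed=1)
        assert a.sizes == b.sizes
        assert a.assignment != b.assignment
        assert ts.split_by_unit(units, seed=0).assignment == a.assignment

    def test_too_few_units_rejected(self):
        with pytest.raises(ValueError, match="too few"):
            ts.split_by_unit([1, 2], (0.5, 0.25, 0.25))

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ts.split_by_unit(list(range(10)), (0.5, 0.2, 0.2))


class TestBuildingScene:
    def test_polygon_count_and_polygonize_round_trip(self, small_scene):
        image, mask, polys = small_scene
        assert image.shape == (160, 160, 3)
        assert len(polys) == 12
        assert len(ts.polygonize(mask)) == 12  # gaps >= 1 pixel keep components apart

    def test_mask_is_rasterized_ground_truth(self, small_scene):
        _, mask, polys = small_scene
        assert np.array_equal(ts.rasterize_polygons(polys, mask.shape), mask)

    def test_seed_determinism(self):
        cfg = SceneConfig(image_size=(120, 120), n_buildings=8, building_size_range=(6, 14), seed=4)
        a = ts.make_building_scene(cfg)
        b = ts.make_building_scene(cfg)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_merged_cluster_exhibit_f1_drops_while_dice_stays_high(self, small_scene):
        # Dilating the mask by the cul-de-sac gap merges the cluster into one
        # blob: pixelwise Dice stays decent, polygon F1 collapses.
        _, mask, polys = small_scene
        dilated = ndimage.binary_dilation(mask, iterations=2).astype(np.uint8)
        d = ts.dice(dilated, mask)
        match = ts.polygon_f1(ts.polygonize(dilated), polys)
        assert len(ts.polygonize(dilated)) < len(polys)  # buildings merged
        assert match.f1 < d
        assert match.f1 < 0.8

    def test_infeasible_packing_raises(self):
        cfg = SceneConfig(
            image_size=(40, 40), n_buildings=30, building_size_range=(10, 12),
            min_gap=6, cul_de_sac_count=0, seed=0,
        )
        with pytest.raises(ValueError, match="packing"):
            ts.make_building_scene(cfg)


class TestAugment:
    def _data(self):
        rng = np.random.default_rng(0)
        img = rng.random((12, 12, 3))
        mask = (rng.random((12, 12)) > 0.6).astype(np.uint8)
        return img, mask

    def test_seed_determinism(self):
        img, mask = self._data()
        a = ts.augment(img, mask, seed=5)
        b = ts.augment(img, mask, seed=5)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_flips_and_rot90_preserve_foreground_count(self):
        img, mask = self._data()
        for seed in range(5):
            _, out = ts.augment(img, mask, ops=("flip_v", "flip_h", "rot90"), seed=seed)
            assert out.sum() == mask.sum()

    def test_mask_stays_binary_under_arbitrary_rotation(self):
        img, mask = self._data()
        _, out = ts.augment(img, mask, ops=("rot",), seed=3)
        assert set(np.unique(out)) <= {0, 1}

    def test_double_flip_is_identity(self):
        img, mask = self._data()
        once = np.flip(img, axis=0)
        assert np.array_equal(np.flip(once, axis=0), img)
        i1, m1 = ts.augment(img, mask, ops=("flip_v",), seed=1)
        i2, m2 = ts.augment(i1, m1, ops=("flip_v",), seed=1)
        assert np.array_equal(i2, img) and np.array_equal(m2, mask)

    def test_unsupported_op_rejected(self):
        img, mask = self._data()
        with pytest.raises(ValueError, match="unsupported"):
            ts.augment(img, mask, ops=("shear",))
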