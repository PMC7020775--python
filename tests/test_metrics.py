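import itertools

import numpy as np
import pytest
import shapely.geometry as sgeom
from hypothesis import given, settings, strategies as st

import tileseg as ts
from tileseg.metrics import PolygonSet, polygon_iou, rasterize_polygons


def hand_counted_masks():
    """3x3 masks: gt has 4 foreground pixels, pred overlaps 3 plus 1 extra."""
    gt = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 0]], np.uint8)
    pred = np.array([[1, 1, 0], [1, 0, 0], [0, 0, 1]], np.uint8)
    return pred, gt


class TestConfusionAndDice:
    def test_hand_counted_confusion(self):
        pred, gt = hand_counted_masks()
        c = ts.confusion_counts(pred, gt)
        assert (c.tp, c.fp, c.fn, c.tn) == (3, 1, 1, 4)
        assert c.total == 9

    def test_dice_of_hand_counted_masks(self):
        pred, gt = hand_counted_masks()
        assert ts.dice(pred, gt) == pytest.approx(2 * 3 / (2 * 3 + 1 + 1))

    def test_identical_masks(self):
        _, gt = hand_counted_masks()
        c = ts.confusion_counts(gt, gt)
        assert c.fp == c.fn == 0
        assert ts.dice(gt, gt) == 1.0

    def test_complement_masks(self):
        _, gt = hand_counted_masks()
        c = ts.confusion_counts(1 - gt, gt)
        assert c.tp == c.tn == 0

    def test_empty_empty_convention(self):
        z = np.zeros((4, 4), np.uint8)
        assert ts.dice(z, z) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), np.uint8)
        b = np.zeros((4, 4), np.uint8)
        a[0, 0] = 1
        b[3, 3] = 1
        assert ts.dice(a, b) == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            ts.dice(np.zeros((3, 3)), np.zeros((4, 3)))

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=40)
    def test_symmetric_and_one_iff_identical(self, seed):
        rng = np.random.default_rng(seed)
        a = (rng.random((6, 6)) > 0.5).astype(np.uint8)
        b = (rng.random((6, 6)) > 0.5).astype(np.uint8)
        assert ts.dice(a, b) == pytest.approx(ts.dice(b, a))
        assert (ts.dice(a, b) == 1.0) == np.array_equal(a, b)


class TestPolygonize:
    def test_empty_mask(self):
        assert len(ts.polygonize(np.zeros((5, 5), np.uint8))) == 0

    def test_solid_block_area(self):
        mask = np.zeros((5, 5), np.uint8)
        mask[1:4, 1:4] = 1
        pset = ts.polygonize(mask)
        assert len(pset) == 1
        assert pset[0].area == pytest.approx(9.0)

    def test_diagonal_pixels_split_under_4_connectivity(self):
        mask = np.zeros((4, 4), np.uint8)
        mask[1, 1] = mask[2, 2] = 1
        assert len(ts.polygonize(mask, connectivity=4)) == 2

    def test_hole_preserved_as_interior_ring(self):
        mask = np.zeros((7, 7), np.uint8)
        mask[1:6, 1:6] = 1
        mask[3, 3] = 0
        pset = ts.polygonize(mask)
        assert len(pset) == 1
        assert len(pset[0].interiors) == 1
        assert pset[0].area == pytest.approx(24.0)  # 25 - 1 hole pixel

    def test_non_2d_rejected(self):
        with pytest.raises(ValueError, match="2D"):
            ts.polygonize(np.zeros((3, 3, 3), np.uint8))

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=20)
    def test_rasterize_round_trip_on_rectangles(self, seed):
        rng = np.random.default_rng(seed)
        mask = np.zeros((24, 24), np.uint8)
        rects = []
        for _ in range(3):
            h, w = rng.integers(2, 6, size=2)
            r = rng.integers(0, 24 - h)
            c = rng.integers(0, 24 - w)
            rects.append((r, c, h, w))
        # keep rectangles >= 1 pixel apart by rejecting overlapping/adjacent draws
        kept = []
        occupied = np.zeros((26, 26), bool)
        for r, c, h, w in rects:
            if occupied[max(0, r - 1) : r + h + 1, max(0, c - 1) : c + w + 1].any():
                continue
            occupied[r : r + h, c : c + w] = True
            mask[r : r + h, c : c + w] = 1
            kept.append((r, c, h, w))
        pset = ts.polygonize(mask)
        assert len(pset) == len(kept)
        assert np.array_equal(rasterize_polygons(pset, mask.shape), mask)


class TestPolygonIoU:
    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_geometric_iou_matches_pixel_set_oracle(self, seed):
        rng = np.random.default_rng(seed)
        r1, c1, h1, w1 = rng.integers(0, 8), rng.integers(0, 8), *rng.integers(2, 8, 2)
        r2, c2, h2, w2 = rng.integers(0, 8), rng.integers(0, 8), *rng.integers(2, 8, 2)
        a = sgeom.box(c1, r1, c1 + w1, r1 + h1)
        b = sgeom.box(c2, r2, c2 + w2, r2 + h2)
        ma = rasterize_polygons([a], (20, 20)).astype(bool)
        mb = rasterize_polygons([b], (20, 20)).astype(bool)
        pixel_iou = (ma & mb).sum() / (ma | mb).sum()
        assert polygon_iou(a, b) == pytest.approx(pixel_iou, abs=1e-9)


def brute_force_max_tp(proposals, truths, thr=0.5):
    """Optimal one-to-one matching TP count by exhaustive assignment."""
    ok = {
        (i, j)
        for i, p in enumerate(proposals)
        for j, g in enumerate(truths)
        if polygon_iou(p, g) > thr
    }
    best = 0
    idx = range(len(truths))
    for k in range(min(len(proposals), len(truths)), 0, -1):
        for props in itertools.combinations(range(len(proposals)), k):
            for perm in itertools.permutations(idx, k):
                if all((i, j) in ok for i, j in zip(props, perm)):
                    return k
    return best


class TestPolygonF1:
    def test_identical_sets_perfect_score(self, small_scene):
        _, _, polys = small_scene
        m = ts.polygon_f1(polys, polys)
        assert m.precision == m.recall == m.f1 == 1.0
        assert m.fp == m.fn == 0

    def test_no_proposals(self, small_scene):
        _, _, polys = small_scene
        m = ts.polygon_f1(PolygonSet([]), polys)
        assert (m.tp, m.f1) == (0, 0.0)
        assert m.fn == len(polys)

    def test_merged_building_blob_scores_zero_f1_but_high_dice(self):
        # ground truth: two 10x10 squares with a 5-pixel gap
        gt_mask = np.zeros((30, 40), np.uint8)
        gt_mask[10:20, 5:15] = 1
        gt_mask[10:20, 20:30] = 1
        # proposal: one 25x10 blob spanning both
        pred_mask = np.zeros((30, 40), np.uint8)
        pred_mask[10:20, 5:30] = 1
        # tp=200, fp=50, fn=0: Dice = 2*200/(2*200+50+0) = 8/9
        assert ts.dice(pred_mask, gt_mask) == pytest.approx(400 / 450)
        m = ts.polygon_f1(ts.polygonize(pred_mask), ts.polygonize(gt_mask))
        # IoU with each square is 100/250 = 0.4 < 0.5: no matches at all
        assert (m.tp, m.fp, m.fn, m.f1) == (0, 1, 2, 0.0)

    def test_strictly_above_threshold_required(self):
        # IoU exactly 0.5 must NOT count as a true positive
        a = sgeom.box(0, 0, 1, 1)
        b = sgeom.box(0, 0, 1, 2)  # IoU = 1/2
        m = ts.polygon_f1(PolygonSet([a]), PolygonSet([b]))
        assert m.tp == 0

    def test_one_to_one_matching(self):
        g = sgeom.box(0, 0, 10, 10)
        p1 = sgeom.box(0, 0, 10, 9)   # IoU 0.9
        p2 = sgeom.box(0, 0, 10, 8)   # IoU 0.8
        m = ts.polygon_f1(PolygonSet([p1, p2]), PolygonSet([g]))
        assert m.tp == 1 and m.fp == 1
        assert m.pairs[0][:2] == (0, 0)  # best-IoU proposal wins

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=15)
    def test_greedy_never_exceeds_optimal_assignment(self, seed):
        rng = np.random.default_rng(seed)
        props = [
            sgeom.box(c, r, c + w, r + h)
            for r, c, h, w in zip(
                rng.integers(0, 10, 4), rng.integers(0, 10, 4),
                rng.integers(2, 8, 4), rng.integers(2, 8, 4),
            )
        ]
        truths = [
            sgeom.box(c, r, c + w, r + h)
            for r, c, h, w in zip(
                rng.integers(0, 10, 4), rng.integers(0, 10, 4),
                rng.integers(2, 8, 4), rng.integers(2, 8, 4),
            )
        ]
        m = ts.polygon_f1(PolygonSet(props), PolygonSet(truths))
        assert m.tp <= brute_force_max_tp(props, truths)


class TestGeoJSON:
    def test_round_trip(self, tmp_path, small_scene):
        _, _, polys = small_scene
        path = tmp_path / "gt.geojson"
        polys.write_geojson(path)
        back = PolygonSet.read_geojson(path)
        assert len(back) == len(polys)
        assert all(p.equals(q) for p, q in zip(back, polys))

    def test_affine_transform_hook(self, small_scene):
        _, _, polys = small_scene
        gj = polys.to_geojson(transform=lambda x, y: (x * 0.5 + 100.0, y * 0.5 + 40.0))
        moved = PolygonSet.from_geojson(gj)
        assert moved[0].area == pytest.approx(polys[0].area * 0.25)
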