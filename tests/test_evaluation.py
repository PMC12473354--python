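"""Matching, metric formulas, stratification, fragmentation, OC/UC/TC, seams."""

import numpy as np
import pytest
from shapely.geometry import box

from phenoseg.evaluation import (
    STRATA_BOUNDS,
    associate_predictions,
    f1_from_pr,
    fragmentation_ratio,
    global_errors,
    greedy_match,
    iou_from_pr,
    oc_uc_tc,
    pair_iou,
    parcel_scores,
    pixel_metrics,
    prf,
    seam_analysis,
    seam_zone_mask,
    stratify_by_area,
)
from phenoseg.geo_io import ParcelSet, SceneGrid
from phenoseg.segmentation import tile_grid


def _ps(polys, ids=None):
    ids = np.arange(1, len(polys) + 1) if ids is None else ids
    return ParcelSet(list(polys), ids)


class TestPairIoU:
    def test_identical_disjoint_offset(self):
        a = box(0, 0, 1, 1)
        assert pair_iou(a, box(0, 0, 1, 1)) == pytest.approx(1.0)
        assert pair_iou(a, box(5, 5, 6, 6)) == 0.0
        assert pair_iou(a, box(0.5, 0, 1.5, 1)) == pytest.approx(1 / 3)


class TestGreedyMatch:
    def test_simple_match_and_below_threshold(self):
        gt = _ps([box(0, 0, 10, 10)])
        hit = _ps([box(0, 0, 10, 7.5)])     # IoU 0.75
        res = greedy_match(gt, hit)
        assert res.tp == 1 and res.fp == 0 and res.fn == 0
        miss = _ps([box(0, 0, 10, 4)])      # IoU 0.4
        res = greedy_match(gt, miss)
        assert res.tp == 0 and res.fp == 1 and res.fn == 1

    def test_earlier_gt_wins_competition(self):
        pred = box(0, 0, 10, 10)
        gt = _ps([box(0, 0, 10, 9), box(0, 1, 10, 10)], ids=[5, 6])
        res = greedy_match(gt, _ps([pred]))
        assert res.pairs[0][0] == 5
        assert res.unmatched_gt_ids == [6]

    def test_matches_literal_sequential_oracle(self, rng):
        for _ in range(10):
            gt_polys = [box(x, y, x + rng.uniform(4, 10), y + rng.uniform(4, 10))
                        for x, y in rng.uniform(0, 40, (8, 2))]
            pred_polys = [box(x, y, x + rng.uniform(4, 10), y + rng.uniform(4, 10))
                          for x, y in rng.uniform(0, 40, (10, 2))]
            gt, preds = _ps(gt_polys), _ps(pred_polys)
            res = greedy_match(gt, preds)
            # literal procedural simulation
            used = set()
            pairs = []
            for gi, g in enumerate(gt_polys):
                best, bj = 0.0, -1
                for j, p in enumerate(pred_polys):
                    if j in used:
                        continue
                    iou = pair_iou(g, p)
                    if iou > best:
                        best, bj = iou, j
                if bj >= 0 and best >= 0.50:
                    used.add(bj)
                    pairs.append((int(gt.ids[gi]), int(preds.ids[bj])))
            assert [(g, p) for g, p, _ in res.pairs] == pairs

    def test_one_to_one_invariant(self, rng):
        gt = _ps([box(x, y, x + 8, y + 8) for x, y in rng.uniform(0, 50, (12, 2))])
        preds = _ps([box(x, y, x + 8, y + 8) for x, y in rng.uniform(0, 50, (15, 2))])
        res = greedy_match(gt, preds)
        gids = [g for g, _, _ in res.pairs]
        pids = [p for _, p, _ in res.pairs]
        assert len(set(gids)) == len(gids) and len(set(pids)) == len(pids)
        assert all(iou >= 0.50 for *_, iou in res.pairs)


class TestCountMetrics:
    def test_prf_examples(self):
        assert prf(1, 1, 1) == pytest.approx((0.5, 0.5, 0.5))
        assert prf(5, 0, 0) == pytest.approx((1.0, 1.0, 1.0))
        assert prf(0, 0, 0) == (0.0, 0.0, 0.0)

    def test_identity_iou_from_counts(self, rng):
        for _ in range(50):
            tp, fp, fn = rng.integers(0, 40, 3)
            if tp + fp == 0 or tp + fn == 0 or tp == 0:
                continue
            p, r, _ = prf(int(tp), int(fp), int(fn))
            assert iou_from_pr(p, r) == pytest.approx(tp / (tp + fp + fn), abs=1e-12)

    def test_perfect_scores(self):
        assert f1_from_pr(1.0, 1.0) == 1.0
        assert iou_from_pr(1.0, 1.0) == 1.0


class TestPixelMetrics:
    def test_perfect_and_empty(self):
        gt = np.zeros((10, 10), bool)
        gt[2:8, 2:8] = True
        m = pixel_metrics(gt, gt)
        assert (m.precision, m.recall, m.f1, m.miou) == (1.0, 1.0, 1.0, 1.0)
        m2 = pixel_metrics(gt, np.zeros_like(gt))
        assert m2.recall == 0.0

    def test_matches_double_loop_oracle(self, rng):
        gt = rng.uniform(size=(15, 15)) > 0.5
        pred = rng.uniform(size=(15, 15)) > 0.5
        m = pixel_metrics(gt, pred)
        tp = fp = fn = 0
        for r in range(15):
            for c in range(15):
                if gt[r, c] and pred[r, c]:
                    tp += 1
                elif pred[r, c]:
                    fp += 1
                elif gt[r, c]:
                    fn += 1
        assert m.precision == pytest.approx(tp / (tp + fp))
        assert m.recall == pytest.approx(tp / (tp + fn))
        assert m.miou == pytest.approx(tp / (tp + fp + fn))

    def test_invariant_to_label_permutation(self, rng):
        # binary burning makes pixel metrics independent of parcel ids
        grid = SceneGrid(width=20, height=20, pixel_size=1.0, origin=(0.0, 20.0))
        from phenoseg.geo_io import rasterize_parcels

        polys = [box(1, 1, 8, 8), box(10, 10, 18, 18)]
        a = rasterize_parcels(_ps(polys, ids=[1, 2]), grid, binary=True)
        b = rasterize_parcels(_ps(polys, ids=[2, 1]), grid, binary=True)
        np.testing.assert_array_equal(a, b)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            pixel_metrics(np.zeros((3, 3), bool), np.zeros((4, 4), bool))


class TestStratify:
    @pytest.mark.parametrize(
        "area,stratum",
        [(4999, "small"), (5000, "medium"), (20000, "medium"), (20001, "large")],
    )
    def test_boundaries(self, area, stratum):
        ps = _ps([box(0, 0, 1, area)])
        strata = stratify_by_area(ps, STRATA_BOUNDS)
        assert len(strata[stratum]) == 1
        assert sum(len(s) for s in strata.values()) == 1


class TestFragmentation:
    def test_one_pred_per_gt(self):
        gt = _ps([box(0, 0, 50, 50), box(100, 0, 150, 50)])
        preds = _ps([box(0, 0, 50, 50), box(100, 0, 150, 50)])
        ratio, n_gt, n_assoc = fragmentation_ratio(gt, preds)
        assert (ratio, n_gt, n_assoc) == (1.0, 2, 2)

    def test_empty_stratum_flagged(self):
        ratio, n_gt, n_assoc = fragmentation_ratio(_ps([]), _ps([box(0, 0, 1, 1)]))
        assert ratio is None and n_gt == 0

    def test_association_matches_bruteforce(self, rng):
        gt_polys = [box(x, y, x + 10, y + 10) for x, y in rng.uniform(0, 60, (6, 2))]
        pred_polys = [box(x, y, x + 6, y + 6) for x, y in rng.uniform(0, 60, (14, 2))]
        gt, preds = _ps(gt_polys), _ps(pred_polys)
        assoc = associate_predictions(preds, gt)
        for i, p in enumerate(pred_polys):
            inters = [p.intersection(g).area for g in gt_polys]
            if max(inters) == 0:
                assert assoc[i] == -1
            else:
                assert inters[assoc[i]] == pytest.approx(max(inters))


class TestClassificationErrors:
    def test_perfect_prediction_zero_errors(self):
        g = box(0, 0, 10, 10)
        assert oc_uc_tc(g, _ps([g])) == pytest.approx((0.0, 0.0, 0.0))

    def test_half_coverage(self):
        g = box(0, 0, 10, 10)
        s = box(0, 0, 10, 5)
        oc, uc, tc = oc_uc_tc(s, _ps([g]))
        assert oc == pytest.approx(0.5)
        assert uc == pytest.approx(0.0)
        assert tc == pytest.approx(0.5 / np.sqrt(2))

    def test_no_intersection_is_none(self):
        assert oc_uc_tc(box(100, 100, 110, 110), _ps([box(0, 0, 10, 10)])) is None

    def test_equal_area_weights_average(self):
        gt = _ps([box(0, 0, 10, 10), box(20, 0, 30, 10)])
        # pred1 covers 0.8 of gt1, pred2 covers 0.6 of gt2, equal pred areas
        preds = _ps([box(0, 0, 10, 8), box(20, 0, 30, 8)])
        rep = global_errors(preds, gt)
        assert rep.goc == pytest.approx((0.2 + 0.2) / 2)
        np.testing.assert_allclose(rep.weights.sum(), 1.0, atol=1e-9)

    def test_matches_unvectorised_oracle(self, rng):
        gt_polys = [box(x, y, x + 14, y + 14) for x, y in rng.uniform(0, 40, (6, 2))]
        pred_polys = [box(x, y, x + 10, y + 10) for x, y in rng.uniform(0, 40, (10, 2))]
        gt, preds = _ps(gt_polys), _ps(pred_polys)
        rep = global_errors(preds, gt)
        assert rep.defined
        ocs, ucs, tcs, areas = [], [], [], []
        for s in pred_polys:
            inters = [s.intersection(g).area for g in gt_polys]
            if max(inters) == 0:
                continue
            o = gt_polys[int(np.argmax(inters))]
            i_area = max(inters)
            oc = 1 - i_area / o.area
            uc = 1 - i_area / s.area
            ocs.append(oc)
            ucs.append(uc)
            tcs.append(np.sqrt((oc**2 + uc**2) / 2))
            areas.append(s.area)
        w = np.array(areas) / np.sum(areas)
        assert rep.goc == pytest.approx(float(w @ ocs), abs=1e-12)
        assert rep.guc == pytest.approx(float(w @ ucs), abs=1e-12)
        assert rep.gtc == pytest.approx(float(w @ tcs), abs=1e-12)

    def test_gtc_bounds(self, rng):
        gt = _ps([box(x, y, x + 12, y + 12) for x, y in rng.uniform(0, 50, (4, 2))])
        preds = _ps([box(x, y, x + 9, y + 9) for x, y in rng.uniform(0, 50, (8, 2))])
        rep = global_errors(preds, gt)
        if rep.defined:
            assert max(rep.goc, rep.guc) / np.sqrt(2) <= rep.gtc + 1e-12
            assert 0 <= rep.goc <= 1 and 0 <= rep.guc <= 1 and 0 <= rep.gtc <= 1

    def test_empty_predictions_flagged(self):
        rep = global_errors(_ps([]), _ps([box(0, 0, 5, 5)]))
        assert not rep.defined


class TestParcelScores:
    def test_unmatched_zero_filled_and_dice(self):
        gt = _ps([box(0, 0, 10, 10), box(50, 0, 60, 10)])
        preds = _ps([box(0, 0, 10, 8)])  # matches gt1 with IoU 0.8
        ious, f1s = parcel_scores(gt, preds)
        assert ious[1] == 0.0 and f1s[1] == 0.0
        assert ious[0] == pytest.approx(0.8)
        assert f1s[0] == pytest.approx(2 * 80 / (100 + 80))


class TestSeams:
    def _setup(self):
        grid = SceneGrid(width=96, height=96, pixel_size=1.0, origin=(0.0, 96.0))
        windows = tile_grid(grid, 48, 0.0)
        return grid, windows

    def test_zone_partition_matches_distance_oracle(self):
        grid, windows = self._setup()
        zone = seam_zone_mask(grid, windows, buffer_px=5)
        # brute force: distance from each pixel to nearest boundary-line pixel
        lines = np.zeros(grid.shape, bool)
        for r0, c0, r1, c1 in windows:
            if r0 > 0:
                lines[r0, c0:c1] = True
            if r1 < grid.height:
                lines[r1 - 1, c0:c1] = True
            if c0 > 0:
                lines[r0:r1, c0] = True
            if c1 < grid.width:
                lines[r0:r1, c1 - 1] = True
        ys, xs = np.nonzero(lines)
        rr, cc = np.mgrid[0:96, 0:96]
        d = np.sqrt((rr[..., None] - ys) ** 2 + (cc[..., None] - xs) ** 2).min(-1)
        np.testing.assert_array_equal(zone, d <= 5)

    def test_perfect_prediction_zero_deltas(self, rng):
        grid, windows = self._setup()
        gt = rng.uniform(size=grid.shape) > 0.5
        rep = seam_analysis(gt, gt, windows, grid, buffer_px=5)
        assert rep.defined
        assert all(abs(v) < 1e-12 for v in rep.deltas.values())

    def test_errors_only_in_seam_leave_interior_perfect(self, rng):
        grid, windows = self._setup()
        zone = seam_zone_mask(grid, windows, buffer_px=5)
        gt = rng.uniform(size=grid.shape) > 0.4
        pred = gt.copy()
        pred[zone] = ~pred[zone]
        rep = seam_analysis(gt, pred, windows, grid, buffer_px=5)
        assert rep.interior.f1 == pytest.approx(1.0)
        assert rep.seam.f1 < 0.5

    def test_single_tile_flagged(self):
        grid = SceneGrid(width=32, height=32)
        rep = seam_analysis(
            np.zeros(grid.shape, bool), np.zeros(grid.shape, bool),
            [(0, 0, 32, 32)], grid,
        )
        assert not rep.defined

    def test_seam_and_interior_partition_scene(self):
        grid, windows = self._setup()
        zone = seam_zone_mask(grid, windows, buffer_px=5)
        assert zone.any() and (~zone).any()
        # union is everything, intersection empty by construction of the mask
        assert zone.shape == grid.shape
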