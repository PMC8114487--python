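"""Segmentation metrics against pixel-set enumeration oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from matisse.config import ScoreConfig
from matisse.model import LabelMap
from matisse.scoring import (
    MatchRecord,
    edge_intersection_score,
    fragmentation_by_group,
    iou,
    match_events,
    recall_curve,
    score_prediction,
    split_fraction,
)


# ---------------------------------------------------------------------------
# brute-force oracles on explicit pixel sets

def brute_iou(a, b):
    sa = {tuple(p) for p in np.argwhere(a)}
    sb = {tuple(p) for p in np.argwhere(b)}
    return len(sa & sb) / len(sa | sb)


def brute_match(gt, pred, overlap_fraction=0.2):
    out = {}
    gt_ids = sorted(set(gt.ravel()) - {0})
    pred_ids = sorted(set(pred.ravel()) - {0})
    for g in gt_ids:
        gset = {tuple(p) for p in np.argwhere(gt == g)}
        best_iou, best_p, over = 0.0, None, []
        for p in pred_ids:
            pset = {tuple(q) for q in np.argwhere(pred == p)}
            inter = len(gset & pset)
            if inter == 0:
                continue
            i = inter / len(gset | pset)
            if i > best_iou:
                best_iou, best_p = i, p
            if inter >= overlap_fraction * len(gset):
                over.append(p)
        out[g] = (best_iou, best_p, sorted(over))
    return out


def _lm(arr):
    return LabelMap(np.asarray(arr, dtype=np.int32), 1.0)


class TestIou:
    def test_identical_masks(self):
        m = np.zeros((5, 5), bool)
        m[1:3, 1:4] = True
        assert iou(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((5, 5), bool)
        b = np.zeros((5, 5), bool)
        a[0, 0] = True
        b[4, 4] = True
        assert iou(a, b) == 0.0

    def test_partial_overlap_pixel_count(self):
        a = np.zeros((6, 6), bool)
        b = np.zeros((6, 6), bool)
        a[0:2, 0:2] = True          # 2x2
        b[1:3, 0:2] = True          # 2x2 sharing a 1x2 strip
        assert iou(a, b) == pytest.approx(2 / 6)

    def test_both_empty_is_error(self):
        with pytest.raises(ValueError):
            iou(np.zeros((3, 3), bool), np.zeros((3, 3), bool))


class TestMatchEvents:
    def test_identical_prediction_all_perfect(self):
        gt = _lm([[1, 1, 0], [0, 2, 2]])
        recs = match_events(gt, gt)
        assert all(r.best_iou == 1.0 for r in recs)

    def test_empty_prediction(self):
        gt = _lm([[1, 1], [2, 2]])
        recs = match_events(gt, _lm(np.zeros((2, 2))))
        assert all(r.best_iou == 0.0 and not r.overlapping_pred_labels_20pct for r in recs)

    def test_square_split_in_halves(self):
        gt = np.zeros((8, 8), dtype=np.int32)
        gt[1:7, 1:7] = 1                      # 6x6 square
        pred = np.zeros((8, 8), dtype=np.int32)
        pred[1:4, 1:7] = 1                    # top 3x6
        pred[4:7, 1:7] = 2                    # bottom 3x6
        (rec,) = match_events(_lm(gt), _lm(pred))
        assert rec.best_iou == pytest.approx(0.5)
        assert rec.overlapping_pred_labels_20pct == [1, 2]

    def test_random_maps_agree_with_enumeration(self, rng):
        for _ in range(25):
            gt = rng.integers(0, 4, size=(12, 12)).astype(np.int32)
            pred = rng.integers(0, 4, size=(12, 12)).astype(np.int32)
            want = brute_match(gt, pred)
            recs = {r.gt_label: r for r in match_events(_lm(gt), _lm(pred))}
            assert set(recs) == set(want)
            for g, (bi, bp, over) in want.items():
                assert recs[g].best_iou == pytest.approx(bi)
                assert recs[g].overlapping_pred_labels_20pct == over


class TestRecall:
    def test_worked_example(self):
        recs = [MatchRecord(1, 1, 0.55), MatchRecord(2, 2, 0.90)]
        cfg = ScoreConfig(iou_thresholds=[0.5, 0.6, 0.95])
        r = recall_curve(recs, cfg)
        assert r[0.5] == 1.0
        assert r[0.6] == 0.5
        assert r[0.95] == 0.0

    def test_all_perfect(self):
        recs = [MatchRecord(i, i, 1.0) for i in range(4)]
        assert set(recall_curve(recs).values()) == {1.0}

    def test_no_predictions(self):
        recs = [MatchRecord(1, None, 0.0)]
        assert set(recall_curve(recs).values()) == {0.0}

    def test_no_ground_truth_is_error(self):
        with pytest.raises(ValueError):
            recall_curve([])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_recall_non_increasing_in_threshold(self, ious):
        recs = [MatchRecord(i + 1, i + 1, v) for i, v in enumerate(ious)]
        curve = recall_curve(recs)
        vals = [curve[t] for t in sorted(curve)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestSplitFraction:
    def test_all_one_to_one(self):
        recs = [MatchRecord(1, 1, 0.9, [1]), MatchRecord(2, 2, 0.8, [2])]
        assert split_fraction(recs) == 0.0

    def test_one_split_one_matched(self):
        recs = [MatchRecord(1, 1, 0.5, [1, 2]), MatchRecord(2, 3, 0.9, [3])]
        assert split_fraction(recs) == 0.5

    def test_small_overlap_does_not_count(self):
        # second prediction covers only 10% of the GT: below the 20% rule
        gt = np.zeros((10, 10), dtype=np.int32)
        gt[0, :] = 1                          # 10 px
        pred = np.zeros((10, 10), dtype=np.int32)
        pred[0, :9] = 1
        pred[0, 9] = 2                        # 1 px = 10% of GT area
        (rec,) = match_events(_lm(gt), _lm(pred))
        assert rec.overlapping_pred_labels_20pct == [1]
        assert split_fraction([rec]) == 0.0

    def test_no_overlap_is_error(self):
        with pytest.raises(ValueError):
            split_fraction([MatchRecord(1, None, 0.0, [])])


class TestEdgeIntersection:
    def test_boundaries_avoiding_gt_score_zero(self):
        pred = np.zeros((10, 10), dtype=np.int32)
        pred[0:4, 0:4] = 1
        gt = np.zeros((10, 10), dtype=np.int32)
        gt[7:9, 7:9] = 1
        assert edge_intersection_score(_lm(pred), _lm(gt), "gt_area") == 0.0

    def test_bisecting_line_pixel_count(self):
        gt = np.zeros((10, 10), dtype=np.int32)
        gt[2:8, 2:8] = 1                      # 6x6 nucleus
        pred = np.zeros((10, 10), dtype=np.int32)
        pred[:, :5] = 1
        pred[:, 5:] = 2                       # vertical cut through the square
        # thick (two-sided) boundary: columns 4 and 5 inside the nucleus
        score = edge_intersection_score(_lm(pred), _lm(gt), "gt_area")
        assert score == pytest.approx(12 / 36)

    def test_empty_gt_is_error(self):
        with pytest.raises(ValueError):
            edge_intersection_score(_lm(np.ones((3, 3))), _lm(np.zeros((3, 3))))

    def test_interior_definition_ignores_grazing(self):
        gt = np.zeros((10, 10), dtype=np.int32)
        gt[2:8, 2:8] = 1
        pred = np.zeros((10, 10), dtype=np.int32)
        pred[:, :3] = 1
        pred[:, 3:] = 2                       # cut grazes the annotation edge col 2/3
        graze = edge_intersection_score(_lm(pred), _lm(gt), "gt_interior")
        full = edge_intersection_score(_lm(pred), _lm(gt), "gt_area")
        assert full > 0
        assert graze < full


class TestFragmentation:
    def test_all_one_to_one_zero_per_group(self):
        recs = [MatchRecord(1, 1, 0.9, [1]), MatchRecord(2, 2, 0.9, [2])]
        frag = fragmentation_by_group(recs, {1: "a", 2: "a"})
        assert frag == {"a": 0.0}

    def test_group_splitting_one_gt_is_one(self):
        recs = [MatchRecord(1, 1, 0.5, [1, 2])]
        frag = fragmentation_by_group(recs, {1: "g", 2: "g"})
        assert frag == {"g": 1.0}

    def test_group_without_overlap_missing(self):
        recs = [MatchRecord(1, 1, 0.9, [1])]
        frag = fragmentation_by_group(recs, {1: "a", 99: "b"})
        assert "b" not in frag


class TestPerfectPredictionFixedPoint:
    def test_prediction_equal_gt(self, rng):
        lab = np.zeros((20, 20), dtype=np.int32)
        lab[2:8, 2:8] = 1
        lab[12:18, 4:9] = 2
        lab[5:10, 12:18] = 3
        gt = _lm(lab)
        report = score_prediction(gt, gt, prediction_cells=gt,
                                  cell_groups={1: "x", 2: "x", 3: "y"})
        assert set(report.recall_by_threshold.values()) == {1.0}
        assert report.split_fraction == 0.0
        assert all(v == 0.0 for v in report.per_group_fragmentation.values())
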