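"""Evaluation metrics: matching, AP with brute-force oracle, F1 identities."""

import numpy as np
import pytest

from greenfruit.boxes import DetectionBox, box_iou
from greenfruit.metrics import (
    MatchResult,
    average_precision,
    evaluate_detections,
    f1_score,
    match_detections,
    summarize_metrics,
)


def det(conf, x1, y1, x2, y2, cat=0):
    return DetectionBox(cat, conf, x1, y1, x2, y2)


# ----------------------------------------------------------------------------
# independent oracle: re-match from scratch at every confidence threshold and
# integrate the monotone precision envelope over recall
# ----------------------------------------------------------------------------

def _greedy_counts(dets, gts, iou_thr):
    """TP count of a detection subset against one image's gts (greedy by conf)."""
    taken = [False] * len(gts)
    tp = 0
    for d in sorted(dets, key=lambda d: -d.confidence):
        best, best_j = 0.0, -1
        for j, g in enumerate(gts):
            if taken[j]:
                continue
            iou = box_iou(d.corners, g)
            if iou > best:
                best, best_j = iou, j
        if best_j >= 0 and best > iou_thr:
            taken[best_j] = True
            tp += 1
    return tp


def brute_force_ap(dets_per_image, gts_per_image, iou_thr=0.5):
    """AP via explicit confidence-threshold sweep (independent of the module)."""
    n_gt = sum(len(g) for g in gts_per_image)
    confs = sorted({d.confidence for dets in dets_per_image for d in dets}, reverse=True)
    points = []  # (recall, precision) at each threshold
    for t in confs:
        tp = fp = 0
        for dets, gts in zip(dets_per_image, gts_per_image):
            keep = [d for d in dets if d.confidence >= t]
            tp_i = _greedy_counts(keep, gts, iou_thr)
            tp += tp_i
            fp += len(keep) - tp_i
        points.append((tp / n_gt, tp / max(tp + fp, 1e-16)))
    ap = 0.0
    prev_r = 0.0
    for k, (r, _p) in enumerate(points):
        p_interp = max(p for (_r2, p) in points[k:])  # envelope: best p at recall >= r
        ap += (r - prev_r) * p_interp
        prev_r = r
    return ap


def random_instance(rng, max_boxes=50, conf_pool=None):
    """One random image: gts and detections.

    ``conf_pool`` (a mutable list) supplies globally unique confidences so
    the pooled precision-recall curve has no cross-image ties.
    """
    n_gt = int(rng.integers(0, max_boxes // 2 + 1))
    n_det = int(rng.integers(0, max_boxes // 2 + 1))
    gts = []
    for _ in range(n_gt):
        x, y = rng.uniform(0, 80, size=2)
        w, h = rng.uniform(5, 20, size=2)
        gts.append((x, y, x + w, y + h))
    if conf_pool is None:
        conf_pool = list(rng.permutation(np.linspace(0.02, 0.98, n_det))) if n_det else []
    dets = []
    for _ in range(min(n_det, len(conf_pool))):
        c = conf_pool.pop()
        if n_gt and rng.uniform() < 0.6:  # perturbation of a gt box
            x1, y1, x2, y2 = gts[int(rng.integers(n_gt))]
            dx, dy = rng.uniform(-6, 6, size=2)
            dets.append(det(float(c), x1 + dx, y1 + dy, x2 + dx, y2 + dy))
        else:
            x, y = rng.uniform(0, 80, size=2)
            w, h = rng.uniform(5, 20, size=2)
            dets.append(det(float(c), x, y, x + w, y + h))
    return dets, gts


class TestMatching:
    def test_perfect_detections(self):
        gts = [(0, 0, 10, 10), (20, 20, 30, 30)]
        dets = [det(0.9, 0, 0, 10, 10), det(0.8, 20, 20, 30, 30)]
        m = match_detections(dets, gts)
        assert (m.n_tp, m.n_fp, m.n_fn) == (2, 0, 0)

    def test_low_iou_is_both_fp_and_fn(self):
        """A detection at IoU 0.4 against the only gt counts as FP, gt as FN."""
        gt = (0.0, 0.0, 10.0, 10.0)
        d = det(0.9, 3.75, 0, 13.75, 10)  # IoU = 62.5 / 137.5 ~ 0.4545... adjust
        iou = box_iou(d.corners, gt)
        assert iou < 0.5
        m = match_detections([d], [gt])
        assert (m.n_tp, m.n_fp, m.n_fn) == (0, 1, 1)

    def test_iou_exactly_half_is_fp(self):
        """Strict inequality: IoU exactly 0.5 does not make a TP."""
        gt = (0.0, 0.0, 2.0, 2.0)
        d = det(0.9, 0.0, 0.0, 2.0, 1.0)  # inter 2, union 4 -> IoU 0.5
        assert box_iou(d.corners, gt) == 0.5
        m = match_detections([d], [gt], iou_threshold=0.5)
        assert (m.n_tp, m.n_fp) == (0, 1)

    def test_double_detection_greedy(self):
        gt = [(0, 0, 10, 10)]
        dets = [det(0.9, 0, 0, 10, 10), det(0.8, 0.5, 0.5, 10.5, 10.5)]
        m = match_detections(dets, gt)
        assert m.tp_flags.tolist() == [True, False]

    def test_conservation_on_random_instances(self, rng):
        for _ in range(30):
            dets, gts = random_instance(rng, max_boxes=20)
            m = match_detections(dets, gts)
            assert m.n_tp + m.n_fp == len(dets)
            assert m.n_tp + m.n_fn == len(gts)


class TestAveragePrecision:
    def test_full_precision_full_recall(self):
        m = MatchResult(np.array([True, True]), np.array([0.9, 0.8]), np.array([0, 1]), 2)
        ap, _, _ = average_precision([m])
        assert ap == pytest.approx(1.0)

    def test_three_detection_example_by_hand(self):
        """TP(0.9), FP(0.8), TP(0.7) on 2 gts: AP = 0.5 + 0.5 * 2/3 = 0.8333."""
        m = MatchResult(np.array([True, False, True]), np.array([0.9, 0.8, 0.7]),
                        np.array([0, -1, 1]), 2)
        ap, _, _ = average_precision([m])
        assert ap == pytest.approx(5 / 6, abs=1e-12)

    def test_no_detections(self):
        m = MatchResult(np.zeros(0, bool), np.zeros(0), np.zeros(0, int), 3)
        ap, _, _ = average_precision([m])
        assert ap == 0.0

    def test_zero_gt_undefined(self):
        m = MatchResult(np.array([False]), np.array([0.5]), np.array([-1]), 0)
        with pytest.raises(ValueError):
            average_precision([m])

    def test_monotone_confidence_transform_invariance(self, rng):
        dets, gts = random_instance(rng, max_boxes=30)
        if not gts or not dets:
            dets = [det(0.6, 0, 0, 10, 10)]
            gts = [(0, 0, 10, 10)]
        m1 = match_detections(dets, gts)
        squashed = [det(d.confidence**3, *d.corners) for d in dets]  # order-preserving
        m2 = match_detections(squashed, gts)
        ap1, _, _ = average_precision([m1])
        ap2, _, _ = average_precision([m2])
        assert ap1 == pytest.approx(ap2, abs=1e-12)

    def test_relabeling_tp_as_fp_never_raises_ap(self, rng):
        for _ in range(10):
            dets, gts = random_instance(rng, max_boxes=20)
            m = match_detections(dets, gts)
            if not m.tp_flags.any():
                continue
            ap, _, _ = average_precision([m])
            worse = MatchResult(m.tp_flags.copy(), m.confidences, m.matched_gt, m.n_gt)
            worse.tp_flags[np.argmax(worse.tp_flags)] = False
            ap2, _, _ = average_precision([worse])
            assert ap2 <= ap + 1e-12

    def test_matches_brute_force_sweep(self, rng):
        """Module AP equals the from-scratch threshold-sweep oracle to 1e-9."""
        for _ in range(25):
            pool = list(rng.permutation(np.linspace(0.02, 0.98, 64)))
            images = [random_instance(rng, max_boxes=16, conf_pool=pool) for _ in range(3)]
            gts_all = [g for _, g in images]
            if sum(len(g) for g in gts_all) == 0:
                continue
            matches = [match_detections(d, g) for d, g in images]
            ap, _, _ = average_precision(matches)
            oracle = brute_force_ap([d for d, _ in images], gts_all)
            assert ap == pytest.approx(oracle, abs=1e-9)


class TestSummaries:
    @pytest.mark.parametrize(
        "p,r,expected",
        [(86.3, 76.3, 81.0), (89.0, 63.0, 73.8), (95.1, 93.4, 94.2)],
    )
    def test_f1_identity_on_reported_operating_points(self, p, r, expected):
        assert round(f1_score(p, r), 1) == expected

    def test_f1_equals_p_when_p_equals_r(self):
        assert f1_score(0.7, 0.7) == pytest.approx(0.7)

    def test_f1_zero_recall(self):
        assert f1_score(0.9, 0.0) == 0.0

    def test_report_at_max_f1_point(self):
        m = MatchResult(np.array([True, False, True]), np.array([0.9, 0.8, 0.7]),
                        np.array([0, -1, 1]), 2)
        report = summarize_metrics({0: [m]})
        # candidate F1s along the curve: 2/3, 1/2, 4/5 -> max at the end
        assert report.f1[0] == pytest.approx(0.8)
        assert report.precision[0] == pytest.approx(2 / 3)
        assert report.recall[0] == pytest.approx(1.0)
        assert report.map50 == pytest.approx(report.ap[0])


class TestEvaluateDataset:
    def test_ground_truth_as_predictions_is_perfect(self, tiny_scenes):
        dets, gts, sizes = [], [], []
        for scene in tiny_scenes:
            w, h = scene.size
            from greenfruit.boxes import bbox_to_corners

            dets.append([det(1.0, *bbox_to_corners(b, (w, h))) for b in scene.boxes])
            gts.append(scene.boxes)
            sizes.append((w, h))
        report = evaluate_detections(dets, gts, sizes)
        assert report.map50 == pytest.approx(1.0)
        assert report.f1[0] == pytest.approx(1.0)

    def test_empty_predictions(self, tiny_scenes):
        gts = [s.boxes for s in tiny_scenes]
        sizes = [s.size for s in tiny_scenes]
        report = evaluate_detections([[] for _ in tiny_scenes], gts, sizes)
        assert report.map50 == 0.0
        assert report.recall[0] == 0.0
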