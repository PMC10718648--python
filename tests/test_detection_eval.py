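"""Detection metrics against independent brute-force oracles."""

import numpy as np
import pytest

from conftest import random_boxset
from lodgekit.detection_eval import (
    average_precision,
    confidence_filter,
    confusion_matrix,
    evaluate_detections,
    iou,
    map_range,
    match_detections,
    mean_ap,
    nms,
    precision_recall_f1,
)
from lodgekit.io_formats import Box, BoxSet


# ---------------------------------------------------------------- oracles

def iou_oracle(a, b):
    ix = max(0.0, min(a.x_max, b.x_max) - max(a.x_min, b.x_min))
    iy = max(0.0, min(a.y_max, b.y_max) - max(a.y_min, b.y_min))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def nms_oracle(boxset, iou_threshold, class_aware=True):
    """Set-based NMS: repeatedly pop the best remaining, discard overlaps."""
    remaining = list(range(len(boxset.boxes)))
    kept = []
    while remaining:
        best = min(remaining, key=lambda i: (-boxset.boxes[i].confidence, i))
        kept.append(best)
        remaining.remove(best)
        drop = []
        for j in remaining:
            same = boxset.boxes[j].class_id == boxset.boxes[best].class_id
            if (not class_aware or same) and \
                    iou_oracle(boxset.boxes[best], boxset.boxes[j]) > iou_threshold:
                drop.append(j)
        remaining = [j for j in remaining if j not in drop]
    return sorted(kept)


def match_oracle(dets, gts, iou_threshold):
    """Greedy matching re-derived with explicit candidate enumeration."""
    order = sorted(range(len(dets.boxes)),
                   key=lambda i: (-dets.boxes[i].confidence, i))
    taken = set()
    pairs = []
    for i in order:
        candidates = [(iou_oracle(dets.boxes[i], g), -j, j)
                      for j, g in enumerate(gts.boxes)
                      if j not in taken and
                      iou_oracle(dets.boxes[i], g) >= iou_threshold]
        if candidates:
            _, _, j = max(candidates)
            taken.add(j)
            pairs.append((i, j))
    return pairs


def ap_oracle(dets, gts, class_id, iou_threshold):
    """Threshold-enumeration AP: PR point per distinct confidence, then the
    monotone-envelope integral over recall change-points."""
    d = {img: s.filter_class(class_id) for img, s in dets.items()}
    g = {img: s.filter_class(class_id) for img, s in gts.items()}
    n_gt = sum(len(s) for s in g.values())
    confs = sorted({b.confidence for s in d.values() for b in s}, reverse=True)
    if n_gt == 0:
        raise ValueError("no ground truth")
    points = []
    for t in confs:
        tp = fp = 0
        for img in sorted(set(d) | set(g)):
            dd = d.get(img, BoxSet(img, 1, 1, []))
            gg = g.get(img, BoxSet(img, 1, 1, []))
            kept = BoxSet(dd.image_id, dd.image_width, dd.image_height,
                          [b for b in dd if b.confidence >= t])
            pairs = match_oracle(kept, gg, iou_threshold)
            tp += len(pairs)
            fp += len(kept) - len(pairs)
        points.append((tp / (tp + fp) if tp + fp else 0.0, tp / n_gt))
    mrec = [0.0] + [r for _, r in points] + [1.0]
    mpre = [1.0] + [p for p, _ in points] + [0.0]
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    ap = 0.0
    for i in range(len(mrec) - 1):
        if mrec[i + 1] != mrec[i]:
            ap += (mrec[i + 1] - mrec[i]) * mpre[i + 1]
    return ap


def distinct_conf_boxset(rng, image_id, **kw):
    """Random BoxSet with strictly distinct confidences (ties tested apart)."""
    bs = random_boxset(rng, image_id=image_id, **kw)
    confs = rng.permutation(np.linspace(0.05, 0.95, len(bs.boxes)))
    boxes = [Box(b.class_id, b.x_min, b.y_min, b.x_max, b.y_max, float(c))
             for b, c in zip(bs.boxes, confs)]
    return BoxSet(bs.image_id, bs.image_width, bs.image_height, boxes)


def random_scenario(rng, n_images=None, max_classes=3):
    """Random dataset with globally distinct confidences.

    The per-detection PR sweep and the per-threshold oracle sweep coincide
    only when no two detections share a confidence; tie handling is covered
    separately by the determinism/invariance tests.
    """
    n_images = n_images or int(rng.integers(1, 7))
    gts, dets = {}, {}
    for i in range(n_images):
        img = f"img{i}"
        gts[img] = random_boxset(rng, image_id=img, with_confidence=False,
                                 max_classes=max_classes)
        dets[img] = random_boxset(rng, image_id=img, max_classes=max_classes)
    all_boxes = [(img, i) for img, s in dets.items()
                 for i in range(len(s.boxes))]
    confs = rng.permutation(np.linspace(0.02, 0.98, len(all_boxes)))
    for (img, i), c in zip(all_boxes, confs):
        b = dets[img].boxes[i]
        dets[img].boxes[i] = Box(b.class_id, b.x_min, b.y_min, b.x_max,
                                 b.y_max, float(c))
    return dets, gts


# ----------------------------------------------------------------- tests

class TestIoU:
    def test_identical_boxes(self):
        b = Box(1, 0, 0, 10, 10)
        assert iou(b, b) == 1.0

    def test_disjoint_boxes(self):
        assert iou(Box(1, 0, 0, 10, 10), Box(1, 20, 20, 30, 30)) == 0.0

    def test_half_overlap_hand_value(self):
        assert iou(Box(1, 0, 0, 10, 10), Box(1, 5, 0, 15, 10)) == pytest.approx(1 / 3)

    def test_symmetry_random(self):
        rng = np.random.default_rng(0)
        bs = random_boxset(rng, n=12)
        for a in bs:
            for b in bs:
                assert iou(a, b) == iou(b, a)
                assert (iou(a, b) == 1.0) == (
                    (a.x_min, a.y_min, a.x_max, a.y_max)
                    == (b.x_min, b.y_min, b.x_max, b.y_max))


class TestConfidenceFilter:
    def test_threshold_zero_is_identity(self):
        rng = np.random.default_rng(1)
        bs = random_boxset(rng, n=8)
        assert confidence_filter(bs, 0.0).boxes == bs.boxes

    def test_threshold_one_empties(self):
        rng = np.random.default_rng(2)
        bs = random_boxset(rng, n=8)
        assert len(confidence_filter(bs, 1.0)) == 0

    def test_kept_count(self):
        boxes = [Box(1, 0, 0, 10, 10, c) for c in (0.3, 0.6, 0.9)]
        bs = BoxSet("x", 100, 100, boxes)
        assert len(confidence_filter(bs, 0.5)) == 2

    def test_missing_confidence_rejected(self):
        bs = BoxSet("x", 100, 100, [Box(1, 0, 0, 10, 10)])
        with pytest.raises(ValueError, match="confidence"):
            confidence_filter(bs, 0.5)


class TestNMS:
    def test_duplicate_suppressed(self):
        boxes = [Box(1, 0, 0, 10, 10, 0.9), Box(1, 0, 0, 10, 10, 0.8)]
        out = nms(BoxSet("x", 100, 100, boxes))
        assert [b.confidence for b in out] == [0.9]

    def test_disjoint_survive(self):
        boxes = [Box(1, 0, 0, 10, 10, 0.9), Box(1, 50, 50, 60, 60, 0.8)]
        assert len(nms(BoxSet("x", 100, 100, boxes))) == 2

    def test_cross_class_never_suppressed_when_class_aware(self):
        boxes = [Box(1, 0, 0, 10, 10, 0.9), Box(2, 0, 0, 10, 10, 0.8)]
        assert len(nms(BoxSet("x", 100, 100, boxes))) == 2
        assert len(nms(BoxSet("x", 100, 100, boxes), class_aware=False)) == 1

    @pytest.mark.parametrize("class_aware", [True, False])
    def test_matches_set_based_oracle(self, class_aware):
        rng = np.random.default_rng(3)
        for _ in range(50):
            bs = distinct_conf_boxset(rng, "x", n=10, max_classes=3)
            got = nms(bs, 0.45, class_aware=class_aware)
            expected = nms_oracle(bs, 0.45, class_aware=class_aware)
            assert [bs.boxes[i] for i in expected] == got.boxes


class TestMatching:
    def test_exact_hit(self):
        gt = BoxSet("x", 100, 100, [Box(1, 0, 0, 10, 10)])
        det = BoxSet("x", 100, 100, [Box(1, 0, 0, 10, 10, 0.9)])
        out = match_detections(det, gt, 0.5)
        assert (out.tp, out.fp, out.fn) == (1, 0, 0)
        assert out.pairs == [(0, 0, 1.0)]

    def test_detection_without_truth_is_fp(self):
        det = BoxSet("x", 100, 100, [Box(1, 0, 0, 10, 10, 0.9)])
        out = match_detections(det, BoxSet("x", 100, 100, []), 0.5)
        assert (out.tp, out.fp, out.fn) == (0, 1, 0)

    def test_mixed_classes_rejected(self):
        det = BoxSet("x", 100, 100, [Box(1, 0, 0, 10, 10, 0.9)])
        gt = BoxSet("x", 100, 100, [Box(2, 0, 0, 10, 10)])
        with pytest.raises(ValueError, match="single class"):
            match_detections(det, gt, 0.5)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            det = distinct_conf_boxset(rng, "x", n=5, max_classes=1)
            gt = random_boxset(rng, n=4, with_confidence=False, max_classes=1)
            out = match_detections(det, gt, 0.3)
            pairs = match_oracle(det, gt, 0.3)
            assert out.tp == len(pairs)
            assert [(i, j) for i, j, _ in out.pairs] == pairs


class TestPrecisionRecallF1:
    @pytest.mark.parametrize(
        "tp,fp,fn,expected",
        [
            (8, 2, 0, (0.8, 1.0, 8 / 9)),
            (0, 0, 5, (0.0, 0.0, 0.0)),
            (5, 5, 15, (0.5, 0.25, 1 / 3)),
            (0, 0, 0, (0.0, 0.0, 0.0)),
        ],
    )
    def test_hand_values_and_conventions(self, tp, fp, fn, expected):
        assert precision_recall_f1(tp, fp, fn) == pytest.approx(expected)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            precision_recall_f1(-1, 0, 0)


class TestAveragePrecision:
    def _perfect(self, rng, n_images=3):
        gts, dets = {}, {}
        for i in range(n_images):
            img = f"img{i}"
            g = random_boxset(rng, image_id=img, n=4, with_confidence=False,
                              max_classes=1)
            gts[img] = g
            dets[img] = BoxSet(img, g.image_width, g.image_height,
                               [Box(b.class_id, b.x_min, b.y_min, b.x_max,
                                    b.y_max, 0.9) for b in g])
        return dets, gts

    def test_perfect_detections_give_ap_one(self):
        dets, gts = self._perfect(np.random.default_rng(5))
        assert average_precision(dets, gts, 1, 0.5) == 1.0

    def test_zero_detections_give_ap_zero(self):
        rng = np.random.default_rng(6)
        gts = {"a": random_boxset(rng, image_id="a", n=3,
                                  with_confidence=False, max_classes=1)}
        dets = {"a": BoxSet("a", 200, 160, [])}
        assert average_precision(dets, gts, 1, 0.5) == 0.0

    def test_known_sequence_matches_sweep_oracle(self):
        """3 GTs, detections (0.9 T)(0.8 F)(0.7 T)(0.6 T)."""
        gts = {"a": BoxSet("a", 200, 200, [Box(1, 0, 0, 20, 20),
                                           Box(1, 50, 50, 70, 70),
                                           Box(1, 100, 100, 120, 120)])}
        dets = {"a": BoxSet("a", 200, 200, [
            Box(1, 0, 0, 20, 20, 0.9),        # hit
            Box(1, 150, 0, 170, 20, 0.8),     # miss
            Box(1, 50, 50, 70, 70, 0.7),      # hit
            Box(1, 100, 100, 120, 120, 0.6),  # hit
        ])}
        got = average_precision(dets, gts, 1, 0.5)
        assert got == pytest.approx(ap_oracle(dets, gts, 1, 0.5), abs=1e-12)
        # by hand: envelope 1 on recall [0,1/3], 0.75 on (1/3, 1]
        assert got == pytest.approx(1 / 3 + 0.75 * 2 / 3, abs=1e-12)

    def test_random_scenarios_match_sweep_oracle(self):
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(60):
            dets, gts = random_scenario(rng)
            for c in sorted({b.class_id for s in gts.values() for b in s}):
                assert average_precision(dets, gts, c, 0.5) == pytest.approx(
                    ap_oracle(dets, gts, c, 0.5), abs=1e-9)
                checked += 1
        assert checked > 50

    def test_class_without_ground_truth_rejected(self):
        rng = np.random.default_rng(8)
        dets, gts = random_scenario(rng, max_classes=1)
        with pytest.raises(ValueError, match="no ground truths"):
            average_precision(dets, gts, 9, 0.5)

    def test_invariant_to_image_and_input_order(self):
        rng = np.random.default_rng(9)
        dets, gts = random_scenario(rng, n_images=4)
        base = mean_ap(dets, gts, 0.5)
        shuffled_imgs = dict(reversed(list(dets.items())))
        assert mean_ap(shuffled_imgs, gts, 0.5) == base
        reversed_boxes = {
            img: BoxSet(s.image_id, s.image_width, s.image_height,
                        list(reversed(s.boxes)))
            for img, s in dets.items()}
        assert mean_ap(reversed_boxes, gts, 0.5) == pytest.approx(base, abs=1e-12)


class TestMeanAP:
    def test_mean_of_two_classes(self):
        gts = {"a": BoxSet("a", 200, 200, [Box(1, 0, 0, 20, 20),
                                           Box(2, 50, 50, 70, 70)])}
        dets = {"a": BoxSet("a", 200, 200, [Box(1, 0, 0, 20, 20, 0.9),
                                            Box(2, 150, 150, 170, 170, 0.8)])}
        assert mean_ap(dets, gts, 0.5) == pytest.approx(0.5)

    def test_perfect_nine_classes(self):
        gts, dets = {}, {}
        for c in range(1, 10):
            img = f"img{c}"
            g = Box(c, 10, 10, 50, 50)
            gts[img] = BoxSet(img, 100, 100, [g])
            dets[img] = BoxSet(img, 100, 100,
                               [Box(c, 10, 10, 50, 50, 0.9)])
        assert mean_ap(dets, gts, 0.5) == 1.0

    def test_compositional_equality_with_per_class_aps(self):
        rng = np.random.default_rng(10)
        dets, gts = random_scenario(rng)
        classes = sorted({b.class_id for s in gts.values() for b in s})
        expected = np.mean([average_precision(dets, gts, c, 0.5)
                            for c in classes])
        assert mean_ap(dets, gts, 0.5) == pytest.approx(expected, abs=1e-12)

    def test_no_ground_truth_rejected(self):
        with pytest.raises(ValueError, match="no ground-truth"):
            mean_ap({}, {"a": BoxSet("a", 10, 10, [])}, 0.5)


class TestMapRange:
    def test_ten_thresholds(self):
        from lodgekit.detection_eval import IOU_RANGE_THRESHOLDS

        assert len(IOU_RANGE_THRESHOLDS) == 10
        assert IOU_RANGE_THRESHOLDS[0] == 0.5
        assert IOU_RANGE_THRESHOLDS[-1] == 0.95

    def test_perfect_detections_mean_one(self):
        gts = {"a": BoxSet("a", 100, 100, [Box(1, 10, 10, 60, 60)])}
        dets = {"a": BoxSet("a", 100, 100, [Box(1, 10, 10, 60, 60, 0.9)])}
        assert map_range(dets, gts) == 1.0

    def test_jittered_boxes_penalised_at_high_iou(self):
        # IoU with truth ~ 0.7: counted at 0.5 but not at 0.75+
        gts = {"a": BoxSet("a", 200, 200, [Box(1, 0, 0, 100, 100)])}
        dets = {"a": BoxSet("a", 200, 200, [Box(1, 0, 0, 100, 84, 0.9)])}
        assert iou(gts["a"].boxes[0], dets["a"].boxes[0]) == pytest.approx(0.84)
        m50 = mean_ap(dets, gts, 0.5)
        assert m50 > map_range(dets, gts)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(11)
        dets, gts = random_scenario(rng)
        values = [mean_ap(dets, gts, t)
                  for t in np.arange(0.5, 0.96, 0.05)]
        assert all(b <= a + 1e-12 for a, b in zip(values, values[1:]))


class TestConfusionMatrix:
    def test_perfect_detections_diagonal(self):
        gts, dets = {}, {}
        for c in (1, 4, 9):
            img = f"i{c}"
            gts[img] = BoxSet(img, 100, 100, [Box(c, 10, 10, 50, 50)])
            dets[img] = BoxSet(img, 100, 100, [Box(c, 10, 10, 50, 50, 0.9)])
        m = confusion_matrix(dets, gts)
        assert m.sum() == 3
        for c in (1, 4, 9):
            assert m[c - 1, c - 1] == 1

    def test_zero_detections_background_column(self):
        gts = {"a": BoxSet("a", 100, 100, [Box(2, 0, 0, 10, 10),
                                           Box(5, 20, 20, 40, 40)])}
        m = confusion_matrix({"a": BoxSet("a", 100, 100, [])}, gts)
        assert m[1, 9] == 1 and m[4, 9] == 1
        assert m.sum() == 2

    def test_cross_class_confusion_visible(self):
        gts = {"a": BoxSet("a", 100, 100, [Box(3, 10, 10, 50, 50)])}
        dets = {"a": BoxSet("a", 100, 100, [Box(7, 10, 10, 50, 50, 0.9)])}
        m = confusion_matrix(dets, gts)
        assert m[2, 6] == 1

    def test_row_sums_conserve_ground_truth(self):
        rng = np.random.default_rng(12)
        dets, gts = random_scenario(rng, max_classes=9)
        m = confusion_matrix(dets, gts)
        for c in range(1, 10):
            n_gt = sum(1 for s in gts.values() for b in s if b.class_id == c)
            assert m[c - 1, :].sum() == n_gt


class TestEvaluateDetections:
    def test_report_is_self_consistent(self):
        rng = np.random.default_rng(13)
        dets, gts = random_scenario(rng)
        report = evaluate_detections(dets, gts)
        classes = sorted({b.class_id for s in gts.values() for b in s})
        assert sorted(report.per_class_ap) == classes
        assert report.class_count == len(classes)
        assert report.map50 == pytest.approx(
            np.mean(list(report.per_class_ap.values())), abs=1e-12)
        assert report.map50_95 <= report.map50 + 1e-12
        assert report.confusion.shape == (10, 10)
        d = report.to_dict()
        assert set(d) == {"per_class_ap", "map50", "map50_95", "f1_curve",
                          "confusion", "counts", "class_count"}
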