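"""Object-detection post-processing and evaluation metrics.

Implements the standard detection scoring stack for severity-classed
bounding boxes: IoU, confidence thresholding, greedy class-aware NMS,
greedy confidence-ordered matching, precision / recall / F1, per-class
average precision with all-point (continuous) interpolation, mAP at a fixed
IoU threshold and averaged over IoU 0.50:0.95, and a detection confusion
matrix with a background row/column for unmatched boxes.

Every tie is broken deterministically (confidence ties by input order, IoU
ties by lower ground-truth index), so all results are bit-reproducible and
invariant to image ordering.  Classes absent from the ground truth are
excluded from the mAP mean rather than counted as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import Box, BoxSet

__all__ = [
    "MatchOutcome",
    "PRCurve",
    "EvalReport",
    "iou",
    "confidence_filter",
    "nms",
    "match_detections",
    "precision_recall_f1",
    "pr_curve",
    "average_precision",
    "mean_ap",
    "map_range",
    "confusion_matrix",
    "evaluate_detections",
    "IOU_RANGE_THRESHOLDS",
]

#: the ten IoU thresholds 0.50, 0.55, ..., 0.95
IOU_RANGE_THRESHOLDS: tuple[float, ...] = tuple(
    round(0.5 + 0.05 * i, 2) for i in range(10)
)


@dataclass
class MatchOutcome:
    """Counts and matched pairs from greedy detection-to-truth matching."""

    tp: int
    fp: int
    fn: int
    #: (detection index, ground-truth index, IoU) per matched pair
    pairs: list[tuple[int, int, float]] = field(default_factory=list)


@dataclass
class PRCurve:
    """Precision-recall points swept over detection confidences.

    ``envelope`` is the monotonically non-increasing precision used for the
    all-point AP integral, aligned with ``recall``.
    """

    confidence: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    envelope: np.ndarray
    ap: float


@dataclass
class EvalReport:
    """Full evaluation summary over a dataset."""

    per_class_ap: dict[int, float]
    map50: float
    map50_95: float
    f1_curve: list[tuple[float, float]]
    confusion: np.ndarray
    counts: dict[int, MatchOutcome]
    class_count: int

    def to_dict(self) -> dict:
        return {
            "per_class_ap": {str(k): v for k, v in self.per_class_ap.items()},
            "map50": self.map50,
            "map50_95": self.map50_95,
            "f1_curve": [[c, f] for c, f in self.f1_curve],
            "confusion": self.confusion.tolist(),
            "counts": {
                str(k): {"tp": m.tp, "fp": m.fp, "fn": m.fn}
                for k, m in self.counts.items()
            },
            "class_count": self.class_count,
        }


def iou(a: Box, b: Box) -> float:
    """Jaccard overlap of two half-open boxes: |a∩b| / |a∪b|."""
    if a.area <= 0 or b.area <= 0:
        raise ValueError("degenerate zero-area box")
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def _require_confidences(boxes: Iterable[Box]) -> None:
    for b in boxes:
        if b.confidence is None:
            raise ValueError(f"detection {b} is missing a confidence")


def confidence_filter(detections: BoxSet, threshold: float) -> BoxSet:
    """Keep detections scoring at least ``threshold``; order preserved."""
    _require_confidences(detections)
    return BoxSet(detections.image_id, detections.image_width,
                  detections.image_height,
                  [b for b in detections if b.confidence >= threshold])


def _by_confidence(boxes: Sequence[Box]) -> list[int]:
    """Indices sorted by descending confidence, ties by input order."""
    return sorted(range(len(boxes)), key=lambda i: -boxes[i].confidence)


def nms(detections: BoxSet, iou_threshold: float = 0.45,
        class_aware: bool = True) -> BoxSet:
    """Greedy non-maximum suppression.

    Boxes are visited in descending confidence; each kept box suppresses
    remaining boxes (of the same class when ``class_aware``) overlapping it
    with IoU strictly above ``iou_threshold``.
    """
    _require_confidences(detections)
    boxes = detections.boxes
    order = _by_confidence(boxes)
    suppressed = [False] * len(boxes)
    keep: list[int] = []
    for pos, i in enumerate(order):
        if suppressed[i]:
            continue
        keep.append(i)
        for j in order[pos + 1:]:
            if suppressed[j]:
                continue
            if class_aware and boxes[j].class_id != boxes[i].class_id:
                continue
            if iou(boxes[i], boxes[j]) > iou_threshold:
                suppressed[j] = True
    keep.sort()  # preserve input order among survivors
    return BoxSet(detections.image_id, detections.image_width,
                  detections.image_height, [boxes[i] for i in keep])


def match_detections(dets: BoxSet, gts: BoxSet,
                     iou_threshold: float = 0.5) -> MatchOutcome:
    """Greedily match single-class detections to ground truths.

    Detections are visited in descending confidence; each claims the still
    unmatched ground truth of highest IoU at or above the threshold (IoU
    ties resolved toward the lower ground-truth index).  Unmatched
    detections count as false positives, unmatched truths as false
    negatives.
    """
    classes = {b.class_id for b in dets} | {b.class_id for b in gts}
    if len(classes) > 1:
        raise ValueError(f"match_detections expects a single class, got {sorted(classes)}")
    _require_confidences(dets)
    gt_taken = [False] * len(gts)
    pairs: list[tuple[int, int, float]] = []
    for i in _by_confidence(dets.boxes):
        best_j, best_iou = -1, 0.0
        for j, g in enumerate(gts.boxes):
            if gt_taken[j]:
                continue
            v = iou(dets.boxes[i], g)
            if v >= iou_threshold and v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            gt_taken[best_j] = True
            pairs.append((i, best_j, best_iou))
    tp = len(pairs)
    return MatchOutcome(tp, len(dets) - tp, len(gts) - tp, pairs)


def precision_recall_f1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall and F1 with the zero-denominator conventions.

    P = TP/(TP+FP) (0 when no detections), R = TP/(TP+FN) (0 when no
    truths), F1 = 2PR/(P+R) (0 when both vanish).
    """
    if tp < 0 or fp < 0 or fn < 0:
        raise ValueError("counts must be nonnegative")
    p = tp / (tp + fp) if tp + fp > 0 else 0.0
    r = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return p, r, f1


def _class_labels(dets: Mapping[str, BoxSet], gts: Mapping[str, BoxSet],
                  class_id: int, iou_threshold: float
                  ) -> tuple[list[tuple[float, str, int, bool]], int]:
    """TP/FP-label every detection of one class across the dataset.

    Returns ``(records, n_gt)`` where each record is
    ``(confidence, image_id, input index, is_tp)``.
    """
    records: list[tuple[float, str, int, bool]] = []
    n_gt = 0
    for img in sorted(set(dets) | set(gts)):
        d = dets.get(img)
        g = gts.get(img)
        d_cls = d.filter_class(class_id) if d is not None else None
        g_cls = g.filter_class(class_id) if g is not None else \
            BoxSet(img, 1, 1, [])
        n_gt += len(g_cls)
        if d_cls is None or len(d_cls) == 0:
            continue
        outcome = match_detections(d_cls, g_cls, iou_threshold)
        tp_idx = {i for i, _, _ in outcome.pairs}
        for i, b in enumerate(d_cls.boxes):
            records.append((b.confidence, img, i, i in tp_idx))
    return records, n_gt


def pr_curve(dets: Mapping[str, BoxSet], gts: Mapping[str, BoxSet],
             class_id: int, iou_threshold: float = 0.5) -> PRCurve:
    """Dataset-level PR curve and AP for one class.

    Detections are swept in descending confidence (ties by image id, then
    input order); AP integrates the monotone precision envelope over all
    recall change-points (all-point interpolation).
    """
    records, n_gt = _class_labels(dets, gts, class_id, iou_threshold)
    if n_gt == 0:
        raise ValueError(f"class {class_id} has no ground truths; AP undefined")
    records.sort(key=lambda r: (-r[0], r[1], r[2]))
    conf = np.array([r[0] for r in records], dtype=np.float64)
    tp = np.cumsum([1.0 if r[3] else 0.0 for r in records])
    fp = np.cumsum([0.0 if r[3] else 1.0 for r in records])
    if len(records) == 0:
        return PRCurve(np.empty(0), np.empty(0), np.empty(0), np.empty(0), 0.0)
    precision = tp / (tp + fp)
    recall = tp / n_gt
    # sentinels: recall 0 at precision 1, recall 1 at precision 0
    mrec = np.concatenate(([0.0], recall, [1.0]))
    mpre = np.concatenate(([1.0], precision, [0.0]))
    env = np.flip(np.maximum.accumulate(np.flip(mpre)))
    change = np.nonzero(mrec[1:] != mrec[:-1])[0]
    ap = float(np.sum((mrec[change + 1] - mrec[change]) * env[change + 1]))
    return PRCurve(conf, precision, recall, env[1:-1], ap)


def average_precision(dets: Mapping[str, BoxSet], gts: Mapping[str, BoxSet],
                      class_id: int, iou_threshold: float = 0.5) -> float:
    """All-point-interpolated average precision for one class."""
    return pr_curve(dets, gts, class_id, iou_threshold).ap


def _gt_classes(gts: Mapping[str, BoxSet]) -> list[int]:
    present = sorted({b.class_id for s in gts.values() for b in s})
    return present


def mean_ap(dets: Mapping[str, BoxSet], gts: Mapping[str, BoxSet],
            iou_threshold: float = 0.5) -> float:
    """Unweighted mean AP over the classes present in the ground truth."""
    classes = _gt_classes(gts)
    if not classes:
        raise ValueError("no ground-truth boxes: mAP undefined")
    return float(np.mean([average_precision(dets, gts, c, iou_threshold)
                          for c in classes]))


def map_range(dets: Mapping[str, BoxSet], gts: Mapping[str, BoxSet],
              thresholds: Sequence[float] = IOU_RANGE_THRESHOLDS) -> float:
    """Mean of mAP over an IoU threshold range (default 0.50:0.95, step .05)."""
    return float(np.mean([mean_ap(dets, gts, t) for t in thresholds]))


def confusion_matrix(dets: Mapping[str, BoxSet], gts: Mapping[str, BoxSet],
                     iou_threshold: float = 0.5,
                     conf_threshold: float = 0.0) -> np.ndarray:
    """10x10 detection confusion matrix (9 severity classes + background).

    Matching is class-agnostic greedy so cross-class confusions appear as
    off-diagonal mass: rows are ground-truth classes, columns detected
    classes; row/column 10 holds unmatched boxes (background).
    """
    m = np.zeros((10, 10), dtype=np.int64)
    for img in sorted(set(dets) | set(gts)):
        d = dets.get(img)
        g = gts.get(img, BoxSet(img, 1, 1, []))
        d_boxes = [] if d is None else \
            confidence_filter(d, conf_threshold).boxes
        gt_taken = [False] * len(g)
        for i in _by_confidence(d_boxes):
            best_j, best_iou = -1, 0.0
            for j, gt in enumerate(g.boxes):
                if gt_taken[j]:
                    continue
                v = iou(d_boxes[i], gt)
                if v >= iou_threshold and v > best_iou:
                    best_j, best_iou = j, v
            if best_j >= 0:
                gt_taken[best_j] = True
                m[g.boxes[best_j].class_id - 1, d_boxes[i].class_id - 1] += 1
            else:
                m[9, d_boxes[i].class_id - 1] += 1
        for j, gt in enumerate(g.boxes):
            if not gt_taken[j]:
                m[gt.class_id - 1, 9] += 1
    return m


def _f1_sweep(dets: Mapping[str, BoxSet], gts: Mapping[str, BoxSet],
              iou_threshold: float, n_points: int = 51
              ) -> list[tuple[float, float]]:
    """All-class (micro-averaged) F1 sampled over a confidence grid."""
    classes = _gt_classes(gts)
    out = []
    for conf in np.linspace(0.0, 1.0, n_points):
        tp = fp = fn = 0
        for img in sorted(set(dets) | set(gts)):
            d = dets.get(img)
            g = gts.get(img, BoxSet(img, 1, 1, []))
            d_f = confidence_filter(d, conf) if d is not None else None
            for c in sorted({b.class_id for b in g} |
                            ({b.class_id for b in d_f} if d_f else set())):
                d_cls = d_f.filter_class(c) if d_f is not None else BoxSet(img, 1, 1, [])
                outcome = match_detections(d_cls, g.filter_class(c), iou_threshold)
                tp += outcome.tp
                fp += outcome.fp
                fn += outcome.fn
        _, _, f1 = precision_recall_f1(tp, fp, fn)
        out.append((float(conf), f1))
    return out


def evaluate_detections(dets: Mapping[str, BoxSet], gts: Mapping[str, BoxSet],
                        iou_threshold: float = 0.5,
                        conf_threshold: float = 0.0) -> EvalReport:
    """Compute the full evaluation report over a dataset.

    ``conf_threshold`` applies to the confusion matrix only; AP sweeps all
    confidences by construction.
    """
    classes = _gt_classes(gts)
    per_class_ap = {c: average_precision(dets, gts, c, iou_threshold)
                    for c in classes}
    counts = {}
    for c in classes:
        tp = fp = fn = 0
        for img in sorted(set(dets) | set(gts)):
            d = dets.get(img)
            g = gts.get(img, BoxSet(img, 1, 1, []))
            d_cls = d.filter_class(c) if d is not None else BoxSet(img, 1, 1, [])
            o = match_detections(d_cls, g.filter_class(c), iou_threshold)
            tp, fp, fn = tp + o.tp, fp + o.fp, fn + o.fn
        counts[c] = MatchOutcome(tp, fp, fn)
    return EvalReport(
        per_class_ap=per_class_ap,
        map50=float(np.mean(list(per_class_ap.values()))),
        map50_95=map_range(dets, gts),
        f1_curve=_f1_sweep(dets, gts, iou_threshold),
        confusion=confusion_matrix(dets, gts, iou_threshold, conf_threshold),
        counts=counts,
        class_count=len(classes),
    )
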