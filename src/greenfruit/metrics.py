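"""Detection evaluation at IoU 0.5: P, R, F1, AP and mAP.

Matching rule: detections are processed in descending confidence; a detection
is a true positive when its IoU with an unmatched same-category ground-truth
box is strictly greater than the threshold (ties at exactly 0.5 count as
false positives).  Each ground truth is matched at most once; unmatched
ground truths are false negatives.

AP is the area under the precision-recall curve after applying the monotone
(non-increasing) precision envelope, using all-point interpolation.  mAP is
the unweighted mean of per-category APs.  Reported P and R are taken at the
confidence that maximizes F1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .boxes import BBox, DetectionBox, bbox_to_corners, box_iou

__all__ = [
    "MatchResult",
    "EvalReport",
    "match_detections",
    "average_precision",
    "f1_score",
    "summarize_metrics",
    "evaluate_detections",
]


@dataclass
class MatchResult:
    """Per-image matching outcome for one category.

    ``tp_flags[i]`` says whether detection ``i`` (sorted by descending
    confidence) matched a ground truth; ``confidences`` aligns with it.
    ``n_gt`` is the number of ground-truth boxes, so FN = n_gt - sum(tp).
    """

    tp_flags: np.ndarray  # bool, per detection
    confidences: np.ndarray  # float, per detection, descending
    matched_gt: np.ndarray  # int, gt index or -1, per detection
    n_gt: int

    @property
    def n_tp(self) -> int:
        return int(self.tp_flags.sum())

    @property
    def n_fp(self) -> int:
        return int(len(self.tp_flags) - self.tp_flags.sum())

    @property
    def n_fn(self) -> int:
        return self.n_gt - self.n_tp


def match_detections(
    detections: Sequence[DetectionBox],
    gt_boxes: Sequence[DetectionBox | tuple],
    iou_threshold: float = 0.5,
    category_id: int | None = None,
) -> MatchResult:
    """Greedy confidence-ordered matching of detections to ground truths.

    ``gt_boxes`` holds corner boxes ``(x1, y1, x2, y2)`` (tuples or objects
    with ``.corners``); when ``category_id`` is given, both detections and
    ground truths are assumed pre-filtered to that category.
    """
    dets = sorted(detections, key=lambda d: -d.confidence)
    gts = [g.corners if hasattr(g, "corners") else tuple(g) for g in gt_boxes]
    taken = np.zeros(len(gts), dtype=bool)
    tp = np.zeros(len(dets), dtype=bool)
    matched = np.full(len(dets), -1, dtype=int)
    for i, det in enumerate(dets):
        best_iou, best_j = 0.0, -1
        for j, gt in enumerate(gts):
            if taken[j]:
                continue
            iou = box_iou(det.corners, gt)
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0 and best_iou > iou_threshold:
            tp[i] = True
            taken[best_j] = True
            matched[i] = best_j
    conf = np.array([d.confidence for d in dets], dtype=float)
    return MatchResult(tp_flags=tp, confidences=conf, matched_gt=matched, n_gt=len(gts))


def _pr_points(tp: np.ndarray, conf: np.ndarray, n_gt: int):
    """Cumulative precision/recall along the confidence-sorted detection list."""
    order = np.argsort(-conf, kind="stable")
    tp = tp[order].astype(float)
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(1.0 - tp)
    recall = cum_tp / n_gt
    precision = cum_tp / np.maximum(cum_tp + cum_fp, 1e-16)
    return precision, recall, conf[order]


def average_precision(
    matches: Sequence[MatchResult],
) -> tuple[float, np.ndarray, np.ndarray]:
    """AP for one category from match results pooled over the test set.

    Returns ``(ap, precision_envelope, recall_points)``; the PR curve points
    are the raw cumulative values before the envelope.  Requires at least one
    ground truth for the category.
    """
    n_gt = sum(m.n_gt for m in matches)
    if n_gt == 0:
        raise ValueError("average_precision undefined with zero ground truths")
    tp = np.concatenate([m.tp_flags for m in matches]) if matches else np.zeros(0, bool)
    conf = np.concatenate([m.confidences for m in matches]) if matches else np.zeros(0)
    if len(tp) == 0:
        return 0.0, np.zeros(0), np.zeros(0)
    precision, recall, _ = _pr_points(tp, conf, n_gt)
    # all-point interpolation over the monotone precision envelope
    r = np.concatenate(([0.0], recall, [recall[-1]]))
    p = np.concatenate(([1.0], precision, [0.0]))
    p = np.maximum.accumulate(p[::-1])[::-1]
    idx = np.where(r[1:] != r[:-1])[0]
    ap = float(np.sum((r[idx + 1] - r[idx]) * p[idx + 1]))
    return ap, p, r


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision < 0 or recall < 0:
        raise ValueError("precision and recall must be non-negative")
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class EvalReport:
    """Per-category P/R/F1/AP (fractions in [0,1]) and their mean AP."""

    precision: dict[int, float]
    recall: dict[int, float]
    f1: dict[int, float]
    ap: dict[int, float]
    map50: float
    pr_curves: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def as_percent_table(self) -> str:
        """Markdown table with one-decimal percentages, one row per category."""
        lines = ["| category | P | R | F1 | AP |", "|---|---|---|---|---|"]
        for c in sorted(self.ap):
            lines.append(
                f"| {c} | {100 * self.precision[c]:.1f} | {100 * self.recall[c]:.1f}"
                f" | {100 * self.f1[c]:.1f} | {100 * self.ap[c]:.1f} |"
            )
        lines.append(f"| **mAP** | | | | **{100 * self.map50:.1f}** |")
        return "\n".join(lines)


def summarize_metrics(matches_by_category: Mapping[int, Sequence[MatchResult]]) -> EvalReport:
    """Build an :class:`EvalReport` from per-category pooled match results.

    P and R are read off the PR curve at the confidence maximizing F1 (with
    F1 computed pointwise along the curve).  Categories with zero ground
    truths are excluded from mAP with a warning.
    """
    precision: dict[int, float] = {}
    recall: dict[int, float] = {}
    f1: dict[int, float] = {}
    ap: dict[int, float] = {}
    curves: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for cat, matches in matches_by_category.items():
        n_gt = sum(m.n_gt for m in matches)
        if n_gt == 0:
            warnings.warn(f"category {cat}: no ground truths, excluded from mAP")
            continue
        ap_c, p_env, r_env = average_precision(matches)
        ap[cat] = ap_c
        curves[cat] = (p_env, r_env)
        tp = np.concatenate([m.tp_flags for m in matches]) if matches else np.zeros(0, bool)
        conf = np.concatenate([m.confidences for m in matches]) if matches else np.zeros(0)
        if len(tp) == 0:
            precision[cat], recall[cat], f1[cat] = 0.0, 0.0, 0.0
            continue
        p_curve, r_curve, _ = _pr_points(tp, conf, n_gt)
        f1_curve = np.where(
            p_curve + r_curve > 0, 2 * p_curve * r_curve / np.maximum(p_curve + r_curve, 1e-16), 0.0
        )
        best = int(np.argmax(f1_curve))
        precision[cat] = float(p_curve[best])
        recall[cat] = float(r_curve[best])
        f1[cat] = float(f1_curve[best])
    if not ap:
        raise ValueError("no category had ground truths; report is empty")
    map50 = float(np.mean(list(ap.values())))
    return EvalReport(precision, recall, f1, ap, map50, curves)


def evaluate_detections(
    detections_per_image: Sequence[Sequence[DetectionBox]],
    gts_per_image: Sequence[Sequence[BBox]],
    image_sizes: Sequence[tuple[int, int]],
    iou_threshold: float = 0.5,
) -> EvalReport:
    """Match detections to normalized ground truths image by image and summarize.

    Ground truths are converted to absolute corners with each image's size.
    Deterministic for fixed predictions.
    """
    if not (len(detections_per_image) == len(gts_per_image) == len(image_sizes)):
        raise ValueError("detections, ground truths and sizes must align per image")
    categories = set()
    for gts in gts_per_image:
        categories.update(b.category_id for b in gts)
    for dets in detections_per_image:
        categories.update(d.category_id for d in dets)
    by_cat: dict[int, list[MatchResult]] = {c: [] for c in sorted(categories)}
    for dets, gts, size in zip(detections_per_image, gts_per_image, image_sizes):
        for cat in by_cat:
            cat_dets = [d for d in dets if d.category_id == cat]
            cat_gts = [bbox_to_corners(b, size) for b in gts if b.category_id == cat]
            by_cat[cat].append(match_detections(cat_dets, cat_gts, iou_threshold))
    return summarize_metrics(by_cat)
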