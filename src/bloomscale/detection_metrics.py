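"""Instance-segmentation evaluation: mask IoU, greedy matching, precision,
recall, AP, mAP@0.5 and mAP@0.5:0.95.

Average precision follows the all-point precision-envelope convention used by
COCO-style detection evaluation: the ranked detection list is swept, a
precision-recall curve is accumulated, precision at each recall r is replaced
by the maximum precision at any recall >= r, and the envelope is integrated
over recall.  Matching is greedy in confidence order, one-to-one, with ties
broken toward the lowest ground-truth index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import MaskShapeError, ParameterError, UndefinedIoUError
from .imaging import InstanceDetection

COCO_IOU_THRESHOLDS: tuple[float, ...] = tuple(round(0.5 + 0.05 * i, 2) for i in range(10))


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two masks; symmetric, in [0, 1]."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise MaskShapeError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        raise UndefinedIoUError("IoU of two empty masks is undefined")
    inter = int(np.count_nonzero(a & b))
    return inter / union


@dataclass
class MatchResult:
    """One-to-one assignment of predictions to ground truths at a threshold."""

    pairs: list[tuple[int, int, float]]  # (prediction idx, truth idx, IoU)
    unmatched_predictions: list[int]  # false positives
    unmatched_truths: list[int]  # false negatives
    iou_threshold: float


def _ranked_order(predictions: Sequence[InstanceDetection]) -> list[int]:
    confidences = np.array([d.confidence for d in predictions])
    # stable sort keeps original order among ties
    return list(np.argsort(-confidences, kind="stable"))


def match_detections(
    predictions: Sequence[InstanceDetection],
    truths: Sequence[np.ndarray],
    iou_threshold: float = 0.5,
) -> MatchResult:
    """Greedy confidence-ordered matching.

    Each prediction, in descending-confidence order, claims the still-unmatched
    truth with the highest IoU >= threshold (IoU ties go to the lowest truth
    index).  Indices in the result refer to the original input order.
    """
    order = _ranked_order(predictions)
    truth_taken = [False] * len(truths)
    pairs: list[tuple[int, int, float]] = []
    unmatched_predictions: list[int] = []
    for pi in order:
        best_iou = 0.0
        best_ti = -1
        for ti, truth in enumerate(truths):
            if truth_taken[ti]:
                continue
            iou = mask_iou(predictions[pi].mask, truth)
            if iou >= iou_threshold and iou > best_iou:
                best_iou = iou
                best_ti = ti
        if best_ti >= 0:
            truth_taken[best_ti] = True
            pairs.append((pi, best_ti, best_iou))
        else:
            unmatched_predictions.append(pi)
    unmatched_truths = [ti for ti, taken in enumerate(truth_taken) if not taken]
    return MatchResult(pairs, unmatched_predictions, unmatched_truths, iou_threshold)


@dataclass
class PrecisionRecall:
    precision: float
    recall: float
    precision_undefined: bool = False  # true when there were zero predictions


def precision_recall(match: MatchResult, n_predictions: int, n_truths: int) -> PrecisionRecall:
    """Set-level precision (TP / all detections) and recall (TP / all truths)."""
    if n_truths < 1:
        raise ParameterError("recall is undefined with zero ground truths")
    tp = len(match.pairs)
    if n_predictions == 0:
        return PrecisionRecall(precision=0.0, recall=0.0, precision_undefined=True)
    return PrecisionRecall(precision=tp / n_predictions, recall=tp / n_truths)


@dataclass
class PRPoint:
    recall: float
    precision: float


@dataclass
class APResult:
    ap: float
    iou_threshold: float
    curve: list[PRPoint] = field(default_factory=list)


def average_precision(
    predictions: Sequence[InstanceDetection],
    truths: Sequence[np.ndarray],
    iou_threshold: float = 0.5,
) -> APResult:
    """Area under the precision-recall curve for one class at one threshold."""
    if len(truths) < 1:
        raise ParameterError("average precision is undefined with zero ground truths")
    if not predictions:
        return APResult(ap=0.0, iou_threshold=iou_threshold, curve=[])
    match = match_detections(predictions, truths, iou_threshold)
    matched = {pi for pi, _, _ in match.pairs}
    order = _ranked_order(predictions)
    is_tp = np.array([pi in matched for pi in order])
    tp_cum = np.cumsum(is_tp)
    ranks = np.arange(1, len(order) + 1)
    recall = tp_cum / len(truths)
    precision = tp_cum / ranks
    # all-point envelope: precision at recall r -> max precision at recall >= r
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    ap = float(np.sum((recall - prev_recall) * envelope))
    curve = [PRPoint(float(r), float(p)) for r, p in zip(recall, precision)]
    return APResult(ap=ap, iou_threshold=iou_threshold, curve=curve)


@dataclass
class DetectionSummary:
    """The four headline detection metrics for one class."""

    precision: float
    recall: float
    map50: float
    map50_95: float
    ap_by_threshold: dict[float, float] = field(default_factory=dict)
    precision_undefined: bool = False


def mean_ap(
    predictions: Sequence[InstanceDetection],
    truths: Sequence[np.ndarray],
    thresholds: Sequence[float] = COCO_IOU_THRESHOLDS,
) -> DetectionSummary:
    """Unweighted mean of AP over IoU thresholds for a single class.

    Precision and recall are reported at IoU 0.5 over the full detection
    list.  For multi-class evaluation, call per class and average the
    summaries with equal weights (see :func:`summarize_classes`).
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ParameterError("at least one IoU threshold is required")
    ap_by_threshold = {t: average_precision(predictions, truths, t).ap for t in thresholds}
    pr = precision_recall(
        match_detections(predictions, truths, 0.5), len(predictions), len(truths)
    )
    map50 = ap_by_threshold.get(0.5, average_precision(predictions, truths, 0.5).ap)
    return DetectionSummary(
        precision=pr.precision,
        recall=pr.recall,
        map50=map50,
        map50_95=float(np.mean(list(ap_by_threshold.values()))),
        ap_by_threshold=ap_by_threshold,
        precision_undefined=pr.precision_undefined,
    )


def summarize_classes(per_class: dict[str, DetectionSummary]) -> DetectionSummary:
    """Equal-weight mean of per-class summaries (the multi-class mAP)."""
    if not per_class:
        raise ParameterError("no classes to summarize")
    vals = list(per_class.values())
    return DetectionSummary(
        precision=float(np.mean([v.precision for v in vals])),
        recall=float(np.mean([v.recall for v in vals])),
        map50=float(np.mean([v.map50 for v in vals])),
        map50_95=float(np.mean([v.map50_95 for v in vals])),
    )
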