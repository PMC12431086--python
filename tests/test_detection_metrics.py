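"""Mask IoU, greedy matching, AP and mAP — checked against an independent
brute-force oracle that enumerates confidence cuts and integrates the
precision envelope numerically."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bloomscale.detection_metrics import (
    COCO_IOU_THRESHOLDS,
    average_precision,
    mask_iou,
    match_detections,
    mean_ap,
    precision_recall,
    summarize_classes,
)
from bloomscale.errors import ParameterError, UndefinedIoUError
from bloomscale.imaging import FLOWER, InstanceDetection

SHAPE = (30, 30)


def rect(r0, r1, c0, c1, shape=SHAPE):
    m = np.zeros(shape, dtype=bool)
    m[r0:r1, c0:c1] = True
    return m


def det(mask, conf):
    return InstanceDetection(FLOWER, mask, conf)


# ---------------------------------------------------------------------------
# Independent oracle: enumerate every confidence cut, compute the PR point
# from scratch with its own greedy matcher, and integrate the envelope on a
# dense recall grid.
# ---------------------------------------------------------------------------

def _oracle_greedy_tp(dets, truths, thr):
    order = sorted(range(len(dets)), key=lambda i: -dets[i].confidence)
    taken = set()
    tp_flags = {}
    for i in order:
        candidates = []
        for t, truth in enumerate(truths):
            if t in taken:
                continue
            inter = np.count_nonzero(dets[i].mask & truth)
            union = np.count_nonzero(dets[i].mask | truth)
            iou = inter / union if union else 0.0
            if iou >= thr:
                candidates.append((iou, -t))
        if candidates:
            best = max(candidates)
            taken.add(-best[1])
            tp_flags[i] = True
        else:
            tp_flags[i] = False
    return tp_flags


def brute_force_ap(dets, truths, thr, grid=200_000):
    if not dets:
        return 0.0
    tp_flags = _oracle_greedy_tp(dets, truths, thr)
    cuts = sorted({d.confidence for d in dets}, reverse=True)
    points = []
    for cut in cuts:
        kept = [i for i, d in enumerate(dets) if d.confidence >= cut]
        tp = sum(tp_flags[i] for i in kept)
        points.append((tp / len(truths), tp / len(kept)))
    rs = np.array([p[0] for p in points])  # nondecreasing as the cut lowers
    ps = np.array([p[1] for p in points])
    # envelope(r) = max precision among PR points with recall >= r
    suffix_max = np.maximum.accumulate(ps[::-1])[::-1]
    r_grid = (np.arange(grid) + 0.5) / grid
    idx = np.searchsorted(rs, r_grid, side="left")
    env = np.where(idx < len(rs), suffix_max[np.minimum(idx, len(rs) - 1)], 0.0)
    return float(env.mean())


class TestMaskIoU:
    def test_identical_masks(self):
        m = rect(0, 5, 0, 5)
        assert mask_iou(m, m) == 1.0

    def test_disjoint_masks(self):
        assert mask_iou(rect(0, 5, 0, 5), rect(10, 15, 10, 15)) == 0.0

    def test_partial_overlap(self):
        a = rect(0, 5, 0, 20)  # 100 px
        b = rect(0, 5, 12, 20) | rect(5, 10, 0, 12)  # 100 px, 40 shared
        assert mask_iou(a, b) == pytest.approx(40 / 160)
        assert mask_iou(a, b) == mask_iou(b, a)

    def test_both_empty_undefined(self):
        empty = np.zeros(SHAPE, dtype=bool)
        with pytest.raises(UndefinedIoUError):
            mask_iou(empty, empty)


class TestMatching:
    def test_exact_match(self):
        truth = rect(0, 5, 0, 5)
        m = match_detections([det(truth, 0.9)], [truth], 0.5)
        assert m.pairs == [(0, 0, 1.0)]
        assert not m.unmatched_predictions and not m.unmatched_truths

    def test_higher_confidence_claims_the_truth(self):
        truth = rect(0, 10, 0, 10)
        strong = det(rect(0, 10, 0, 9), 0.9)
        weak = det(rect(0, 9, 0, 10), 0.8)
        m = match_detections([weak, strong], [truth], 0.5)
        assert [(pi, ti) for pi, ti, _ in m.pairs] == [(1, 0)]
        assert m.unmatched_predictions == [0]

    def test_no_predictions_all_false_negatives(self):
        truths = [rect(0, 2, 0, 2), rect(5, 7, 5, 7), rect(10, 12, 10, 12)]
        m = match_detections([], truths, 0.5)
        assert m.unmatched_truths == [0, 1, 2]

    def test_iou_tie_goes_to_lowest_truth_index(self):
        t0 = rect(0, 4, 0, 4)
        t1 = rect(0, 4, 10, 14)
        pred = det(t0 | t1, 0.9)  # identical IoU (0.5) with both truths
        m = match_detections([pred], [t1, t0], 0.5)
        assert m.pairs[0][1] == 0


class TestPrecisionRecall:
    def test_partial(self):
        truths = [rect(0, 4, 0, 4), rect(10, 14, 0, 4)]
        preds = [det(truths[0], 0.9), det(truths[1], 0.8), det(rect(20, 24, 20, 24), 0.7)]
        m = match_detections(preds, truths, 0.5)
        pr = precision_recall(m, len(preds), len(truths))
        assert pr.precision == pytest.approx(2 / 3)
        assert pr.recall == pytest.approx(1.0)

    def test_zero_predictions_flagged(self):
        m = match_detections([], [rect(0, 2, 0, 2)], 0.5)
        pr = precision_recall(m, 0, 1)
        assert pr.precision == 0.0 and pr.precision_undefined

    def test_zero_truths_is_error(self):
        m = match_detections([], [rect(0, 2, 0, 2)], 0.5)
        with pytest.raises(ParameterError):
            precision_recall(m, 0, 0)


def tp_fp_tp_case():
    """Ranked [TP, FP, TP] over two truths: AP = 0.5*1 + 0.5*(2/3) = 0.8333."""
    truths = [rect(0, 5, 0, 5), rect(10, 15, 10, 15)]
    preds = [
        det(truths[0], 0.9),
        det(rect(20, 25, 20, 25), 0.8),  # false positive
        det(truths[1], 0.7),
    ]
    return preds, truths


class TestAveragePrecision:
    def test_hand_computed_envelope_case(self):
        preds, truths = tp_fp_tp_case()
        assert average_precision(preds, truths, 0.5).ap == pytest.approx(5 / 6, abs=1e-9)

    def test_perfect_detections(self):
        truths = [rect(0, 5, 0, 5), rect(10, 15, 10, 15)]
        preds = [det(truths[0], 0.9), det(truths[1], 0.8)]
        assert average_precision(preds, truths, 0.5).ap == 1.0

    def test_no_predictions(self):
        assert average_precision([], [rect(0, 5, 0, 5)], 0.5).ap == 0.0

    def test_empty_truths_error(self):
        with pytest.raises(ParameterError):
            average_precision([], [], 0.5)

    def test_rank_preserving_rescale_invariance(self):
        preds, truths = tp_fp_tp_case()
        rescaled = [det(p.mask, 0.1 + 0.5 * p.confidence) for p in preds]
        assert average_precision(preds, truths, 0.5).ap == pytest.approx(
            average_precision(rescaled, truths, 0.5).ap
        )

    def test_trailing_false_positive_never_raises_ap(self):
        preds, truths = tp_fp_tp_case()
        worse = preds + [det(rect(25, 29, 0, 4), 0.01)]
        assert average_precision(worse, truths, 0.5).ap <= average_precision(preds, truths, 0.5).ap

    def test_matches_bruteforce_on_hand_cases(self):
        preds, truths = tp_fp_tp_case()
        for thr in (0.3, 0.5, 0.75):
            assert average_precision(preds, truths, thr).ap == pytest.approx(
                brute_force_ap(preds, truths, thr), abs=1e-4
            )

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 2**30))
    def test_matches_bruteforce_on_random_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n_truths = int(rng.integers(1, 4))
        n_preds = int(rng.integers(0, 7))
        truths = []
        for _ in range(n_truths):
            r0, c0 = rng.integers(0, 20, 2)
            truths.append(rect(r0, r0 + int(rng.integers(3, 9)), c0, c0 + int(rng.integers(3, 9))))
        confs = rng.permutation(np.linspace(0.1, 0.9, max(n_preds, 1)))[:n_preds]
        preds = []
        for i in range(n_preds):
            r0, c0 = rng.integers(0, 20, 2)
            mask = rect(r0, r0 + int(rng.integers(3, 9)), c0, c0 + int(rng.integers(3, 9)))
            preds.append(det(mask, float(confs[i])))
        thr = float(rng.choice([0.3, 0.5, 0.75]))
        assert average_precision(preds, truths, thr).ap == pytest.approx(
            brute_force_ap(preds, truths, thr), abs=1e-4
        )


class TestMeanAP:
    def test_perfect_predictions_score_one_everywhere(self):
        truths = [rect(0, 5, 0, 5), rect(10, 15, 10, 15)]
        preds = [det(truths[0], 0.9), det(truths[1], 0.8)]
        summary = mean_ap(preds, truths)
        assert summary.map50 == 1.0 and summary.map50_95 == 1.0
        assert all(v == 1.0 for v in summary.ap_by_threshold.values())

    def test_iou_point_six_passes_three_thresholds(self):
        truth = rect(0, 5, 0, 20)  # 100 px
        pred = det(rect(0, 5, 5, 25), 0.9)  # 100 px, 75 shared -> IoU 75/125 = 0.6
        assert mask_iou(pred.mask, truth) == pytest.approx(0.6)
        summary = mean_ap([pred], [truth])
        assert summary.map50_95 == pytest.approx(0.3)

    def test_singleton_threshold_equals_ap50(self):
        preds, truths = tp_fp_tp_case()
        summary = mean_ap(preds, truths, thresholds=[0.5])
        assert summary.map50_95 == pytest.approx(average_precision(preds, truths, 0.5).ap)

    def test_monotone_in_nested_threshold_sets(self):
        preds, truths = tp_fp_tp_case()
        nested = [COCO_IOU_THRESHOLDS[:k] for k in (1, 4, 10)]
        values = [mean_ap(preds, truths, thresholds=t).map50_95 for t in nested]
        assert values == sorted(values, reverse=True)

    def test_multiclass_summary_is_equal_weight_mean(self):
        preds, truths = tp_fp_tp_case()
        good = mean_ap([det(truths[0], 0.9), det(truths[1], 0.8)], truths)
        bad = mean_ap(preds, truths)
        combined = summarize_classes({"a": good, "b": bad})
        assert combined.map50 == pytest.approx((good.map50 + bad.map50) / 2)
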