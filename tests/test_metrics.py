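"""Detection and counting metrics against independent brute-force oracles."""

import numpy as np
import pytest

from germquant.annotations import AnnotatedImage
from germquant.boxes import BoundingBox, iou
from germquant.census import ClassCounts
from germquant.detector.model import Detection
from germquant.metrics import (
    PRCurve,
    average_precision,
    count_error,
    evaluate_on_annotations,
    match_predictions,
    mean_average_precision,
    precision_recall,
)


def boxes_arr(rows):
    return np.array(rows, dtype=float).reshape(-1, 4)


def ap_oracle(tp_flags, n_gt):
    """AP by exhaustive cutoff enumeration: each true positive contributes
    1/n_gt times the best precision achievable at or after its rank."""
    n = len(tp_flags)
    cum = np.cumsum(tp_flags)
    precisions = [cum[k] / (k + 1) for k in range(n)]
    ap = 0.0
    for k in range(n):
        if tp_flags[k]:
            ap += max(precisions[k:]) / n_gt
    return ap


class TestMatching:
    def test_perfect_predictions_all_tp(self):
        gts = boxes_arr([[0, 0, 10, 10], [20, 20, 30, 30]])
        m = match_predictions(gts, np.array([0.9, 0.8]), gts, 0.5)
        assert m.is_tp.all() and m.gt_matched.all() and m.n_fn == 0

    def test_one_gt_two_overlapping_preds(self):
        gt = boxes_arr([[0, 0, 10, 10]])
        preds = boxes_arr([[0, 0, 10, 10], [1, 0, 11, 10]])
        m = match_predictions(preds, np.array([0.6, 0.9]), gt, 0.5)
        # higher-confidence prediction (index 1) matches first; other is FP
        assert m.order.tolist() == [1, 0]
        assert m.is_tp.tolist() == [True, False]

    def test_unmatched_gt_is_fn(self):
        gts = boxes_arr([[0, 0, 10, 10], [50, 50, 60, 60]])
        preds = boxes_arr([[0, 0, 10, 10]])
        m = match_predictions(preds, np.array([0.9]), gts, 0.5)
        assert m.n_fn == 1

    def test_agrees_with_brute_force_greedy_oracle(self, rng):
        for _ in range(40):
            n_p, n_g = rng.integers(0, 9), rng.integers(0, 5)
            p0 = rng.uniform(0, 40, (n_p, 2))
            preds = np.hstack([p0, p0 + rng.uniform(4, 25, (n_p, 2))]) if n_p else np.zeros((0, 4))
            g0 = rng.uniform(0, 40, (n_g, 2))
            gts = np.hstack([g0, g0 + rng.uniform(4, 25, (n_g, 2))]) if n_g else np.zeros((0, 4))
            confs = rng.uniform(0, 1, n_p)

            m = match_predictions(preds, confs, gts, 0.4)

            # reference: greedy over scalar IoU in confidence order
            used = set()
            expect_tp = []
            for i in sorted(range(n_p), key=lambda i: (-confs[i], i)):
                best, best_j = -1.0, None
                for j in range(n_g):
                    if j in used:
                        continue
                    v = iou(BoundingBox(*preds[i]), BoundingBox(*gts[j]))
                    if v > best:
                        best, best_j = v, j
                if best_j is not None and best > 0.4:
                    used.add(best_j)
                    expect_tp.append(True)
                else:
                    expect_tp.append(False)
            assert m.is_tp.tolist() == expect_tp


class TestPrecisionRecall:
    def test_worked_ratios(self):
        # 8 TP then 2 FP: final precision 0.8; recall 0.8 of 10 gts
        m = match_predictions(
            boxes_arr([[i * 20, 0, i * 20 + 10, 10] for i in range(10)]),
            np.linspace(1, 0.1, 10),
            boxes_arr([[i * 20, 0, i * 20 + 10, 10] for i in range(8)] +
                      [[500, 500, 510, 510], [600, 600, 610, 610]]),
            0.5,
        )
        curve = precision_recall(m, 10)
        assert curve.precision[-1] == pytest.approx(0.8)
        assert curve.recall[-1] == pytest.approx(0.8)
        assert (np.diff(curve.recall) >= 0).all()

    def test_zero_predictions_empty_curve(self):
        m = match_predictions(np.zeros((0, 4)), np.zeros(0), boxes_arr([[0, 0, 5, 5]]), 0.5)
        curve = precision_recall(m, 1)
        assert curve.recall.size == 0

    def test_no_gt_flags_recall_undefined(self):
        m = match_predictions(boxes_arr([[0, 0, 5, 5]]), np.array([0.9]),
                              np.zeros((0, 4)), 0.5)
        curve = precision_recall(m, 0)
        assert np.isnan(curve.recall).all()
        assert curve.precision[0] == 0.0


class TestAveragePrecision:
    def test_perfect_single_detection(self):
        assert average_precision(PRCurve(np.array([1.0]), np.array([1.0]))) == 1.0

    def test_worked_tp_fp_tp_example(self):
        """Ranked (TP, FP, TP) over 2 gts: envelope 1.0 on [0, .5], 2/3 above."""
        tp = [True, False, True]
        cum = np.cumsum(tp)
        curve = PRCurve(recall=cum / 2, precision=cum / np.arange(1, 4))
        expected = 0.5 * 1.0 + 0.5 * (2 / 3)
        assert average_precision(curve) == pytest.approx(expected, abs=1e-9)
        assert average_precision(curve) == pytest.approx(ap_oracle(tp, 2), abs=1e-9)

    def test_all_false_positives(self):
        curve = PRCurve(recall=np.zeros(3), precision=np.zeros(3))
        assert average_precision(curve) == 0.0

    def test_empty_curve(self):
        assert average_precision(PRCurve(np.zeros(0), np.zeros(0))) == 0.0

    def test_matches_enumeration_oracle_on_random_rankings(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 11))
            n_gt = int(rng.integers(1, 6))
            tp = []
            count = 0
            for f in rng.random(n) < 0.5:  # at most n_gt true positives
                f = bool(f) and count < n_gt
                count += f
                tp.append(f)
            cum = np.cumsum(tp)
            curve = PRCurve(recall=cum / n_gt, precision=cum / np.arange(1, n + 1))
            assert average_precision(curve) == pytest.approx(ap_oracle(tp, n_gt), abs=1e-9)


class TestMeanAP:
    def test_mean_over_classes(self):
        assert mean_average_precision({"S": 1.0, "R": 0.5}) == pytest.approx(0.75)

    def test_single_class_is_identity(self):
        assert mean_average_precision({"S": 0.42}) == pytest.approx(0.42)


class TestCountError:
    def test_exact_counts_zero_error(self):
        y = ClassCounts("S_R", {"S": 50, "R": 30})
        ae, mae = count_error(y, y)
        assert mae == 0.0 and all(v == 0 for v in ae.values())

    def test_worked_example(self):
        """y=(50,30), t=(45,33): AE = (0.10, 0.10), mAE 0.10."""
        y = ClassCounts("S_R", {"S": 50, "R": 30})
        t = ClassCounts("S_R", {"S": 45, "R": 33})
        ae, mae = count_error(y, t)
        assert ae["S"] == pytest.approx(0.10, abs=1e-9)
        assert ae["R"] == pytest.approx(0.10, abs=1e-9)
        assert mae == pytest.approx(0.10, abs=1e-9)

    def test_single_class_relative_error(self):
        y = ClassCounts("S_R", {"S": 10, "R": 0})
        t = ClassCounts("S_R", {"S": 12, "R": 0})
        ae, mae = count_error(y, t)
        assert ae["S"] == pytest.approx(0.2)
        assert mae == pytest.approx(0.2)  # R absent both sides: skipped

    def test_scale_free(self, rng):
        for _ in range(20):
            y1, y2, t1, t2 = (int(v) for v in rng.integers(1, 50, 4))
            k = int(rng.integers(2, 9))
            _, mae = count_error(ClassCounts("S_R", {"S": y1, "R": y2}),
                                 ClassCounts("S_R", {"S": t1, "R": t2}))
            _, mae_k = count_error(ClassCounts("S_R", {"S": k * y1, "R": k * y2}),
                                   ClassCounts("S_R", {"S": k * t1, "R": k * t2}))
            assert mae_k == pytest.approx(mae, abs=1e-12)

    def test_spurious_count_against_zero_gt(self):
        y = ClassCounts("S_R", {"S": 10, "R": 0})
        t = ClassCounts("S_R", {"S": 10, "R": 3})
        ae, mae = count_error(y, t)
        assert ae["R"] == 3.0  # absolute miscount convention
        assert mae == pytest.approx(1.5)

    def test_scheme_mismatch_rejected(self):
        with pytest.raises(ValueError):
            count_error(ClassCounts("S_R"), ClassCounts("NGS_GS"))


def _ann(objs, scheme="S_R", size=200):
    return AnnotatedImage("img", size, size, scheme, objs)


class TestEvaluateOnAnnotations:
    def test_ground_truth_as_predictions_is_perfect(self):
        objs = [("S", BoundingBox(0, 0, 10, 10)), ("S", BoundingBox(30, 0, 42, 10)),
                ("R", BoundingBox(60, 60, 70, 66))]
        ann = _ann(objs)
        dets = [Detection(b, lab, 1.0) for lab, b in objs]
        rep = evaluate_on_annotations([(dets, ann)], "S_R")
        assert rep.mAP == pytest.approx(1.0)
        assert rep.mAE == pytest.approx(0.0)

    def test_removing_a_detection_increases_class_ae(self):
        objs = [("S", BoundingBox(0, 0, 10, 10)), ("S", BoundingBox(30, 0, 42, 10))]
        ann = _ann(objs)
        dets = [Detection(b, lab, 1.0) for lab, b in objs]
        full = evaluate_on_annotations([(dets, ann)], "S_R")
        partial = evaluate_on_annotations([(dets[:1], ann)], "S_R")
        assert partial.per_class_ae["S"] > full.per_class_ae["S"]

    def test_class_absent_everywhere_scores_ap_one(self):
        objs = [("S", BoundingBox(0, 0, 10, 10))]
        dets = [Detection(BoundingBox(0, 0, 10, 10), "S", 1.0)]
        rep = evaluate_on_annotations([(dets, _ann(objs))], "S_R")
        assert rep.per_class_ap["R"] == 1.0

    def test_map_and_mae_can_rank_detectors_differently(self):
        """Good localization with missed objects vs loose boxes with the
        right count: the first wins mAP, the second wins mAE."""
        gt = [("S", BoundingBox(0, 0, 20, 20)), ("S", BoundingBox(50, 0, 70, 20))]
        ann = _ann(gt)
        # detector A: one perfect box, one object missed entirely
        dets_a = [Detection(BoundingBox(0, 0, 20, 20), "S", 0.95)]
        # detector B: two loose boxes (IoU ~ 0.38, below the 0.5 threshold)
        dets_b = [Detection(BoundingBox(6, 6, 26, 26), "S", 0.9),
                  Detection(BoundingBox(56, 6, 76, 26), "S", 0.9)]
        rep_a = evaluate_on_annotations([(dets_a, ann)], "S_R")
        rep_b = evaluate_on_annotations([(dets_b, ann)], "S_R")
        assert rep_a.mAP > rep_b.mAP       # A localizes better
        assert rep_a.mAE > rep_b.mAE       # but B counts better


class TestEvaluateDetectorGuards:
    def test_training_split_refused(self, tiny_dataset):
        from germquant.metrics import evaluate_detector
        with pytest.raises(ValueError, match="training split"):
            evaluate_detector(model=None, manifest=tiny_dataset, split="train")

    def test_split_overlapping_train_refused(self, tiny_dataset):
        from germquant.metrics import evaluate_detector
        from germquant.simulate import DatasetManifest
        train_id = tiny_dataset.ids("train")[0]
        tainted = DatasetManifest(
            root=tiny_dataset.root,
            entries=tiny_dataset.entries + [(train_id, "test")],
        )
        with pytest.raises(ValueError, match="overlap"):
            evaluate_detector(model=None, manifest=tainted, split="test")
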