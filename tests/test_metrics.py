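"""Detection metrics against hand-tallied fixtures and numerical oracles."""
import numpy as np
import pytest

from iihgnn.metrics import (MatchResult, acc_f1, average_precision, box_iou,
                            confusion_matrix, evaluate_detections,
                            match_detections, mean_ap, precision_recall,
                            pr_curve_from_detections)


def ap_numerical_oracle(recall, precision, n_steps=200001):
    """Fine-grained Riemann-sum oracle for the all-point interpolated AP:
    integrate the precision envelope p(r) = max{prec_i : rec_i >= r}."""
    recall = np.asarray(recall, float)
    precision = np.asarray(precision, float)
    rs = np.linspace(0.0, 1.0, n_steps)
    ps = np.zeros_like(rs)
    for k, r in enumerate(rs):
        cand = precision[recall >= r - 1e-12]
        ps[k] = cand.max() if cand.size else 0.0
    return float(np.trapezoid(ps, rs))


class TestMatching:
    def test_perfect_single_match(self):
        m = match_detections([((0, 0, 10, 10), 0, 0.9)],
                             [((0, 0, 10, 10), 0)], 0.5)
        assert (m.TP, m.FP, m.FN) == (1, 0, 0)

    def test_one_to_one_rule(self):
        preds = [((0, 0, 10, 10), 0, 0.9), ((1, 1, 11, 11), 0, 0.8)]
        m = match_detections(preds, [((0, 0, 10, 10), 0)], 0.5)
        assert (m.TP, m.FP, m.FN) == (1, 1, 0)
        assert m.pred_is_tp.tolist() == [True, False]

    def test_class_must_agree(self):
        m = match_detections([((0, 0, 10, 10), 1, 0.9)],
                             [((0, 0, 10, 10), 0)], 0.5)
        assert (m.TP, m.FP, m.FN) == (0, 1, 1)

    def test_greedy_matches_oracle_on_random_instances(self, rng):
        """TP counts agree with an independent re-implementation of
        confidence-ordered greedy assignment."""
        for _ in range(30):
            n_gt = int(rng.integers(0, 10))
            n_pred = int(rng.integers(0, 20))
            gts = [((x, y, x + w, y + h), 0)
                   for x, y, w, h in zip(rng.uniform(0, 80, n_gt),
                                         rng.uniform(0, 80, n_gt),
                                         rng.uniform(5, 20, n_gt),
                                         rng.uniform(5, 20, n_gt))]
            preds = [((x, y, x + w, y + h), 0, float(c))
                     for x, y, w, h, c in zip(rng.uniform(0, 80, n_pred),
                                              rng.uniform(0, 80, n_pred),
                                              rng.uniform(5, 20, n_pred),
                                              rng.uniform(5, 20, n_pred),
                                              rng.random(n_pred))]
            m = match_detections(preds, gts, 0.5)
            # oracle: explicit loop
            taken = set()
            tp = 0
            for p in sorted(preds, key=lambda p: -p[2]):
                best, best_iou = None, 0.5
                for j, g in enumerate(gts):
                    if j in taken:
                        continue
                    iou = box_iou([p[0]], [g[0]])[0, 0]
                    if iou >= best_iou:
                        best, best_iou = j, iou
                if best is not None:
                    taken.add(best)
                    tp += 1
            assert m.TP == tp
            assert m.TP + m.FN == len(gts)


class TestScalarMetrics:
    def test_precision_recall_arithmetic(self):
        assert precision_recall(MatchResult(8, 2, 0)) == (0.8, 1.0)
        assert precision_recall(MatchResult(8, 0, 2)) == (1.0, 0.8)

    def test_empty_denominator_conventions(self):
        p, r = precision_recall(MatchResult(0, 0, 0))
        assert (p, r) == (1.0, 1.0)

    def test_acc_f1_fixtures(self):
        acc, f1 = acc_f1(MatchResult(5, 0, 0, TN=5))
        assert (acc, f1) == (1.0, 1.0)
        acc, f1 = acc_f1(MatchResult(8, 2, 2, TN=0))
        assert np.isclose(f1, 0.8)          # P = R = 0.8
        acc, f1 = acc_f1(MatchResult(0, 5, 5))
        assert f1 == 0.0


class TestAveragePrecision:
    def test_perfect_detector(self):
        curve = pr_curve_from_detections([True, True, True],
                                         [0.9, 0.8, 0.7], n_gt=3)
        assert np.isclose(curve.ap, 1.0)
        assert np.all(np.diff(curve.recall) >= 0)

    def test_zero_tp_detector(self):
        curve = pr_curve_from_detections([False] * 4,
                                         [0.9, 0.8, 0.7, 0.6], n_gt=5)
        assert curve.ap == 0.0

    def test_ap_matches_numerical_integration_oracle(self):
        flags = [True, False, True, True, False, False, True, False,
                 True, False]
        confs = [0.95, 0.9, 0.85, 0.8, 0.75, 0.7, 0.65, 0.6, 0.55, 0.5]
        curve = pr_curve_from_detections(flags, confs, n_gt=6)
        oracle = ap_numerical_oracle(curve.recall, curve.precision)
        assert abs(curve.ap - oracle) < 1e-4

    def test_ap_matches_oracle_on_random_instances(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 25))
            flags = rng.random(n) > 0.4
            confs = rng.random(n)
            n_gt = int(flags.sum() + rng.integers(0, 5))
            if n_gt == 0:
                continue
            curve = pr_curve_from_detections(flags, confs, n_gt)
            oracle = ap_numerical_oracle(curve.recall, curve.precision)
            assert abs(curve.ap - oracle) < 1e-4

    def test_mean_ap(self):
        assert mean_ap([1.0, 0.5]) == 0.75


class TestConfusionMatrix:
    def test_perfect_predictions_diagonal(self):
        gts = [[((0, 0, 10, 10), 0), ((20, 20, 30, 30), 1)]]
        preds = [[((0, 0, 10, 10), 0, 0.9), ((20, 20, 30, 30), 1, 0.8)]]
        M = confusion_matrix(preds, gts)
        assert np.array_equal(M, [[1, 0, 0], [0, 1, 0], [0, 0, 0]])

    def test_no_predictions_all_background_column(self):
        gts = [[((0, 0, 10, 10), 0), ((20, 20, 30, 30), 1)]]
        M = confusion_matrix([[]], gts)
        assert np.array_equal(M, [[0, 0, 1], [0, 0, 1], [0, 0, 0]])

    def test_hand_tallied_mixed_fixture(self):
        """Three known mistakes: a mitosis called hard-negative, a missed
        hard-negative, and a spurious mitosis call on background."""
        gts = [[((0, 0, 10, 10), 0),       # matched, wrong class
                ((20, 20, 30, 30), 1),     # missed
                ((40, 40, 50, 50), 0)]]    # matched correctly
        preds = [[((0, 0, 10, 10), 1, 0.9),
                  ((40, 40, 50, 50), 0, 0.8),
                  ((70, 70, 80, 80), 0, 0.7)]]
        M = confusion_matrix(preds, gts)
        expected = np.array([[1, 1, 0],    # truth mitotic: 1 ok, 1 as hn
                             [0, 0, 1],    # truth hn: missed
                             [1, 0, 0]])   # background: 1 false mitosis
        assert np.array_equal(M, expected)

    def test_row_sums_equal_gt_counts(self, rng):
        gts, preds = [], []
        for _ in range(5):
            g = [((float(x), float(y), float(x + 8), float(y + 8)),
                  int(rng.integers(0, 2)))
                 for x, y in rng.uniform(0, 90, size=(6, 2))]
            p = [(b, int(rng.integers(0, 2)), float(rng.random()))
                 for b, _ in g[:4]]
            gts.append(g)
            preds.append(p)
        M = confusion_matrix(preds, gts)
        for c in (0, 1):
            n_c = sum(1 for g in gts for _, cc in g if cc == c)
            assert M[c].sum() == n_c

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([[((0, 0, 1, 1), 7, 0.5)]], [[]])


class TestEvaluateDetections:
    def test_identity_case_all_ones(self, smoke_dataset):
        gts = smoke_dataset.annotations[:10]
        preds = [[(b, c, 1.0) for b, c in g] for g in gts]
        rep = evaluate_detections(preds, gts)
        assert rep["mAP50"] == 1.0
        assert rep["precision"] == 1.0 and rep["recall"] == 1.0
        assert rep["ACC"] == 1.0 and rep["F1"] == 1.0

    def test_patch_level_true_negatives(self):
        rep = evaluate_detections([[], []], [[], []])
        assert rep["counts"]["TN"] == 2
        assert rep["ACC"] == 1.0
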