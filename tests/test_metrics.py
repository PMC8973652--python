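"""Evaluation metrics against independent oracles."""

import itertools

import numpy as np
import pytest

from perioscan.pbl_core import Stage
from perioscan.metrics import (
    EmptyMatrix,
    LengthMismatch,
    OneClassOnly,
    ZeroMargin,
    average_precision,
    box_iou,
    chi_square_test,
    classification_metrics,
    confusion_matrix,
    detection_metrics,
    icc,
    rater_table,
    roc_curve,
)


class TestConfusionMatrix:
    def test_hand_tally(self):
        cm = confusion_matrix(
            [Stage.I, Stage.I, Stage.II], [Stage.I, Stage.II, Stage.II]
        )
        assert cm.counts.tolist() == [[1, 1, 0], [0, 1, 0], [0, 0, 0]]

    def test_row_sums_are_reference_counts(self, rng):
        stages = list(Stage)
        ref = [stages[i] for i in rng.integers(0, 3, size=200)]
        pred = [stages[i] for i in rng.integers(0, 3, size=200)]
        cm = confusion_matrix(ref, pred)
        for i, s in enumerate(stages):
            assert cm.counts[i].sum() == sum(r == s for r in ref)

    def test_perfect_predictions_are_diagonal(self):
        ref = [Stage.I, Stage.II, Stage.III_IV] * 5
        cm = confusion_matrix(ref, ref)
        assert np.all(cm.counts == np.diag(np.diag(cm.counts)))

    def test_length_mismatch(self):
        with pytest.raises(LengthMismatch):
            confusion_matrix([Stage.I], [])


class TestClassificationMetrics:
    def test_diagonal_matrix_scores_one(self):
        ref = [Stage.I, Stage.II, Stage.III_IV] * 4
        rep = classification_metrics(confusion_matrix(ref, ref))
        for m in rep.per_class.values():
            assert m.precision == m.sensitivity == m.specificity == m.f1 == 1.0
        assert rep.overall.accuracy == 1.0

    def test_two_class_hand_computation(self):
        cm = confusion_matrix([0] * 6 + [1] * 6, [0] * 5 + [1] + [0] * 2 + [1] * 4,
                              labels=(0, 1))
        rep = classification_metrics(cm)
        assert cm.counts.tolist() == [[5, 1], [2, 4]]
        assert rep.per_class[0].precision == pytest.approx(5 / 7)
        assert rep.per_class[0].sensitivity == pytest.approx(5 / 6)
        assert rep.overall.accuracy == pytest.approx(9 / 12)

    def test_agrees_with_sklearn_on_random_labels(self, rng):
        from sklearn.metrics import precision_recall_fscore_support

        for _ in range(20):
            ref = rng.integers(0, 3, size=100)
            pred = rng.integers(0, 3, size=100)
            rep = classification_metrics(confusion_matrix(ref, pred, labels=(0, 1, 2)))
            p, r, f, _ = precision_recall_fscore_support(
                ref, pred, labels=[0, 1, 2], zero_division=np.nan
            )
            for ci in range(3):
                m = rep.per_class[ci]
                if not np.isnan(p[ci]):
                    assert m.precision == pytest.approx(p[ci])
                if not np.isnan(r[ci]):
                    assert m.sensitivity == pytest.approx(r[ci])
                if not np.isnan(f[ci]) and m.f1 is not None:
                    assert m.f1 == pytest.approx(f[ci])

    def test_f1_between_precision_and_sensitivity(self, rng):
        for _ in range(30):
            ref = rng.integers(0, 3, size=60)
            pred = rng.integers(0, 3, size=60)
            rep = classification_metrics(confusion_matrix(ref, pred, labels=(0, 1, 2)))
            for m in rep.per_class.values():
                if m.f1 is not None:
                    assert min(m.precision, m.sensitivity) - 1e-12 <= m.f1
                    assert m.f1 <= max(m.precision, m.sensitivity) + 1e-12

    def test_undefined_rates_flagged_not_nan(self):
        cm = confusion_matrix([0, 0], [1, 1], labels=(0, 1, 2))
        rep = classification_metrics(cm)
        m = rep.per_class[2]
        assert m.precision is None and "precision" in m.undefined

    def test_empty_matrix_rejected(self):
        with pytest.raises(EmptyMatrix):
            classification_metrics(confusion_matrix([], [], labels=(0, 1)))

    def test_micro_average_pools_counts(self, rng):
        ref = rng.integers(0, 3, size=90)
        pred = rng.integers(0, 3, size=90)
        rep = classification_metrics(confusion_matrix(ref, pred, labels=(0, 1, 2)),
                                     average="micro")
        # micro one-vs-rest precision == sensitivity == overall accuracy
        assert rep.overall.precision == pytest.approx(rep.overall.sensitivity)


def brute_force_ap(dets, gts, thr):
    """Independent PR-curve enumeration: walk detections by score, match
    greedily, accumulate the all-points interpolated area."""
    order = sorted(range(len(dets)), key=lambda i: -dets[i][2])
    matched = set()
    points = []
    tp = fp = 0
    for i in order:
        img, box, _ = dets[i]
        cands = [
            (box_iou(box, g[1]), j)
            for j, g in enumerate(gts)
            if g[0] == img and j not in matched
        ]
        best = max(cands, default=(0.0, -1))
        if best[0] >= thr and best[1] >= 0:
            matched.add(best[1])
            tp += 1
        else:
            fp += 1
        points.append((tp / len(gts), tp / (tp + fp)))
    ap = 0.0
    prev_r = 0.0
    for k, (r, _) in enumerate(points):
        best_p = max(p for rr, p in points[k:])
        ap += (r - prev_r) * best_p
        prev_r = r
    return ap


class TestAveragePrecision:
    def test_perfect_detection_is_one(self):
        gts = [(0, (0, 0, 10, 10)), (0, (20, 0, 30, 10)), (1, (5, 5, 15, 15))]
        dets = [(img, box, 0.9 - 0.1 * i) for i, (img, box) in enumerate(gts)]
        assert average_precision(dets, gts) == pytest.approx(1.0)

    def test_no_detections_is_zero(self):
        assert average_precision([], [(0, (0, 0, 10, 10))]) == 0.0

    def test_no_ground_truth_is_undefined(self):
        assert average_precision([(0, (0, 0, 1, 1), 0.5)], []) is None

    def test_toy_instance_matches_brute_force(self):
        gts = [(0, (0, 0, 10, 10)), (0, (20, 20, 32, 32)), (1, (0, 0, 8, 8))]
        dets = [
            (0, (1, 1, 11, 11), 0.95),   # good match
            (0, (50, 50, 60, 60), 0.9),  # false positive
            (0, (21, 21, 33, 33), 0.6),  # good match
            (1, (4, 4, 12, 12), 0.5),    # borderline overlap
            (1, (0, 0, 9, 9), 0.4),      # duplicate of gt already tried
        ]
        expected = brute_force_ap(dets, gts, 0.5)
        assert average_precision(dets, gts, 0.5) == pytest.approx(expected)

    def test_random_instances_match_brute_force(self, rng):
        for _ in range(25):
            gts = [
                (int(rng.integers(0, 2)), tuple(sorted(rng.uniform(0, 40, 2))) + (0.0, 10.0))
                for _ in range(4)
            ]
            gts = [(im, (x0, 0.0, x1 + 1, 10.0)) for im, (x0, x1, *_rest) in gts]
            dets = [
                (int(rng.integers(0, 2)),
                 (x0 := rng.uniform(0, 40), 0.0, x0 + rng.uniform(1, 12), 10.0),
                 float(rng.random()))
                for _ in range(6)
            ]
            assert average_precision(dets, gts, 0.3) == pytest.approx(
                brute_force_ap(dets, gts, 0.3)
            )

    def test_adding_a_correct_detection_never_lowers_ap(self, rng):
        gts = [(0, (0, 0, 10, 10)), (0, (20, 20, 30, 30))]
        dets = [(0, (1, 1, 11, 11), 0.8), (0, (40, 40, 50, 50), 0.6)]
        base = average_precision(dets, gts)
        more = dets + [(0, (20, 20, 30, 30), 0.5)]
        assert average_precision(more, gts) >= base

    def test_detection_metrics_reports_all_rates(self):
        gts = [(0, (0, 0, 10, 10))]
        dets = [(0, (0, 0, 10, 10), 0.9), (0, (30, 30, 40, 40), 0.8)]
        res = detection_metrics(dets, gts)
        assert res.precision == pytest.approx(0.5)
        assert res.sensitivity == pytest.approx(1.0)
        assert res.ap == pytest.approx(1.0)


class TestROC:
    def test_perfect_separation(self):
        res = roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert res.auc == pytest.approx(1.0)

    def test_random_scores_near_half(self, rng):
        scores = rng.random(1000)
        labels = rng.integers(0, 2, size=1000)
        assert roc_curve(scores, labels).auc == pytest.approx(0.5, abs=0.05)

    def test_auc_equals_pairwise_comparison_oracle(self, rng):
        scores = rng.random(60)
        labels = rng.integers(0, 2, size=60)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum(
            1.0 if p > n_ else 0.5 if p == n_ else 0.0
            for p, n_ in itertools.product(pos, neg)
        )
        expected = wins / (len(pos) * len(neg))
        assert roc_curve(scores, labels).auc == pytest.approx(expected, abs=1e-10)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.random(80)
        labels = rng.integers(0, 2, size=80)
        a = roc_curve(scores, labels).auc
        b = roc_curve(np.exp(3 * scores) + 7, labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(OneClassOnly):
            roc_curve([0.1, 0.2], [1, 1])


class TestICC:
    def test_identical_raters_distinct_subjects(self):
        table = np.array([[1, 1, 1], [2, 2, 2], [3, 3, 3], [2, 2, 2]])
        assert icc(table).value == pytest.approx(1.0)

    def test_random_ratings_near_zero(self, rng):
        table = rng.integers(1, 4, size=(500, 3))
        assert abs(icc(table).value) < 0.1

    def test_fixed_table_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        table = np.array(
            [[1, 2, 2], [2, 2, 3], [3, 3, 3], [1, 1, 2], [2, 3, 3], [1, 1, 1]],
            dtype=float,
        )
        n, k = table.shape
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), k),
                "rater": np.tile(np.arange(k), n),
                "score": table.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        # absolute-agreement, single-rater row (labelled ICC2 or ICC(A,1))
        row = ref[ref["Type"].isin(["ICC2", "ICC(A,1)"])]
        icc2 = float(row["ICC"].iloc[0])
        assert icc(table).value == pytest.approx(icc2, abs=1e-9)

    def test_degenerate_table_flagged_as_perfect(self):
        res = icc(np.full((5, 3), 2.0))
        assert res.value == 1.0 and res.degenerate

    def test_rater_table_from_stage_lists(self):
        table = rater_table([[Stage.I, Stage.II], [Stage.I, Stage.III_IV]])
        assert table.tolist() == [[1, 1], [2, 3]]


class TestChiSquare:
    def test_no_association_gives_zero_statistic(self):
        stat, df, p = chi_square_test([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_hand_evaluated_pearson_statistic(self):
        stat, df, _ = chi_square_test([[20, 10], [10, 20]])
        assert stat == pytest.approx(20 / 3)
        assert df == 1

    def test_agrees_with_direct_formula_on_random_tables(self, rng):
        for _ in range(20):
            t = rng.integers(1, 40, size=(3, 4)).astype(float)
            stat, df, _ = chi_square_test(t)
            exp = np.outer(t.sum(1), t.sum(0)) / t.sum()
            assert stat == pytest.approx(((t - exp) ** 2 / exp).sum())
            assert df == 6

    def test_zero_margin_rejected(self):
        with pytest.raises(ZeroMargin):
            chi_square_test([[0, 0], [5, 5]])
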