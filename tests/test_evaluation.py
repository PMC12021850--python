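"""Metric suite: IoU, confusion metrics, ROC/AUC, regression agreement."""

import numpy as np
import pytest
from scipy import stats

import helpers
from tmhkit import (
    ConfusionMatrix,
    UndefinedMetricError,
    confusion,
    evaluate,
    iou,
    mean_iou,
    regression_agreement,
    roc_auc,
    sensitivity,
    specificity,
    youden,
)


class TestIoU:
    def test_identity(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:5, 2:5] = True
        assert iou(mask, mask) == 1.0

    def test_disjoint(self):
        a = np.zeros((10, 10), dtype=bool)
        b = np.zeros((10, 10), dtype=bool)
        a[0:2, 0:2] = True
        b[5:7, 5:7] = True
        assert iou(a, b) == 0.0

    def test_shifted_block(self):
        a = np.zeros((6, 6), dtype=bool)
        b = np.zeros((6, 6), dtype=bool)
        a[2:4, 2:4] = True
        b[2:4, 3:5] = True
        assert iou(a, b) == pytest.approx(2 / 6)

    def test_empty_conventions(self):
        empty = np.zeros((4, 4), dtype=bool)
        nonempty = ~empty
        assert iou(empty, empty) == 1.0
        assert iou(empty, nonempty) == 0.0

    def test_symmetry_on_random_masks(self, rng):
        for _ in range(25):
            a = helpers.random_mask(rng, allow_empty=True)
            b = helpers.random_mask(rng, allow_empty=True)
            assert iou(a, b) == iou(b, a)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            iou(np.zeros((4, 4), dtype=bool), np.zeros((4, 5), dtype=bool))


class TestMeanIoU:
    def test_known_mixture(self):
        a = np.zeros((4, 4), dtype=bool)
        a[0:2, 0:2] = True
        half = a.copy()
        half[0:2, 2:4] = True  # IoU(a, half) = 2/4
        assert mean_iou([(a, a), (a, half)]) == pytest.approx((1.0 + 0.5) / 2)

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            mean_iou([])

    def test_matches_recomputed_mean(self, rng):
        pairs = [
            (helpers.random_mask(rng), helpers.random_mask(rng)) for _ in range(20)
        ]
        assert mean_iou(pairs) == pytest.approx(np.mean([iou(a, b) for a, b in pairs]))


class TestConfusion:
    def test_all_correct(self):
        true = [True] * 3 + [False] * 7
        cm = confusion(true, true)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (3, 7, 0, 0)

    def test_inverted_predictions(self):
        true = np.array([True] * 3 + [False] * 7)
        cm = confusion(~true, true)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (0, 0, 7, 3)

    def test_matches_exhaustive_tally(self, rng):
        pred = rng.random(200) < 0.4
        true = rng.random(200) < 0.3
        cm = confusion(pred, true)
        tally = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
        for p, t in zip(pred, true):
            tally[("t" if p == t else "f") + ("p" if p else "n")] += 1
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (
            tally["tp"], tally["fp"], tally["tn"], tally["fn"],
        )
        assert cm.total == 200

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            confusion([True], [True, False])


class TestOperatingMetrics:
    def test_perfect_classifier(self):
        cm = ConfusionMatrix(tp=10, fp=0, tn=10, fn=0)
        assert sensitivity(cm) == specificity(cm) == youden(cm) == 1.0

    def test_chance_level(self):
        cm = ConfusionMatrix(tp=5, fp=5, tn=5, fn=5)
        assert youden(cm) == pytest.approx(0.0)

    def test_formula_arithmetic(self):
        cm = ConfusionMatrix(tp=8, fp=1, tn=9, fn=2)
        assert sensitivity(cm) == pytest.approx(0.8)
        assert specificity(cm) == pytest.approx(0.9)
        assert youden(cm) == pytest.approx(0.7)

    def test_zero_denominator_names_empty_class(self):
        with pytest.raises(UndefinedMetricError, match="positive"):
            sensitivity(ConfusionMatrix(tp=0, fp=3, tn=4, fn=0))
        with pytest.raises(UndefinedMetricError, match="negative"):
            specificity(ConfusionMatrix(tp=2, fp=0, tn=0, fn=1))

    def test_youden_bounded_on_random_matrices(self, rng):
        for _ in range(1000):
            tp, fp, tn, fn = rng.integers(0, 50, size=4)
            cm = ConfusionMatrix(int(tp), int(fp), int(tn), int(fn))
            if tp + fn == 0 or tn + fp == 0:
                continue
            assert -1.0 <= youden(cm) <= 1.0


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([0.10, 0.12, 0.30, 0.35], [True, True, False, False])
        assert res.auc == pytest.approx(1.0)

    def test_all_tied_scores_give_chance_auc(self):
        res = roc_auc([0.2] * 6, [True, False, True, False, False, True])
        assert res.auc == pytest.approx(0.5)

    def test_single_class_raises(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([0.1, 0.2], [True, True])

    def test_curve_is_monotone(self, rng):
        tmh = rng.uniform(0.05, 0.4, size=50)
        labels = rng.random(50) < 0.4
        res = roc_auc(tmh, labels)
        assert np.all(np.diff(res.tpr) >= 0) and np.all(np.diff(res.fpr) >= 0)
        assert res.tpr[0] == res.fpr[0] == 0.0
        assert res.tpr[-1] == res.fpr[-1] == 1.0

    def test_trapezoid_equals_pairwise_enumeration(self, rng):
        for _ in range(30):
            n = int(rng.integers(6, 15))
            tmh = np.round(rng.uniform(0.05, 0.4, size=n), 2)  # force ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            res = roc_auc(tmh, labels)
            want = helpers.brute_auc_from_scores(-tmh, labels)
            assert res.auc == pytest.approx(want, abs=1e-9)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        tmh = np.round(rng.uniform(0.05, 0.4, size=120), 2)
        labels = rng.random(120) < 0.35
        assert roc_auc(tmh, labels).auc == pytest.approx(
            roc_auc_score(labels, -tmh), abs=1e-9
        )


class TestRegressionAgreement:
    def test_identity_line(self):
        x = np.linspace(0.1, 0.4, 10)
        res = regression_agreement(x, x)
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(0.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_no_signal_orthogonal_design(self):
        # symmetric x with manual values arranged so the OLS slope is exactly 0
        auto = np.array([0.1, 0.2, 0.3, 0.1, 0.2, 0.3])
        manual = np.array([0.2, 0.3, 0.2, 0.2, 0.1, 0.2])
        res = regression_agreement(auto, manual)
        assert res.slope == pytest.approx(0.0)
        assert res.r_squared == pytest.approx(0.0)

    def test_matches_normal_equations_and_scipy(self, rng):
        auto = rng.uniform(0.1, 0.4, size=8)
        manual = 0.9 * auto + 0.01 + rng.normal(0, 0.01, size=8)
        res = regression_agreement(auto, manual)
        # closed-form normal equations
        X = np.column_stack([auto, np.ones(8)])
        beta = np.linalg.solve(X.T @ X, X.T @ manual)
        assert res.slope == pytest.approx(beta[0], abs=1e-9)
        assert res.intercept == pytest.approx(beta[1], abs=1e-9)
        lin = stats.linregress(auto, manual)
        assert res.r_squared == pytest.approx(lin.rvalue**2, abs=1e-9)

    def test_ssr_over_sst_equals_one_minus_sse_over_sst(self, rng):
        auto = rng.uniform(0.1, 0.4, size=30)
        manual = 1.1 * auto - 0.02 + rng.normal(0, 0.02, size=30)
        res = regression_agreement(auto, manual)
        sse = res.sst - res.ssr
        assert res.r_squared == pytest.approx(1 - sse / res.sst, abs=1e-12)

    def test_r_squared_invariant_to_affine_rescaling_of_x(self, rng):
        auto = rng.uniform(0.1, 0.4, size=25)
        manual = 0.8 * auto + rng.normal(0, 0.02, size=25)
        r2 = regression_agreement(auto, manual).r_squared
        assert regression_agreement(3.7 * auto - 1.2, manual).r_squared == pytest.approx(r2)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            regression_agreement([0.2, 0.2, 0.2], [0.1, 0.2, 0.3])


class TestEvaluate:
    def test_self_consistency_on_ground_truth(self, cohort300):
        subset = cohort300[:60]
        masks = [s.mask for s in subset]
        manual = [s.true_tmh_mm for s in subset]
        report = evaluate(masks, masks, manual, 0.01)
        assert report.mean_iou == 1.0
        assert report.roc.auc == pytest.approx(1.0)
        assert report.regression.r_squared == pytest.approx(1.0)
        assert report.youden == pytest.approx(1.0)
        assert report.n_failed == 0

    def test_youden_equals_sensitivity_plus_specificity_minus_one(self, cohort300):
        subset = cohort300[:60]
        masks = [s.mask for s in subset]
        report = evaluate(masks, masks, [s.true_tmh_mm for s in subset], 0.01)
        assert report.youden == pytest.approx(
            report.sensitivity + report.specificity - 1.0
        )

    def test_shuffled_manual_destroys_association(self, cohort300, rng):
        masks = [s.mask for s in cohort300]
        manual = rng.permutation([s.true_tmh_mm for s in cohort300])
        report = evaluate(masks, masks, manual, 0.01)
        assert report.regression.r_squared < 0.1

    def test_misaligned_records_raise(self):
        with pytest.raises(ValueError):
            evaluate([np.ones((4, 4), bool)], [], [0.2], 0.01)

    def test_report_serializes(self, cohort300, tmp_path):
        import json

        subset = cohort300[:40]
        masks = [s.mask for s in subset]
        report = evaluate(masks, masks, [s.true_tmh_mm for s in subset], 0.01)
        report.to_json(tmp_path / "report.json")
        payload = json.loads((tmp_path / "report.json").read_text())
        assert payload["mean_iou"] == 1.0
        assert set(payload["confusion"]) == {"tp", "fp", "tn", "fn"}
        assert len(payload["roc"]["tpr"]) == len(payload["roc"]["fpr"])
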