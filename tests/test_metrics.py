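"""Confusion-derived metrics, kappa, KL divergence, ROC-AUC, k-fold CV."""

import numpy as np
import pytest

from roughstage.lstm import LSTMConfig
from roughstage.metrics import (
    LabelError,
    MetricWarning,
    basic_metrics,
    confusion,
    evaluate_predictions,
    kappa,
    kl_divergence,
    roc_auc,
    stratified_kfold,
)
from roughstage.rsfas import quantize
from roughstage.synth import generate_synthetic


class TestConfusion:
    def test_perfect_prediction_has_no_errors(self):
        y = np.array([0, 1, 2, 1, 0, 2])
        c = confusion(y, y)
        np.testing.assert_array_equal(c.fp, 0)
        np.testing.assert_array_equal(c.fn, 0)
        assert all(
            c.tp[k] + c.fp[k] + c.fn[k] + c.tn[k] == 6
            for k in range(len(c.classes))
        )

    def test_three_class_hand_tally(self):
        y_true = ["a", "a", "b", "b", "c", "c"]
        y_pred = ["a", "b", "b", "b", "a", "c"]
        c = confusion(y_true, y_pred, classes=("a", "b", "c"))
        # hand tally: a → TP1 FP1 FN1 TN3; b → TP2 FP1 FN0 TN3; c → TP1 FP0 FN1 TN4
        np.testing.assert_array_equal(c.tp, [1, 2, 1])
        np.testing.assert_array_equal(c.fp, [1, 1, 0])
        np.testing.assert_array_equal(c.fn, [1, 0, 1])
        np.testing.assert_array_equal(c.tn, [3, 3, 4])

    def test_empty_inputs_rejected(self):
        with pytest.raises(LabelError):
            confusion([], [])

    def test_unseen_label_rejected(self):
        with pytest.raises(LabelError):
            confusion([0, 1], [0, 7], classes=(0, 1))


class TestBasicMetrics:
    def test_formula_arithmetic(self):
        y_true = [1] * 12 + [0] * 10
        y_pred = [1] * 9 + [0] * 3 + [1] * 1 + [0] * 9
        c = confusion(y_true, y_pred, classes=(0, 1))
        r = basic_metrics(c)
        assert r.precision[1] == pytest.approx(0.9)
        assert r.sensitivity[1] == pytest.approx(0.75)
        assert r.f_score[1] == pytest.approx(2 * 0.675 / 1.65)

    def test_all_correct_gives_ones(self):
        y = [0, 1, 2] * 4
        r = basic_metrics(confusion(y, y))
        assert r.accuracy == 1.0
        assert all(v == 1.0 for v in r.precision.values())
        assert all(v == 1.0 for v in r.f_score.values())

    def test_zero_denominator_returns_zero_with_warning(self):
        # class 2 never predicted and never true-positive
        y_true = [0, 0, 1, 1, 2]
        y_pred = [0, 0, 1, 1, 1]
        with pytest.warns(MetricWarning):
            r = basic_metrics(confusion(y_true, y_pred, classes=(0, 1, 2)))
        assert r.precision[2] == 0.0

    def test_macro_f_bounded_by_class_extremes(self):
        rng = np.random.default_rng(2)
        y_true = rng.integers(0, 3, 300)
        y_pred = np.where(rng.random(300) < 0.7, y_true,
                          rng.integers(0, 3, 300))
        r = basic_metrics(confusion(y_true, y_pred))
        fs = list(r.f_score.values())
        assert min(fs) <= r.macro_f_score <= max(fs)


class TestKappa:
    def test_perfect_agreement_is_one(self):
        y = np.array([0, 1, 2, 3] * 5)
        k, p_o, p_e = kappa(y, y)
        assert k == 1.0 and p_o == 1.0

    def test_kappa_one_iff_accuracy_one(self):
        y = np.array([0, 1, 2, 3] * 5)
        y_off = y.copy()
        y_off[0] = 1
        k, p_o, _ = kappa(y, y_off)
        assert p_o < 1.0 and k < 1.0

    def test_independent_labels_near_zero(self):
        rng = np.random.default_rng(10)
        a = rng.integers(0, 4, 10000)
        b = rng.integers(0, 4, 10000)
        k, _, _ = kappa(a, b)
        assert abs(k) < 0.05

    def test_cross_check_against_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(4)
        a = rng.integers(0, 3, 500)
        b = np.where(rng.random(500) < 0.6, a, rng.integers(0, 3, 500))
        k, _, _ = kappa(a, b)
        assert k == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)

    def test_two_by_two_hand_case(self):
        # contingency: [[20, 5], [10, 15]] → P_o=0.7, P_e=0.5
        y_true = [0] * 25 + [1] * 25
        y_pred = [0] * 20 + [1] * 5 + [0] * 10 + [1] * 15
        k, p_o, p_e = kappa(y_true, y_pred)
        assert p_o == pytest.approx(0.7)
        # marginals: true (0.5, 0.5), pred (0.6, 0.4) → P_e = 0.5·0.6 + 0.5·0.4
        assert p_e == pytest.approx(0.5)
        assert k == pytest.approx((0.7 - 0.5) / 0.5)

    def test_degenerate_expected_agreement_flagged(self):
        with pytest.warns(MetricWarning):
            k, _, _ = kappa([1, 1, 1], [1, 1, 1])
        assert np.isnan(k)


class TestKlDivergence:
    def test_identity_is_zero(self):
        p = np.array([0.2, 0.3, 0.5])
        assert kl_divergence(p, p) == pytest.approx(0.0, abs=1e-15)

    def test_direct_arithmetic(self):
        val = kl_divergence([0.5, 0.5], [0.9, 0.1])
        expected = 0.5 * np.log(0.5 / 0.9) + 0.5 * np.log(0.5 / 0.1)
        assert val == pytest.approx(expected)
        assert val == pytest.approx(0.5108, abs=1e-4)

    def test_nonnegative_on_random_pairs(self):
        rng = np.random.default_rng(6)
        for _ in range(1000):
            k = int(rng.integers(2, 8))
            p = rng.dirichlet(np.ones(k))
            q = rng.dirichlet(np.ones(k))
            assert kl_divergence(p, q) >= 0.0

    def test_zero_handling(self):
        assert kl_divergence([0.0, 1.0], [0.5, 0.5]) == pytest.approx(
            np.log(2.0)
        )
        assert np.isinf(kl_divergence([0.5, 0.5], [1.0, 0.0]))

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            kl_divergence([0.5, 0.6], [0.5, 0.5])

    def test_paper_sign_flag_flips_orientation(self):
        p, q = [0.5, 0.5], [0.9, 0.1]
        assert kl_divergence(p, q, paper_sign=True) == pytest.approx(
            -kl_divergence(p, q)
        )


def pair_counting_auc(y, s):
    """O(n²) oracle: P(score_pos > score_neg) + ½P(tie)."""
    pos = s[np.asarray(y) == 1]
    neg = s[np.asarray(y) == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        per_class, macro = roc_auc(y, scores, classes=(0, 1))
        assert per_class[0] == 1.0 and per_class[1] == 1.0 and macro == 1.0

    def test_uninformative_scores_near_half(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, 5000)
        s = rng.random((5000, 2))
        per_class, macro = roc_auc(y, s, classes=(0, 1))
        assert macro == pytest.approx(0.5, abs=0.03)

    def test_agrees_with_pair_counting_oracle(self):
        rng = np.random.default_rng(13)
        for n in (20, 77, 200):
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                y[0] = 1 - y[0]
            s1 = np.round(rng.random(n), 1)  # coarse → ties exercised
            scores = np.column_stack([1 - s1, s1])
            per_class, _ = roc_auc(y, scores, classes=(0, 1))
            assert per_class[1] == pytest.approx(
                pair_counting_auc(y, s1), abs=1e-12
            )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(14)
        y = rng.integers(0, 2, 300)
        s = rng.random(300)
        base = roc_auc(y, np.column_stack([1 - s, s]), (0, 1))[0][1]
        warped = np.exp(5 * s)
        warped_auc = roc_auc(
            y, np.column_stack([-warped, warped]), (0, 1)
        )[0][1]
        assert warped_auc == pytest.approx(base, abs=1e-12)

    def test_absent_class_flagged_and_excluded(self):
        y = np.array([0, 0, 1, 1])
        s = np.tile([0.3, 0.3, 0.4], (4, 1))
        per_class, macro = roc_auc(y, s, classes=(0, 1, 2))
        assert np.isnan(per_class[2])
        assert not np.isnan(macro)


class TestEvaluatePredictions:
    def test_full_report_serializes(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 4, 200)
        pred = np.where(rng.random(200) < 0.8, y, rng.integers(0, 4, 200))
        scores = rng.dirichlet(np.ones(4), size=200)
        r = evaluate_predictions(y, pred, scores, classes=(0, 1, 2, 3))
        d = r.to_dict()
        assert set(d["per_class"]) == {"0", "1", "2", "3"}
        assert d["kl_divergence"] >= 0.0
        assert -1.0 <= d["kappa"] <= 1.0


class TestStratifiedKfold:
    @pytest.fixture(scope="class")
    def small_ordinal(self):
        is_ = generate_synthetic(120, n_genes=6, effect_size=0.8,
                                 stage_probs=(0.5, 0.5, 0.0, 0.0), seed=20)
        return quantize(is_, 0.97)

    def test_folds_preserve_class_proportions(self, small_ordinal):
        from roughstage.lstm import _extract_xy
        from sklearn.model_selection import StratifiedKFold

        X, y, _, _ = _extract_xy(small_ordinal)
        skf = StratifiedKFold(n_splits=2, shuffle=True, random_state=0)
        totals = np.bincount(y, minlength=2)
        seen = np.zeros(len(y), int)
        for _, te in skf.split(X, y):
            seen[te] += 1
            counts = np.bincount(y[te], minlength=2)
            for c in range(2):
                assert abs(counts[c] - totals[c] / 2) <= 1
        np.testing.assert_array_equal(seen, 1)  # exact partition

    def test_separable_data_scores_high(self, small_ordinal):
        cfg = LSTMConfig(direction="uni", units=8, hidden_layers=1,
                         epochs=15, batch_size=32, learning_rate=0.02,
                         dropout=0.0, optimizer="adam", seed=0)
        accs, mean, sd = stratified_kfold(small_ordinal, cfg, k=2, seed=0)
        assert len(accs) == 2
        assert mean >= 0.9

    def test_class_smaller_than_k_rejected(self, small_ordinal):
        with pytest.raises(ValueError, match="folds"):
            stratified_kfold(small_ordinal, k=100, seed=0)
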