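"""Evaluation statistics against hand-computed oracles and invariants."""

import math

import numpy as np
import pytest

from refined import ValidationError
from refined.metrics import (
    ConfusionCounts,
    PredictionSet,
    auroc,
    bc1_correct,
    bias_angle,
    binomial_ci,
    classification_metrics,
    gap_statistics,
    jab_ci,
    mcnemar,
    nmae,
    nrmse,
    pcc,
    robustness,
    stack_predictions,
)


class TestRegressionMetrics:
    def test_mean_predictor_nrmse_one(self):
        y = np.array([0.2, 0.5, 0.9, 0.4])
        p = PredictionSet(y, np.full(4, y.mean()))
        assert nrmse(p) == pytest.approx(1.0, abs=1e-12)
        assert nmae(p) == pytest.approx(1.0, abs=1e-12)

    def test_perfect_prediction_zero(self):
        y = np.array([0.2, 0.5, 0.9])
        assert nrmse(PredictionSet(y, y)) == 0.0
        assert nmae(PredictionSet(y, y)) == 0.0

    def test_nrmse_hand_value(self):
        p = PredictionSet(np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 1.0]))
        assert nrmse(p) == pytest.approx(1 / math.sqrt(2), abs=1e-10)

    def test_nmae_hand_value(self):
        # sum |y - yhat| = 1, sum |y - ybar| = 2 with ybar = 1
        p = PredictionSet(np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 1.0]))
        assert nmae(p) == pytest.approx(0.5, abs=1e-10)

    def test_constant_observations_rejected(self):
        p = PredictionSet(np.ones(3), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValidationError):
            nrmse(p)

    def test_pcc_affine_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            y = rng.normal(size=10)
            assert pcc(PredictionSet(y, 2 * y + 3)) == pytest.approx(1.0, abs=1e-10)
            assert pcc(PredictionSet(y, -y)) == pytest.approx(-1.0, abs=1e-10)

    def test_pcc_hand_value(self):
        p = PredictionSet(np.array([1.0, 2, 3, 4]), np.array([1.0, 3, 2, 4]))
        assert pcc(p) == pytest.approx(0.8, abs=1e-10)

    def test_mean_predictor_nrmse_property_random(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            y = rng.uniform(size=rng.integers(3, 30))
            if np.std(y) == 0:
                continue
            assert nrmse(PredictionSet(y, np.full(y.size, y.mean()))) == pytest.approx(1.0)


class TestBiasAngle:
    def test_residual_parallel_to_y(self):
        y = np.array([1.0, 2.0, 3.0])
        p = PredictionSet(y, y - 0.5 * y)  # eps = 0.5 y, positive multiple
        bias, theta = bias_angle(p, mode="vector_angle")
        assert theta == pytest.approx(0.0, abs=1e-9)
        assert bias == pytest.approx(0.0, abs=1e-9)

    def test_residual_orthogonal_to_y(self):
        y = np.array([1.0, 0.0])
        eps = np.array([0.0, 1.0])
        p = PredictionSet(y, y - eps)
        _, theta = bias_angle(p, mode="vector_angle")
        assert theta == pytest.approx(90.0, abs=1e-9)

    def test_perfect_prediction_convention(self):
        y = np.array([1.0, 2.0, 3.0])
        bias, theta = bias_angle(PredictionSet(y, y))
        assert (bias, theta) == (0.0, 0.0)

    def test_ols_slope_hand_value(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        eps = 0.5 * (y - y.mean())
        p = PredictionSet(y, y - eps)
        slope, theta = bias_angle(p, mode="ols_slope")
        assert slope == pytest.approx(0.5, abs=1e-10)
        assert theta == pytest.approx(math.degrees(math.atan(0.5)), abs=1e-9)

    def test_unknown_mode(self):
        with pytest.raises(ValidationError):
            bias_angle(PredictionSet(np.array([1.0, 2.0]), np.array([0.5, 1.0])), mode="x")


class TestClassificationMetrics:
    def test_perfect_classifier(self):
        m = classification_metrics(ConfusionCounts(TP=5, TN=5, FP=0, FN=0))
        assert m["accuracy"] == m["precision"] == m["recall"] == m["f1"] == 1.0
        assert m["fpr"] == 0.0

    def test_symmetric_counts(self):
        m = classification_metrics(ConfusionCounts(TP=1, TN=1, FP=1, FN=1))
        assert m["accuracy"] == m["precision"] == m["recall"] == m["f1"] == 0.5

    def test_hand_values(self):
        m = classification_metrics(ConfusionCounts(TP=8, FP=2, FN=4, TN=6))
        assert m["precision"] == pytest.approx(0.8)
        assert m["recall"] == pytest.approx(2 / 3)
        assert m["f1"] == pytest.approx(8 / 11)
        assert m["accuracy"] == pytest.approx(0.7)
        assert m["fpr"] == pytest.approx(0.25)

    def test_zero_denominator_flagged_not_fatal(self):
        m = classification_metrics(ConfusionCounts(TP=0, TN=5, FP=0, FN=0))
        assert math.isnan(m["precision"])
        assert m["accuracy"] == 1.0


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties(self):
        assert auroc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_hand_rank_value(self):
        assert auroc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1]) == pytest.approx(0.75)

    def test_one_class_rejected(self):
        with pytest.raises(ValidationError):
            auroc([1, 1, 1], [0.1, 0.2, 0.3])

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        y = rng.integers(0, 2, size=50)
        y[0], y[1] = 0, 1
        s = rng.uniform(size=50)
        assert auroc(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)


class TestBinomialCI:
    def test_hand_value(self):
        lo, hi = binomial_ci(50, 100)
        from scipy.stats import norm

        z = norm.ppf(0.975)
        assert lo == pytest.approx(0.5 - z * 0.05, abs=1e-10)
        assert hi == pytest.approx(0.5 + z * 0.05, abs=1e-10)

    def test_upper_clipped(self):
        lo, hi = binomial_ci(10, 10)
        assert hi == 1.0

    def test_alpha_one_zero_width(self):
        lo, hi = binomial_ci(3, 10, alpha=1.0)
        assert lo == pytest.approx(hi)

    def test_wilson_option(self):
        lo, hi = binomial_ci(50, 100, method="wilson")
        assert 0.4 < lo < 0.5 < hi < 0.6

    def test_zero_n_rejected(self):
        with pytest.raises(ValidationError):
            binomial_ci(0, 0)


class TestMcNemar:
    def test_symmetric_disagreement(self):
        a = np.array([1, 1, 0, 0, 1, 0], dtype=bool)
        b = np.array([1, 0, 1, 0, 0, 1], dtype=bool)  # b = c = 2
        _, p = mcnemar(a, b)
        assert p == pytest.approx(1.0)

    def test_one_sided_disagreement_exact(self):
        a = np.ones(10, dtype=bool)
        b = np.zeros(10, dtype=bool)  # b=10, c=0
        _, p = mcnemar(a, b)
        assert p == pytest.approx(2 * 0.5**10, abs=1e-12)

    def test_identical_vectors(self):
        a = np.array([1, 0, 1], dtype=bool)
        _, p = mcnemar(a, a)
        assert p == 1.0

    def test_large_discordance_chi_square(self):
        a = np.concatenate([np.ones(40), np.zeros(10)]).astype(bool)
        b = np.concatenate([np.zeros(40), np.ones(10)]).astype(bool)
        stat, p = mcnemar(a, b)
        # continuity-corrected chi-square: (|40-10|-1)^2 / 50
        assert stat == pytest.approx((abs(40 - 10) - 1) ** 2 / 50)
        assert p < 0.05


class TestGapStatistics:
    def test_null_vs_null_small_gap(self, rng):
        y_train = rng.uniform(size=200)
        y_test = rng.uniform(size=60)
        fake_model = rng.choice(y_train, size=60)
        res = gap_statistics(y_test, fake_model, y_train, reps=400, seed=0)
        rec = res.metrics["nrmse"]
        pooled = np.concatenate([rec["model"], rec["null"]])
        assert rec["gap"] < 4 * np.std(pooled)

    def test_perfect_model_centroids_separate(self, rng):
        y_train = rng.uniform(size=200)
        y_test = rng.uniform(size=60)
        res = gap_statistics(y_test, y_test, y_train, reps=300, seed=1)
        lo, hi = res.metrics["nrmse"]["centroids"]
        assert lo < 0.1 and hi > 0.8

    def test_seeded_and_order_invariant(self, rng):
        y_test = rng.uniform(size=30)
        y_pred = y_test + rng.normal(scale=0.1, size=30)
        y_train = rng.uniform(size=100)
        a = gap_statistics(y_test, y_pred, y_train, reps=100, seed=5)
        perm = rng.permutation(30)
        b = gap_statistics(y_test[perm], y_pred[perm], y_train, reps=100, seed=5)
        assert a.metrics["nrmse"]["gap"] == pytest.approx(b.metrics["nrmse"]["gap"], abs=1e-12)

    def test_too_few_reps(self):
        with pytest.raises(ValidationError):
            gap_statistics([0.1, 0.9], [0.1, 0.9], [0.5], reps=1)


class TestRobustness:
    def test_ties_are_not_wins(self, rng):
        y = rng.uniform(size=20)
        p = y + rng.normal(scale=0.1, size=20)
        assert robustness(y, p, p, "nrmse", reps=200, seed=0) == 0.0

    def test_dominant_model(self, rng):
        y = rng.uniform(size=40)
        shuffled = rng.permutation(y)
        frac = robustness(y, y, shuffled, "nrmse", reps=300, seed=1)
        assert frac > 0.95

    def test_order_invariance(self, rng):
        y = rng.uniform(size=25)
        pa = y + rng.normal(scale=0.05, size=25)
        pb = y + rng.normal(scale=0.2, size=25)
        perm = rng.permutation(25)
        f1 = robustness(y, pa, pb, "pcc", reps=150, seed=2)
        f2 = robustness(y[perm], pa[perm], pb[perm], "pcc", reps=150, seed=2)
        assert f1 == f2

    def test_unknown_metric(self):
        with pytest.raises(ValidationError):
            robustness([0.0, 1.0], [0.0, 1.0], [1.0, 0.0], metric="rmse")


class TestJabCI:
    def test_perfect_prediction_degenerate_interval(self, rng):
        y = rng.uniform(size=30)
        lo, hi = jab_ci(y, y, "nrmse", reps=200, seed=0)
        assert (lo, hi) == (0.0, 0.0)

    def test_interval_orders_and_covers(self, rng):
        hits = 0
        for seed in range(10):
            local = np.random.default_rng(seed)
            y = local.uniform(size=80)
            pred = y + local.normal(scale=0.1, size=80)
            point = nrmse(PredictionSet(y, pred))
            lo, hi = jab_ci(y, pred, "nrmse", reps=400, seed=seed)
            assert lo <= hi
            hits += lo <= point <= hi
        assert hits >= 9


class TestBC1:
    def test_zero_residuals_unchanged(self):
        y = np.array([0.1, 0.4, 0.7, 0.9])
        fit = PredictionSet(y, y)
        out = bc1_correct(fit, fit)
        assert np.allclose(out.y_hat, y)

    def test_linear_residuals_slope_removed_on_fitting_set(self, rng):
        y = rng.uniform(size=50)
        eps = 0.3 + 0.4 * y  # exactly linear residual trend
        fit = PredictionSet(y, y - eps)
        out = bc1_correct(fit, fit, use_observed=True)
        slope, _ = bias_angle(out, mode="ols_slope")
        assert slope == pytest.approx(0.0, abs=1e-10)

    def test_proxy_correction_reduces_bias_on_heldout(self, rng):
        n = 400
        y = rng.uniform(size=n)
        eps = 0.2 + 0.5 * y + rng.normal(scale=0.02, size=n)
        preds = y - eps
        half = n // 2
        fit = PredictionSet(y[:half], preds[:half])
        held = PredictionSet(y[half:], preds[half:])
        corrected = bc1_correct(fit, held)
        # with a linear bias eps = a + b*y, the proxy correction shrinks the
        # residual-on-observation slope from b toward b^2
        before = abs(bias_angle(held, mode="ols_slope")[0])
        after = abs(bias_angle(corrected, mode="ols_slope")[0])
        assert after < before

    def test_constant_target_rejected(self):
        fit = PredictionSet(np.ones(4), np.array([0.9, 1.0, 1.1, 1.0]))
        with pytest.raises(ValidationError):
            bc1_correct(fit, fit)


class TestStacking:
    def test_exact_model_gets_full_weight(self, rng):
        y_val = rng.uniform(size=30)
        exact = PredictionSet(y_val, y_val)
        noisy = PredictionSet(y_val, y_val + rng.normal(scale=0.3, size=30))
        stacked, w, w_norm = stack_predictions([exact, noisy], [y_val, noisy.y_hat])
        assert w_norm[0] == pytest.approx(1.0, abs=1e-8)
        assert np.allclose(stacked, y_val, atol=1e-8)

    def test_single_model_normalized_weight_one(self, rng):
        y_val = rng.uniform(size=20)
        model = PredictionSet(y_val, y_val + rng.normal(scale=0.05, size=20))
        _, _, w_norm = stack_predictions([model], [model.y_hat])
        assert w_norm[0] == pytest.approx(1.0)

    def test_stack_beats_best_single_on_validation(self, rng):
        y_val = rng.uniform(size=60)
        models = [
            PredictionSet(y_val, y_val + rng.normal(scale=s, size=60)) for s in (0.05, 0.1, 0.3)
        ]
        stacked_val, _, _ = stack_predictions(models, [m.y_hat for m in models])
        stacked_nrmse = nrmse(PredictionSet(y_val, stacked_val))
        best_single = min(nrmse(m) for m in models)
        assert stacked_nrmse <= best_single + 1e-9

    def test_empty_model_list(self):
        with pytest.raises(ValidationError):
            stack_predictions([], [])
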