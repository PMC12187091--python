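"""Classifier comparison, ROC/DeLong, calibration, decision curves, sample size."""

import numpy as np
import pandas as pd
import pytest

import oracles
from radpath import response


def _planted_data(n=200, sep=2.0, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.binomial(1, 0.5, n)
    X = rng.standard_normal((n, 4))
    X[:, 0] += sep * y
    X[:, 1] += sep * y
    return pd.DataFrame(X), y


class TestCompareClassifiers:
    ALGOS = ("random_forest", "logistic_regression", "svm")

    def test_separable_data_high_auc(self):
        X, y = _planted_data(sep=3.0)
        lb, model = response.compare_classifiers(X, y, self.ALGOS, seed=1)
        assert lb["cv_auc_mean"].max() > 0.95
        assert hasattr(model, "predict_proba")

    def test_shuffled_labels_near_chance(self):
        # average over label shuffles so a single chance correlation
        # cannot dominate
        X, y = _planted_data(sep=3.0, seed=2)
        rng = np.random.default_rng(0)
        aucs = []
        for _ in range(5):
            ys = rng.permutation(y)
            lb, _ = response.compare_classifiers(
                X, ys, ("logistic_regression",), seed=2
            )
            aucs.append(lb["cv_auc_mean"].iloc[0])
        assert abs(np.mean(aucs) - 0.5) < 0.08

    def test_same_seed_identical_leaderboard(self):
        X, y = _planted_data(seed=3)
        lb1, _ = response.compare_classifiers(X, y, self.ALGOS, seed=7)
        lb2, _ = response.compare_classifiers(X, y, self.ALGOS, seed=7)
        pd.testing.assert_frame_equal(lb1, lb2)

    def test_all_seven_slots_runnable(self):
        X, y = _planted_data(n=60, seed=4)
        lb, _ = response.compare_classifiers(X, y, response.CLASSIFIERS, seed=4)
        assert len(lb) == 7

    def test_radscore_properties(self):
        X, y = _planted_data(seed=5)
        _, model = response.compare_classifiers(X, y, ("logistic_regression",), seed=5)
        s = response.radscore(model, X)
        assert np.all((0 <= s) & (s <= 1))
        s2 = response.radscore(model, pd.concat([X.iloc[[0]], X.iloc[[0]]]))
        assert s2[0] == s2[1]
        # responder mean profile scores above non-responder mean profile
        prof = pd.DataFrame(
            [X[y == 1].mean(), X[y == 0].mean()], columns=X.columns
        )
        sp = response.radscore(model, prof)
        assert sp[0] > sp[1]


class TestStepwiseLogistic:
    def test_pure_noise_mostly_empty(self):
        empty = 0
        for rep in range(30):
            rng = np.random.default_rng(rep)
            X = pd.DataFrame(rng.standard_normal((200, 5)), columns=list("abcde"))
            y = rng.binomial(1, 0.5, 200)
            m = response.stepwise_logistic(X, y)
            empty += len(m.terms) == 0
        assert empty >= 24  # >= 80 % intercept-only

    def test_strong_predictor_or_recovered(self):
        rng = np.random.default_rng(1)
        n = 300
        x = rng.standard_normal(n)
        logit = np.log(3.0) * x
        y = rng.binomial(1, 1 / (1 + np.exp(-logit)))
        X = pd.DataFrame({"x": x, "junk": rng.standard_normal(n)})
        m = response.stepwise_logistic(X, y)
        assert "x" in m.terms
        or_x = m.odds_ratios().loc["x", "odds_ratio"]
        assert 2.0 <= or_x <= 4.5

    def test_ordinal_effect_sign_positive(self):
        rng = np.random.default_rng(2)
        n = 400
        stage = rng.integers(0, 4, n).astype(float)
        y = rng.binomial(1, 1 / (1 + np.exp(-(0.6 * stage - 1))))
        X = pd.DataFrame({"n_stage": stage})
        m = response.stepwise_logistic(X, y)
        assert m.result.params["n_stage"] > 0


class TestRocMetrics:
    def test_perfect_scores(self):
        y = np.array([0, 0, 1, 1])
        r = response.roc_metrics(y.astype(float), y)
        assert r.auc == 1.0
        assert (r.sensitivity, r.specificity, r.accuracy) == (1.0, 1.0, 1.0)

    def test_constant_scores_auc_half(self):
        y = np.array([0, 1, 0, 1])
        r = response.roc_metrics(np.full(4, 0.3), y)
        assert r.auc == 0.5

    def test_pair_enumeration_example(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        y = np.array([0, 0, 1, 1])
        r = response.roc_metrics(scores, y)
        assert r.auc == pytest.approx(0.75)

    def test_frozen_threshold_respected(self):
        y = np.array([0, 0, 1, 1, 0, 1])
        s = np.array([0.1, 0.2, 0.9, 0.8, 0.7, 0.3])
        r = response.roc_metrics(s, y, threshold=0.5)
        assert r.threshold == 0.5

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            response.roc_metrics(np.array([0.1, 0.2]), np.array([1, 1]))


class TestDelong:
    def test_identical_models(self):
        y = np.array([1, 1, 0, 0, 1, 0])
        s = np.array([0.9, 0.8, 0.3, 0.2, 0.7, 0.4])
        res = response.delong(s, s, y)
        assert res.z == 0.0 and res.p == 1.0

    def test_perfect_scores_zero_variance(self):
        y = np.array([1, 1, 1, 0, 0, 0])
        res = response.delong(y.astype(float), y.astype(float), y)
        assert res.var_a == 0.0

    def test_six_sample_worked_set_vs_brute_force(self):
        y = np.array([1, 1, 1, 0, 0, 0])
        a = np.array([0.9, 0.8, 0.7, 0.3, 0.2, 0.1])
        b = np.array([0.9, 0.1, 0.7, 0.3, 0.8, 0.2])
        res = response.delong(a, b, y)
        auc_a, auc_b, cov, z = oracles.delong_brute(a, b, y)
        assert res.auc_a == pytest.approx(auc_a, abs=1e-12)
        assert res.auc_b == pytest.approx(auc_b, abs=1e-12)
        assert res.var_a == pytest.approx(cov[0, 0], abs=1e-12)
        assert res.var_b == pytest.approx(cov[1, 1], abs=1e-12)
        assert res.cov_ab == pytest.approx(cov[0, 1], abs=1e-12)
        assert res.z == pytest.approx(z, abs=1e-12)

    def test_auc_matches_roc_metrics_exactly(self, rng):
        y = rng.binomial(1, 0.5, 50)
        y[0], y[1] = 0, 1
        s = rng.random(50)
        res = response.delong(s, s[::-1].copy(), y)
        assert res.auc_a == pytest.approx(response.roc_metrics(s, y).auc, abs=1e-12)


class TestCalibration:
    def test_well_calibrated_probs(self, rng):
        n = 4000
        p = rng.uniform(0.05, 0.95, n)
        y = rng.binomial(1, p)
        chi2, pval, _ = response.hosmer_lemeshow(p, y)
        assert pval > 0.01

    def test_anti_calibrated_probs(self, rng):
        n = 400
        p = rng.uniform(0.1, 0.9, n)
        y = rng.binomial(1, 1 - p)
        chi2, pval, _ = response.hosmer_lemeshow(p, y)
        assert pval < 0.001

    def test_two_group_hand_arithmetic(self):
        # group 1: n=10, E=5, O=3; group 2: n=10, E=2, O=4 (plus a third
        # group to satisfy df) -> contribution (O-E)^2/(E(1-E/n)) each
        probs = np.concatenate(
            [np.full(10, 0.5), np.full(10, 0.2), np.full(10, 0.8)]
        )
        y = np.concatenate(
            [np.repeat([1, 0], [3, 7]), np.repeat([1, 0], [4, 6]), np.repeat([1, 0], [8, 2])]
        )
        chi2, _, _ = response.hosmer_lemeshow(probs, y, groups=3)
        expected = (
            (4 - 2) ** 2 / (2 * (1 - 0.2))
            + (3 - 5) ** 2 / (5 * (1 - 0.5))
            + (8 - 8) ** 2 / (8 * (1 - 0.8))
        )
        assert chi2 == pytest.approx(expected)

    def test_bootstrap_curve_shape(self, rng):
        p = rng.uniform(0.05, 0.95, 300)
        y = rng.binomial(1, p)
        out = response.calibration(p, y, bootstrap=50, seed=0)
        assert len(out["curve"]) <= 10
        assert {"mean_predicted", "observed", "bias_corrected"} <= set(out["curve"])


class TestDecisionCurve:
    def test_perfect_classifier_net_benefit_equals_prevalence(self):
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        dc = response.decision_curve(y.astype(float), y, np.array([0.1, 0.5, 0.9]))
        np.testing.assert_allclose(dc["net_benefit"], y.mean())

    def test_treat_all_zero_at_prevalence_threshold(self):
        y = np.repeat([1, 0], [3, 7])
        dc = response.decision_curve(np.full(10, 0.5), y, np.array([0.3]))
        assert dc["treat_all"].iloc[0] == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        # n=10, prev .3, TP=2 FP=1 at pt=.2 -> NB = .2 - .1*.25 = .175
        y = np.repeat([1, 0], [3, 7])
        probs = np.zeros(10)
        probs[[0, 1]] = 0.9  # two true positives
        probs[[5]] = 0.9  # one false positive
        dc = response.decision_curve(probs, y, np.array([0.2]))
        assert dc["net_benefit"].iloc[0] == pytest.approx(0.175)

    def test_net_benefit_bounded_by_prevalence(self, rng):
        y = rng.binomial(1, 0.4, 200)
        probs = rng.random(200)
        dc = response.decision_curve(probs, y)
        assert (dc["net_benefit"] <= y.mean() + 1e-12).all()


class TestAucSampleSize:
    def test_published_configuration_returns_37(self):
        n = response.auc_sample_size(
            auc_alt=0.80, auc_null=0.50, power=0.90, alpha=0.05, prevalence=0.70
        )
        assert n == 37

    def test_low_power_smaller_n(self):
        lo = response.auc_sample_size(power=0.05)
        hi = response.auc_sample_size(power=0.90)
        assert lo < hi

    def test_monotone_in_power_and_effect(self):
        ns = [response.auc_sample_size(power=p) for p in (0.5, 0.7, 0.8, 0.9, 0.95)]
        assert ns == sorted(ns)
        ns = [
            response.auc_sample_size(auc_alt=a, power=0.9)
            for a in (0.9, 0.8, 0.7, 0.65)
        ]
        assert ns == sorted(ns)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            response.auc_sample_size(auc_alt=0.4)
        with pytest.raises(ValueError):
            response.auc_sample_size(prevalence=1.2)
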