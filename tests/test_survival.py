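"""SMOTE, Cox fits, concordance, Kaplan-Meier/log-rank, optimal cutpoint."""

import numpy as np
import pandas as pd
import pytest

import oracles
from radpath import survival
from radpath.synthetic import CohortSpec, SurvivalModel, generate_cohort


class TestSmote:
    def test_balanced_input_unchanged(self, rng):
        X = rng.standard_normal((20, 3))
        y = np.repeat([0, 1], 10)
        X2, y2 = survival.smote(X, y, seed=0)
        np.testing.assert_array_equal(X2, X)
        np.testing.assert_array_equal(y2, y)

    def test_counts_balanced(self, rng):
        X = rng.standard_normal((100, 4))
        y = np.repeat([0, 1], [80, 20])
        X2, y2 = survival.smote(X, y, seed=1)
        assert (y2 == 0).sum() == 80 and (y2 == 1).sum() == 80

    def test_majority_rows_unchanged_and_first(self, rng):
        X = rng.standard_normal((50, 3))
        y = np.repeat([0, 1], [40, 10])
        X2, _ = survival.smote(X, y, seed=2)
        np.testing.assert_array_equal(X2[:50], X)

    def test_synthetic_points_are_convex_combinations(self, rng):
        X = rng.standard_normal((60, 3))
        y = np.repeat([0, 1], [45, 15])
        X2, y2 = survival.smote(X, y, k=5, seed=3)
        minor = X[y == 1]
        for s in X2[60:]:
            # s = a + lam (b - a) for some minority pair (a, b), lam in [0,1]
            found = False
            for i in range(len(minor)):
                for j in range(len(minor)):
                    if i == j:
                        continue
                    d = minor[j] - minor[i]
                    nz = np.abs(d) > 1e-12
                    if not nz.any():
                        continue
                    lam = (s - minor[i])[nz] / d[nz]
                    if np.allclose(lam, lam[0], atol=1e-8) and -1e-9 <= lam[0] <= 1 + 1e-9:
                        found = True
                        break
                if found:
                    break
            assert found

    def test_small_minority_reduces_k(self, rng):
        X = rng.standard_normal((23, 2))
        y = np.repeat([0, 1], [20, 3])
        with pytest.warns(UserWarning, match="k reduced"):
            X2, y2 = survival.smote(X, y, k=5, seed=4)
        assert (y2 == 1).sum() == 20


class TestFollowUpFilter:
    def test_short_censored_followup_excluded(self):
        df = pd.DataFrame(
            {"time_months": [10.0, 30.0, 10.0], "event": [0, 0, 1]}
        )
        out = survival.follow_up_filter(df, 24.0)
        assert list(out.index) == [1, 2]


class TestCoxFit:
    def test_null_covariate_ci_covers_one(self):
        covered = 0
        for rep in range(60):
            r = np.random.default_rng(rep)
            n = 300
            x = r.standard_normal(n)
            t = r.exponential(10, n)
            e = np.ones(n, int)
            cph = survival.cox_fit(pd.DataFrame({"x": x}), t, e)
            lo, hi = np.exp(cph.confidence_intervals_.iloc[0])
            covered += lo <= 1.0 <= hi
        assert covered / 60 >= 0.85  # ~95 % nominal coverage

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            survival.cox_fit(
                pd.DataFrame({"x": [1.0, 2.0]}), [1.0, 2.0], [0, 0]
            )

    def test_stepwise_drops_noise_keeps_signal(self):
        rng = np.random.default_rng(5)
        n = 400
        x = rng.standard_normal(n)
        noise = rng.standard_normal(n)
        t = rng.exponential(1.0 / (0.05 * np.exp(1.0 * x)))
        cph = survival.cox_fit(
            pd.DataFrame({"signal": x, "noise": noise}), t, np.ones(n, int),
            stepwise=True,
        )
        assert "signal" in cph.params_.index
        assert "noise" not in cph.params_.index


class TestConcordance:
    def test_perfect_risk_ordering(self):
        t = np.array([2.0, 4, 6, 8])
        risk = -t
        assert survival.harrell_c(risk, t, np.ones(4, int)) == 1.0

    def test_constant_risk_half(self):
        t = np.array([2.0, 4, 6, 8])
        assert survival.harrell_c(np.ones(4), t, np.ones(4, int)) == 0.5

    def test_four_subject_hand_enumeration(self):
        t = np.array([2.0, 4, 6, 8])
        e = np.array([1, 1, 0, 1])
        risk = np.array([0.9, 0.7, 0.8, 0.1])
        c = survival.harrell_c(risk, t, e)
        assert c == pytest.approx(oracles.harrell_c_brute(risk, t, e))

    def test_matches_brute_force_random(self, rng):
        t = rng.exponential(5, 40)
        e = rng.binomial(1, 0.7, 40)
        e[0] = 1
        risk = rng.standard_normal(40)
        c = survival.harrell_c(risk, t, e)
        assert c == pytest.approx(oracles.harrell_c_brute(risk, t, e), abs=1e-12)

    def test_matches_lifelines(self, rng):
        from lifelines.utils import concordance_index

        t = rng.exponential(5, 60)
        e = rng.binomial(1, 0.6, 60)
        e[0] = 1
        risk = rng.standard_normal(60)
        ours = survival.harrell_c(risk, t, e)
        ref = concordance_index(t, -risk, e)
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        t = rng.exponential(5, 30)
        e = rng.binomial(1, 0.8, 30)
        e[0] = 1
        risk = rng.standard_normal(30)
        c1 = survival.harrell_c(risk, t, e)
        c2 = survival.harrell_c(np.exp(3 * risk), t, e)
        assert c1 == pytest.approx(c2, abs=1e-12)

    def test_horizon_beyond_all_times_equals_harrell(self, rng):
        t = rng.exponential(5, 30)
        e = rng.binomial(1, 0.7, 30)
        e[0] = 1
        risk = rng.standard_normal(30)
        assert survival.horizon_c(risk, t, e, 1e9) == pytest.approx(
            survival.harrell_c(risk, t, e)
        )

    def test_horizon_before_first_event_rejected(self):
        with pytest.raises(ValueError, match="horizon"):
            survival.horizon_c(
                np.array([1.0, 2.0]), np.array([5.0, 6.0]), np.array([1, 1]), 1.0
            )

    def test_horizon_drops_pairs_anchored_on_late_events(self):
        t = np.array([1.0, 2, 3, 10, 12])
        e = np.ones(5, int)
        risk = np.array([5.0, 4, 3, 2, 1])
        full = survival.harrell_c(risk, t, e)  # 10 comparable pairs
        trunc = survival.horizon_c(risk, t, e, horizon=9.0)
        # anchor at t=10 (1 pair) removed; anchors at 1,2,3 retained
        assert full == 1.0 and trunc == 1.0
        comp_full = oracles.harrell_c_brute(risk, t, e)
        assert comp_full == 1.0


class TestKmLogrank:
    def test_identical_groups_null(self, rng):
        t = rng.exponential(5, 40)
        e = np.ones(40, int)
        t2 = np.concatenate([t, t])
        e2 = np.concatenate([e, e])
        g = np.repeat([0, 1], 40)
        res = survival.km_logrank(t2, e2, g)
        assert res.chi2 == pytest.approx(0.0, abs=1e-10)
        assert res.p == pytest.approx(1.0)

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = np.sort(rng.exponential(5, 20).round(2))
        e = np.ones(20, int)
        res = survival.km_logrank(
            np.concatenate([t, t + 100]), np.ones(40, int), np.repeat([0, 1], 20)
        )
        curve = res.curves[0]
        # step size 1/n at each distinct event time
        surv = curve.set_index("time")["survival"]
        for i, ti in enumerate(np.unique(t)):
            expected = 1 - (t <= ti).sum() / 20
            assert surv.loc[ti] == pytest.approx(expected)

    def test_separated_groups_hand_tables(self):
        t = np.array([1.0, 2, 3, 4, 5, 6])
        e = np.ones(6, int)
        g = np.repeat([0, 1], 3)
        res = survival.km_logrank(t, e, g)
        # hand-computed 2x2 tables at each event time: O-E for group 0 =
        # (1-1/2)+(1-2/5)+(1-1/4)+0-1/3+0-1/2+0-1 -> chi2 via hypergeometric vars
        o_minus_e = (1 - 3 / 6) + (1 - 3 / 5) + (1 - 3 / 4) + (0 - 2 / 3) + (0 - 1 / 2) + 0
        # lifelines computes the same statistic; verify O-E sign logic via chi2 > 3
        assert res.chi2 > 3.0
        assert res.p < 0.1


class TestOptimalCutpoint:
    def test_separated_risk_groups_cut_in_gap(self):
        rng = np.random.default_rng(3)
        n = 200
        group = rng.binomial(1, 0.5, n)
        score = np.where(group, 2.0, 0.0) + 0.1 * rng.standard_normal(n)
        lam = np.where(group, 0.25, 0.05)
        t = rng.exponential(1 / lam)
        cut, chi2, p = survival.optimal_cutpoint(score, t, np.ones(n, int))
        assert 0.5 < cut < 1.5
        assert p < 1e-6

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            survival.optimal_cutpoint(
                np.ones(20), np.arange(1.0, 21.0), np.ones(20, int)
            )

    def test_minprop_honored(self, rng):
        score = rng.standard_normal(60)
        t = rng.exponential(5, 60)
        cut, _, _ = survival.optimal_cutpoint(score, t, np.ones(60, int), minprop=0.2)
        frac_high = (score > cut).mean()
        assert 0.2 <= frac_high <= 0.8
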