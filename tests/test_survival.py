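"""Statistical core: Cox partial likelihood, PH fitting with stepwise
selection, concordance, Kaplan-Meier / Nelson-Aalen, logrank and maximally
selected cut-offs — each checked against an independent oracle."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from radsurv.survival import (ConvergenceError, concordance_index,
                              cox_partial_loglik, cox_partial_loglik_grad,
                              fit_cox, kaplan_meier, logrank_test,
                              nelson_aalen, optimal_cutoff, stepwise_select)


def brute_force_loglik(eta, time, event):
    """Term-by-term partial log-likelihood over explicit risk sets."""
    total = 0.0
    for i in range(len(time)):
        if event[i] == 1:
            risk_set = [j for j in range(len(time)) if time[j] >= time[i]]
            total += eta[i] - np.log(np.sum(np.exp(eta[risk_set])))
    return total


class TestCoxPartialLoglik:
    def test_symmetric_risk_set(self):
        # two subjects with equal risk, one event at the earlier time
        val = cox_partial_loglik([0.3, 0.3], [1.0, 2.0], [1, 0])
        assert val == pytest.approx(math.log(0.5))

    def test_flat_risks_closed_form(self):
        n = 7
        val = cox_partial_loglik(np.zeros(n), np.arange(1.0, n + 1),
                                 np.ones(n, int))
        assert val == pytest.approx(-math.log(math.factorial(n)))

    def test_mixed_censoring_matches_enumeration(self, rng):
        time = np.array([3.0, 1.0, 4.0, 1.5, 2.5])
        event = np.array([1, 0, 1, 1, 0])
        eta = rng.normal(size=5)
        assert cox_partial_loglik(eta, time, event) == pytest.approx(
            brute_force_loglik(eta, time, event))

    def test_tied_times_breslow(self, rng):
        time = np.array([2.0, 2.0, 2.0, 5.0, 1.0])
        event = np.array([1, 1, 0, 1, 0])
        eta = rng.normal(size=5)
        # Breslow: each tied event sees the full risk set at its time
        expected = brute_force_loglik(eta, time, event)
        assert cox_partial_loglik(eta, time, event) == pytest.approx(expected)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError):
            cox_partial_loglik([0.0, 0.0], [1.0, 2.0], [0, 0])

    def test_gradient_matches_finite_differences(self, rng):
        time = rng.exponential(5, 9) + 0.1
        event = rng.integers(0, 2, 9)
        event[0] = 1
        eta = rng.normal(size=9)
        grad = cox_partial_loglik_grad(eta, time, event)
        eps = 1e-6
        for k in range(9):
            up, dn = eta.copy(), eta.copy()
            up[k] += eps
            dn[k] -= eps
            fd = (cox_partial_loglik(up, time, event)
                  - cox_partial_loglik(dn, time, event)) / (2 * eps)
            assert grad[k] == pytest.approx(fd, abs=1e-5)


def _simulate_ph(rng, n, beta, censor_scale=40.0):
    x = rng.integers(0, 2, n).astype(float)
    t_star = rng.exponential(1.0 / (0.05 * np.exp(beta * x)))
    c = rng.exponential(censor_scale, n)
    return x[:, None], np.minimum(t_star, c), (t_star <= c).astype(int)


class TestFitCox:
    def test_hazard_ratio_is_exp_beta(self, rng):
        X, t, e = _simulate_ph(rng, 200, math.log(2))
        fit = fit_cox(X, t, e, names=["grp"])
        assert fit.hazard_ratios["grp"] == pytest.approx(
            math.exp(fit.coefficients["grp"]))

    def test_recovers_true_coefficient(self, rng):
        X, t, e = _simulate_ph(rng, 500, math.log(2))
        fit = fit_cox(X, t, e, names=["grp"])
        se = fit.standard_errors["grp"]
        assert abs(fit.coefficients["grp"] - math.log(2)) < 3 * se

    def test_agrees_with_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        X, t, e = _simulate_ph(rng, 300, 0.8)
        X = np.column_stack([X, rng.normal(size=300)])
        fit = fit_cox(X, t, e, names=["a", "b"])
        df = pd.DataFrame({"a": X[:, 0], "b": X[:, 1], "t": t, "e": e})
        cph = lifelines.CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert fit.coefficients["a"] == pytest.approx(
            cph.params_["a"], abs=1e-4)
        assert fit.coefficients["b"] == pytest.approx(
            cph.params_["b"], abs=1e-4)

    def test_constant_covariate_rejected(self):
        X = np.ones((20, 1))
        with pytest.raises(ValueError, match="constant"):
            fit_cox(X, np.arange(1.0, 21), np.ones(20, int))

    def test_separation_flagged(self):
        # monotone likelihood: all group-1 events precede every group-0 time
        t = np.concatenate([np.arange(1.0, 11), np.arange(20.0, 30)])
        e = np.ones(20, int)
        X = np.concatenate([np.ones(10), np.zeros(10)])[:, None]
        with pytest.raises(ConvergenceError):
            fit_cox(X, t, e)


class TestStepwise:
    def test_strong_predictor_kept_noise_dropped(self, rng):
        n = 400
        x_sig = rng.integers(0, 2, n).astype(float)
        noise = rng.normal(size=(n, 3))
        t_star = rng.exponential(1.0 / (0.05 * np.exp(1.2 * x_sig)))
        c = rng.exponential(40.0, n)
        t, e = np.minimum(t_star, c), (t_star <= c).astype(int)
        X = np.column_stack([x_sig, noise])
        fit = stepwise_select(X, t, e, names=["sig", "n1", "n2", "n3"])
        assert "sig" in fit.selected
        assert all(p < 0.05 for p in fit.p_values.values())

    def test_single_significant_covariate_selected(self, rng):
        X, t, e = _simulate_ph(rng, 400, 1.0)
        fit = stepwise_select(X, t, e, names=["grp"])
        assert fit.selected == ["grp"]

    def test_all_noise_can_return_empty(self, rng):
        # with pure-noise covariates the selection is usually empty; the
        # empty fit carries no coefficients and flags the concordance as
        # not calculable
        empties = 0
        for seed in range(8):
            r = np.random.default_rng(seed)
            n = 120
            X = r.normal(size=(n, 3))
            t = r.exponential(20.0, n) + 0.01
            e = r.integers(0, 2, n)
            fit = stepwise_select(X, t, e)
            if fit.is_empty:
                empties += 1
                assert fit.selected == [] and fit.coefficients == {}
        assert empties >= 5  # ~0.86 expected per replicate at alpha 0.05


def brute_force_cindex(pred_time, time, event, tie_half=True):
    num = den = 0.0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if event[i] == 1 and time[j] > time[i]:
                den += 1
                if pred_time[i] < pred_time[j]:
                    num += 1
                elif tie_half and pred_time[i] == pred_time[j]:
                    num += 0.5
    return num / den


class TestConcordance:
    def test_perfect_prediction(self):
        t = np.array([3.0, 1.0, 4.0, 2.0])
        assert concordance_index(t, t, np.ones(4, int), kind="time") == 1.0

    def test_reversed_prediction(self):
        t = np.array([3.0, 1.0, 4.0, 2.0])
        assert concordance_index(-t, t, np.ones(4, int), kind="time") == 0.0

    def test_matches_pair_enumeration(self, rng):
        for _ in range(30):
            n = int(rng.integers(6, 13))
            t = np.round(rng.exponential(10, n), 1) + 0.1
            e = rng.integers(0, 2, n)
            if ((e == 1)[:, None] & (t[None, :] > t[:, None])).sum() == 0:
                continue
            pred = np.round(rng.normal(size=n), 1)  # rounding forces ties
            got = concordance_index(pred, t, e, kind="time")
            assert got == pytest.approx(brute_force_cindex(pred, t, e))

    def test_strict_mode_scores_ties_zero(self):
        t = np.array([1.0, 2.0, 3.0])
        e = np.ones(3, int)
        pred = np.array([5.0, 5.0, 5.0])
        assert concordance_index(pred, t, e, kind="time",
                                 tie_policy="strict") == 0.0
        assert concordance_index(pred, t, e, kind="time") == 0.5

    def test_risk_kind_flips_sign(self, rng):
        t = rng.exponential(10, 20) + 0.1
        e = np.ones(20, int)
        risk = rng.normal(size=20)
        assert concordance_index(risk, t, e, kind="risk") == pytest.approx(
            concordance_index(-risk, t, e, kind="time"))

    def test_complement_symmetry_without_ties(self, rng):
        t = rng.exponential(10, 25) + 0.1
        e = rng.integers(0, 2, 25)
        e[:3] = 1
        f = rng.normal(size=25)
        c1 = concordance_index(f, t, e, kind="time")
        c2 = concordance_index(-f, t, e, kind="time")
        assert c1 + c2 == pytest.approx(1.0)

    def test_no_permissible_pairs_rejected(self):
        with pytest.raises(ValueError):
            concordance_index([1.0, 2.0], [5.0, 3.0], [0, 0])


class TestKaplanMeierNelsonAalen:
    def test_km_hand_worked(self):
        # events at 1 and 2, censored at 1.5 and 3
        curve = kaplan_meier([1.0, 1.5, 2.0, 3.0], [1, 0, 1, 0])
        assert curve.times.tolist() == [1.0, 2.0]
        assert curve.survival[0] == pytest.approx(3 / 4)
        assert curve.survival[1] == pytest.approx(3 / 4 * 1 / 2)  # = 3/8

    def test_km_all_censored_identity(self):
        curve = kaplan_meier([1.0, 2.0, 3.0], [0, 0, 0])
        assert curve.evaluate([0.5, 1.5, 10.0]).tolist() == [1.0, 1.0, 1.0]

    def test_km_single_subject(self):
        curve = kaplan_meier([5.0], [1])
        assert curve.evaluate([4.9, 5.0, 6.0]).tolist() == [1.0, 0.0, 0.0]

    def test_na_no_events_zero(self):
        curve = nelson_aalen([2.0, 3.0], [0, 0])
        assert curve.evaluate([1.0, 10.0]).tolist() == [0.0, 0.0]

    def test_na_two_subjects(self):
        curve = nelson_aalen([1.0, 2.0], [1, 0])
        assert curve.evaluate([1.0])[0] == pytest.approx(0.5)

    def test_na_matches_enumeration(self):
        time = np.array([1.0, 2.0, 2.0, 3.0, 4.0])
        event = np.array([1, 1, 0, 0, 1])
        curve = nelson_aalen(time, event)
        # hand enumeration of d_l / Y_l: 1/5 at t=1, 1/4 at t=2, 1/1 at t=4
        assert curve.chf == pytest.approx([1 / 5, 1 / 5 + 1 / 4,
                                           1 / 5 + 1 / 4 + 1.0])

    def test_km_approx_exp_neg_chf_small_increments(self, rng):
        time = rng.exponential(50, 400) + 0.1
        event = rng.integers(0, 2, 400)
        km = kaplan_meier(time, event)
        na = nelson_aalen(time, event)
        small = na.deaths / na.at_risk < 0.1
        approx = np.exp(-na.chf[small])
        assert np.allclose(km.survival[small], approx, rtol=0.05)

    def test_agrees_with_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        t = rng.exponential(10, 60) + 0.1
        e = rng.integers(0, 2, 60)
        e[0] = 1
        na_ref = lifelines.NelsonAalenFitter().fit(t, e)
        ours = nelson_aalen(t, e)
        grid = ours.times
        ref_vals = na_ref.cumulative_hazard_at_times(grid).to_numpy()
        assert np.allclose(ours.chf, ref_vals, atol=1e-8)


class TestLogrank:
    def test_identical_groups_null(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 0, 1, 1])
        stat, p = logrank_test(t, e, t, e)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_fully_separated_groups_significant(self):
        t1 = np.arange(1.0, 13)
        t2 = np.arange(50.0, 62)
        stat, p = logrank_test(t1, np.ones(12, int), t2, np.ones(12, int))
        assert stat > sps.chi2.ppf(0.95, 1)
        assert p < 0.05

    def test_agrees_with_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        from lifelines.statistics import logrank_test as ll_logrank

        t1 = rng.exponential(10, 30) + 0.1
        t2 = rng.exponential(14, 25) + 0.1
        e1 = rng.integers(0, 2, 30)
        e2 = rng.integers(0, 2, 25)
        e1[0] = 1
        stat, p = logrank_test(t1, e1, t2, e2)
        ref = ll_logrank(t1, t2, event_observed_A=e1, event_observed_B=e2)
        assert stat == pytest.approx(ref.test_statistic, rel=1e-6)
        assert p == pytest.approx(ref.p_value, rel=1e-6)

    def test_p_value_close_to_permutation_null(self, rng):
        t1 = rng.exponential(10, 15) + 0.1
        t2 = rng.exponential(18, 15) + 0.1
        e1 = np.ones(15, int)
        e2 = np.ones(15, int)
        stat, p = logrank_test(t1, e1, t2, e2)
        t_all = np.concatenate([t1, t2])
        count = 0
        reps = 400
        for _ in range(reps):
            perm = rng.permutation(30)
            s, _ = logrank_test(t_all[perm[:15]], e1, t_all[perm[15:]], e2)
            count += s >= stat
        mc_p = count / reps
        assert abs(p - mc_p) < 3 * math.sqrt(max(mc_p, 0.01) * 0.99 / reps) + 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([], [], [1.0], [1])


class TestOptimalCutoff:
    def test_perfect_binary_split(self):
        values = np.array([0.0] * 10 + [1.0] * 10)
        time = np.concatenate([np.arange(1.0, 11), np.arange(40.0, 50)])
        event = np.ones(20, int)
        res = optimal_cutoff(values, time, event)
        assert res.threshold == pytest.approx(0.5)
        assert res.n_low == res.n_high == 10

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            optimal_cutoff(np.ones(10), np.arange(1.0, 11), np.ones(10, int))

    def test_matches_exhaustive_scan(self, rng):
        n = 20
        values = rng.normal(size=n)
        time = rng.exponential(10, n) + 0.1
        event = rng.integers(0, 2, n)
        event[:4] = 1
        res = optimal_cutoff(values, time, event, min_group_fraction=0.1)
        # independent scan using the pairwise logrank test directly
        best_stat, best_thr = -1.0, None
        uniq = np.sort(np.unique(values))
        min_n = int(np.ceil(0.1 * n))
        for lo, hi in zip(uniq[:-1], uniq[1:]):
            thr = (lo + hi) / 2
            low = values <= thr
            if low.sum() < min_n or (~low).sum() < min_n:
                continue
            stat, _ = logrank_test(time[low], event[low],
                                   time[~low], event[~low])
            if stat > best_stat:
                best_stat, best_thr = stat, thr
        assert res.threshold == pytest.approx(best_thr)
        assert res.logrank_statistic == pytest.approx(best_stat)
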