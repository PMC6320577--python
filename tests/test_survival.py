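"""Survival stack tests: hand calculations, oracles, and lifelines cross-checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from erlangen import survival as sv
from erlangen.simulate import HazardSpec, sample_progression_time

from conftest import surv_frame


# ---------------------------------------------------------------------------
# Kaplan-Meier / Nelson-Aalen
# ---------------------------------------------------------------------------

class TestEstimators:
    def test_km_hand_example(self):
        km = sv.km_estimator([1, 2, 3], [1, 1, 0])
        np.testing.assert_allclose(km.event_times, [1, 2])
        np.testing.assert_allclose(km.estimate, [2 / 3, 1 / 3])
        assert km(0.5) == 1.0
        assert km(3.0) == pytest.approx(1 / 3)

    def test_na_hand_example(self):
        na = sv.na_estimator([1, 2, 3], [1, 1, 0])
        np.testing.assert_allclose(na.estimate, [1 / 3, 1 / 3 + 1 / 2])

    def test_no_events(self):
        km = sv.km_estimator([1, 2, 3], [0, 0, 0])
        assert km(np.array([0.5, 2.5, 10.0])).tolist() == [1.0, 1.0, 1.0]
        na = sv.na_estimator([1, 2, 3], [0, 0, 0])
        assert na(5.0) == 0.0

    def test_all_events_distinct_times(self):
        n = 5
        km = sv.km_estimator(np.arange(1, n + 1), np.ones(n))
        # closed form: S after the k-th of n distinct events is (n-k)/n
        np.testing.assert_allclose(km.estimate, (n - np.arange(1, n + 1)) / n)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            sv.km_estimator([], [])
        with pytest.raises(ValueError):
            sv.km_estimator([0.0, 1.0], [1, 1])

    def test_against_lifelines(self):
        from lifelines import KaplanMeierFitter, NelsonAalenFitter
        rng = np.random.default_rng(0)
        t = rng.exponential(5, 300)
        c = rng.uniform(1, 10, 300)
        time, event = np.minimum(t, c), (t <= c).astype(int)
        km = sv.km_estimator(time, event)
        kmf = KaplanMeierFitter().fit(time, event)
        np.testing.assert_allclose(km(km.event_times),
                                   kmf.predict(km.event_times).to_numpy(),
                                   rtol=1e-10)
        na = sv.na_estimator(time, event)
        naf = NelsonAalenFitter(nelson_aalen_smoothing=False).fit(time, event)
        np.testing.assert_allclose(na(na.event_times),
                                   naf.cumulative_hazard_at_times(na.event_times),
                                   rtol=1e-10)

    def test_neg_log_km_dominates_na(self):
        """-ln S_KM(t) >= H_NA(t), nearly equal for many small increments."""
        rng = np.random.default_rng(1)
        t = rng.exponential(5, 2000)
        c = rng.uniform(1, 20, 2000)
        time, event = np.minimum(t, c), (t <= c).astype(int)
        km = sv.km_estimator(time, event)
        na = sv.na_estimator(time, event)
        grid = np.linspace(0.5, 10, 40)
        neg_log_s = -np.log(km(grid))
        h = na(grid)
        assert np.all(neg_log_s >= h - 1e-12)
        np.testing.assert_allclose(neg_log_s, h, rtol=0.02)

    def test_risk_table_intervals(self):
        km = sv.km_estimator([0.5, 1.5, 2.5, 3.5, 5.0], [1, 0, 1, 0, 1])
        table = km.risk_table(interval=2.0)
        assert table.loc[0, "n_at_risk"] == 5
        assert table.loc[0, "n_events"] == 1
        assert table.loc[0, "n_censored"] == 1
        assert table.loc[1, "n_at_risk"] == 3


# ---------------------------------------------------------------------------
# Weighted log-rank family
# ---------------------------------------------------------------------------

class TestWeightedLogrank:
    def test_identical_groups_give_zero(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 1, 0, 1]
        res = sv.weighted_logrank(t + t, e + e, [0] * 4 + [1] * 4)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_two_sample_equals_squared_standardized_oe(self):
        """With k=2 the chi-square is (O-E)^2 / Var for either group."""
        rng = np.random.default_rng(4)
        t = np.concatenate([rng.exponential(5, 60), rng.exponential(2, 60)])
        e = np.ones(120, dtype=int)
        g = np.repeat([0, 1], 60)
        res = sv.weighted_logrank(t, e, g)
        # independent O-E computation from scratch
        oe, var = 0.0, 0.0
        for tk in np.unique(t[e == 1]):
            at = t >= tk
            n, n0 = at.sum(), (at & (g == 0)).sum()
            d = ((t == tk) & (e == 1)).sum()
            d0 = ((t == tk) & (e == 1) & (g == 0)).sum()
            oe += d0 - d * n0 / n
            if n > 1:
                var += d * (n - d) / (n - 1) * (n0 / n) * (1 - n0 / n)
        assert res.statistic == pytest.approx(oe**2 / var, rel=1e-10)
        assert res.df == 1

    def test_against_lifelines_all_weights(self):
        from lifelines.statistics import multivariate_logrank_test
        rng = np.random.default_rng(5)
        parts = [(rng.exponential(1 / lam, 80), rng.uniform(2, 12, 80))
                 for lam in (0.05, 0.1, 0.2)]
        t = np.concatenate([np.minimum(a, b) for a, b in parts])
        e = np.concatenate([(a <= b).astype(int) for a, b in parts])
        g = np.repeat([0, 1, 2], 80)
        ours = sv.weighted_logrank(t, e, g)
        ref = multivariate_logrank_test(t, g, e)
        assert ours.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
        ours_w = sv.weighted_logrank(t, e, g, "wilcoxon")
        ref_w = multivariate_logrank_test(t, g, e, weightings="wilcoxon")
        assert ours_w.statistic == pytest.approx(ref_w.test_statistic, rel=1e-9)

    def test_trend_detects_ordered_hazards(self):
        rng = np.random.default_rng(6)
        parts = [(rng.exponential(1 / lam, 200), rng.uniform(2, 12, 200))
                 for lam in (0.04, 0.12, 0.4)]
        t = np.concatenate([np.minimum(a, b) for a, b in parts])
        e = np.concatenate([(a <= b).astype(int) for a, b in parts])
        g = np.repeat([0, 1, 2], 200)
        res = sv.weighted_logrank(t, e, g, "trend")
        assert res.df == 1
        assert res.statistic > 0
        assert res.p_value < 1e-6

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            sv.weighted_logrank([1, 2], [1, 1], [0, 0])


# ---------------------------------------------------------------------------
# Episode splitting
# ---------------------------------------------------------------------------

def _mci_frame(rows):
    return pd.DataFrame(rows, columns=["id", "followup_years", "event",
                                       "es_category3"])


class TestEpisodeSplit:
    def test_possible_long_followup(self):
        epi = sv.episode_split(_mci_frame([("a", 5.0, 1, "possible")]))
        assert len(epi) == 2
        r0, r1 = epi.iloc[0], epi.iloc[1]
        assert (r0.start, r0.stop, r0.event, r0.possible_early, r0.possible_late) \
            == (0.0, 3.0, 0, 1, 0)
        assert (r1.start, r1.stop, r1.event, r1.possible_early, r1.possible_late) \
            == (3.0, 5.0, 1, 0, 1)

    def test_improbable_long_followup(self):
        epi = sv.episode_split(_mci_frame([("a", 5.0, 0, "improbable")]))
        assert len(epi) == 2
        assert epi[["possible_early", "possible_late", "probable"]].to_numpy().sum() == 0

    def test_short_followup_single_row(self):
        epi = sv.episode_split(_mci_frame([("a", 2.0, 1, "possible")]))
        assert len(epi) == 1
        assert (epi.iloc[0].possible_early, epi.iloc[0].event) == (1, 1)

    def test_event_at_split_stays_early(self):
        epi = sv.episode_split(_mci_frame([("a", 3.0, 1, "possible")]))
        assert len(epi) == 1
        assert (epi.iloc[0].stop, epi.iloc[0].event, epi.iloc[0].possible_early) \
            == (3.0, 1, 1)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_conserves_exposure_and_events(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        frame = _mci_frame([
            (i, rng.uniform(0.1, 10), int(rng.uniform() < 0.5),
             rng.choice(["improbable", "possible", "probable"]))
            for i in range(n)
        ])
        epi = sv.episode_split(frame)
        assert (epi.stop - epi.start).sum() == pytest.approx(
            frame.followup_years.sum(), rel=1e-12)
        assert epi.event.sum() == frame.event.sum()
        # rows of one subject partition (0, followup]
        for sid, g in epi.groupby("id"):
            g = g.sort_values("start")
            assert g.iloc[0].start == 0.0
            np.testing.assert_allclose(g.start.to_numpy()[1:],
                                       g.stop.to_numpy()[:-1])

    def test_invalid_followup_raises(self):
        with pytest.raises(ValueError):
            sv.episode_split(_mci_frame([("a", -1.0, 0, "possible")]))


# ---------------------------------------------------------------------------
# Cox model
# ---------------------------------------------------------------------------

class TestCoxModel:
    def test_hand_example_matches_brute_force_root(self):
        """4-subject example: NR solution equals the partial-likelihood root."""
        epi = surv_frame([1, 2, 3, 4], [1, 1, 1, 0], x=[1, 0, 1, 0])
        fit = sv.CoxModel(epi, ["x"]).fit()

        # independent oracle: the partial likelihood written out by hand
        # risk sets: t=1 {1,2,3,4}, t=2 {2,3,4}, t=3 {3,4}
        def neg_ll(b):
            eb = np.exp(b)
            return -(np.log(eb / (2 * eb + 2)) + np.log(1 / (eb + 2))
                     + np.log(eb / (eb + 1)))
        root = optimize.minimize_scalar(neg_ll, bounds=(-5, 5), method="bounded")
        assert fit.params[0] == pytest.approx(root.x, abs=1e-6)
        assert fit.llf == pytest.approx(-neg_ll(root.x), abs=1e-9)

    def test_hand_example_matches_lifelines(self):
        from lifelines import CoxPHFitter
        epi = surv_frame([1, 2, 3, 4], [1, 1, 1, 0], x=[1, 0, 1, 0])
        fit = sv.CoxModel(epi, ["x"]).fit()
        cph = CoxPHFitter().fit(
            pd.DataFrame(dict(T=[1, 2, 3, 4.], E=[1, 1, 1, 0], x=[1, 0, 1, 0.])),
            "T", "E")
        assert fit.params[0] == pytest.approx(cph.params_.iloc[0], abs=1e-5)
        assert fit.bse[0] == pytest.approx(cph.standard_errors_.iloc[0], rel=1e-4)

    def test_null_covariate_recovers_zero(self):
        rng = np.random.default_rng(8)
        n = 2000
        x = rng.standard_normal(n)
        t = rng.exponential(10, n)
        c = rng.uniform(2, 12, n)
        fit = sv.CoxModel(surv_frame(np.minimum(t, c), (t <= c).astype(int), x=x),
                          ["x"]).fit()
        assert abs(fit.params[0]) < 2 * fit.bse[0]

    def test_hr2_parameter_recovery(self):
        rng = np.random.default_rng(9)
        n = 5000
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1 / (0.1 * np.exp(np.log(2) * x)))
        c = rng.uniform(2, 12, n)
        fit = sv.CoxModel(surv_frame(np.minimum(t, c), (t <= c).astype(int), x=x),
                          ["x"]).fit()
        assert 1.9 <= np.exp(fit.params[0]) <= 2.1

    def test_breslow_efron_agree_without_ties(self):
        rng = np.random.default_rng(10)
        n = 300
        x = rng.standard_normal(n)
        t = rng.exponential(5, n)
        epi = surv_frame(t, np.ones(n, int), x=x)
        fb = sv.CoxModel(epi, ["x"], ties="breslow").fit()
        fe = sv.CoxModel(epi, ["x"], ties="efron").fit()
        assert abs(fb.params[0] - fe.params[0]) < 1e-8

    def test_efron_ties_match_lifelines(self):
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(11)
        n = 400
        x = rng.integers(0, 2, n).astype(float)
        t = np.ceil(rng.exponential(1 / (0.2 * np.exp(0.7 * x))))  # heavy ties
        c = rng.uniform(2, 12, n)
        time, ev = np.minimum(t, np.ceil(c)), (t <= c).astype(int)
        time = np.maximum(time, 1.0)
        fit = sv.CoxModel(surv_frame(time, ev, x=x), ["x"], ties="efron").fit()
        cph = CoxPHFitter().fit(pd.DataFrame(dict(T=time, E=ev, x=x)), "T", "E")
        assert fit.params[0] == pytest.approx(cph.params_.iloc[0], abs=1e-5)
        assert fit.llf == pytest.approx(cph.log_likelihood_, abs=1e-6)

    def test_time_varying_episodes_match_lifelines(self):
        """Split-episode ECM coefficients agree with lifelines CoxTimeVaryingFitter."""
        from lifelines import CoxTimeVaryingFitter
        rng = np.random.default_rng(12)
        n = 500
        cat = rng.choice(["improbable", "possible", "probable"], n)
        spec = HazardSpec()
        t = np.array([sample_progression_time(c, spec, rng) for c in cat])
        c_ = rng.uniform(2, 12, n)
        frame = pd.DataFrame(dict(
            id=np.arange(n), followup_years=np.minimum(t, c_),
            event=(t <= c_).astype(int), es_category3=cat))
        epi = sv.episode_split(frame)
        cols = ["possible_early", "possible_late", "probable"]
        fit = sv.CoxModel(epi, cols).fit()
        ctv = CoxTimeVaryingFitter()
        ctv.fit(epi[["id", "start", "stop", "event", *cols]],
                id_col="id", start_col="start", stop_col="stop", event_col="event")
        np.testing.assert_allclose(fit.params, ctv.params_.to_numpy(), atol=1e-4)

    def test_collinear_covariates_raise(self):
        rng = np.random.default_rng(13)
        x = rng.standard_normal(100)
        epi = surv_frame(rng.exponential(5, 100), np.ones(100, int), x=x, x2=2 * x)
        with pytest.raises(sv.SingularInformationError):
            sv.CoxModel(epi, ["x", "x2"]).fit()

    def test_separation_detected(self):
        epi = surv_frame([1, 2, 3, 4, 5, 6], [1, 1, 1, 0, 0, 0],
                         x=[1, 1, 1, 0, 0, 0])
        with pytest.raises((sv.SeparationError, sv.ConvergenceError)):
            sv.CoxModel(epi, ["x"]).fit()

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            sv.CoxModel(surv_frame([1, 2], [0, 0], x=[0, 1]), ["x"])

    def test_summary_mentions_covariates(self):
        epi = surv_frame([1, 2, 3, 4], [1, 1, 1, 0], x=[1, 0, 1, 0])
        fit = sv.CoxModel(epi, ["x"]).fit()
        text = fit.summary()
        assert "x" in text and "log-likelihood" in text
        ci = fit.conf_int()
        assert (ci["lower"] <= ci["upper"]).all()


# ---------------------------------------------------------------------------
# Schoenfeld proportionality test
# ---------------------------------------------------------------------------

class TestSchoenfeldTest:
    @staticmethod
    def _ph_data(seed, n=400):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1 / (0.1 * np.exp(0.5 * x)))
        c = rng.uniform(2, 12, n)
        return surv_frame(np.minimum(t, c), (t <= c).astype(int), x=x)

    def test_matches_lifelines_identity_transform(self):
        from lifelines import CoxPHFitter
        from lifelines.statistics import proportional_hazard_test
        epi = self._ph_data(14)
        fit = sv.CoxModel(epi, ["x"]).fit()
        ph = fit.schoenfeld_test()
        df = epi.rename(columns={"stop": "T", "event": "E"})[["T", "E", "x"]]
        cph = CoxPHFitter().fit(df, "T", "E")
        ref = proportional_hazard_test(cph, df, time_transform="identity")
        assert ph.chi2[0] == pytest.approx(ref.summary["test_statistic"].iloc[0],
                                           rel=1e-3)

    def test_holds_under_proportional_hazards(self):
        ph = sv.CoxModel(self._ph_data(15, n=1000), ["x"]).fit().schoenfeld_test()
        assert ph.global_p > 0.05

    def test_rejects_time_varying_hazard_ratio(self):
        """HR 7.7 before year 3, 1.0 after: the unsplit covariate fails PH."""
        rng = np.random.default_rng(16)
        n = 2000
        cat = rng.choice(["improbable", "possible"], n)
        spec = HazardSpec(hr_possible_early=7.7, hr_possible_late=1.0)
        t = np.array([sample_progression_time(c, spec, rng) for c in cat])
        c_ = rng.uniform(2, 12, n)
        epi = surv_frame(np.minimum(t, c_), (t <= c_).astype(int),
                         possible=(cat == "possible").astype(float))
        ph = sv.CoxModel(epi, ["possible"]).fit().schoenfeld_test()
        assert ph.p_values[0] < 0.01

    def test_too_few_events_rejected(self):
        epi = surv_frame([1, 2, 3], [1, 1, 0], x=[1.0, 0.0, 1.0])
        fit = sv.CoxModel(epi, ["x"]).fit()
        with pytest.raises(ValueError, match="3 events"):
            fit.schoenfeld_test()
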