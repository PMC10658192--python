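import numpy as np
import pytest

from ept.causal_impact import (
    PosteriorDraws,
    counterfactual_forecast,
    fit_pre_period,
    impact_summary,
    run_event_impacts,
)


def simulate_local_level(n, obs_sd, level_sd, seed, start=0.0):
    rng = np.random.default_rng(seed)
    level = start + np.cumsum(rng.normal(0, level_sd, n))
    return level + rng.normal(0, obs_sd, n)


class TestFitPrePeriod:
    def test_constant_series_posterior_level_is_that_constant(self):
        y = np.full(30, 7.5)
        d = fit_pre_period(y, draws=200, burn_in=50, seed=1)
        assert np.median(d.level_path) == pytest.approx(7.5, abs=0.01)
        assert np.median(d.level_sd) < 0.01

    def test_same_seed_gives_identical_draws(self):
        y = simulate_local_level(50, 1.0, 0.3, seed=2)
        d1 = fit_pre_period(y, draws=100, burn_in=20, seed=9)
        d2 = fit_pre_period(y, draws=100, burn_in=20, seed=9)
        assert np.array_equal(d1.obs_sd, d2.obs_sd)
        assert np.array_equal(d1.level_path, d2.level_path)

    def test_parameter_recovery_on_simulated_series(self):
        y = simulate_local_level(200, obs_sd=1.0, level_sd=0.3, seed=3)
        d = fit_pre_period(y, draws=1000, burn_in=200, seed=4)
        assert np.median(d.obs_sd) == pytest.approx(1.0, rel=0.3)
        assert np.median(d.level_sd) == pytest.approx(0.3, rel=0.3)

    def test_agrees_with_statsmodels_mle_level(self):
        """Cross-check: the posterior-mean level path tracks the smoothed
        level of a maximum-likelihood local-level fit."""
        from statsmodels.tsa.statespace.structural import UnobservedComponents

        y = simulate_local_level(150, obs_sd=1.0, level_sd=0.5, seed=5, start=20.0)
        d = fit_pre_period(y, draws=500, burn_in=100, seed=6)
        mle = UnobservedComponents(y, level="local level").fit(disp=0)
        sm_level = mle.smoothed_state[0]
        ours = d.level_path.mean(axis=0)
        assert np.corrcoef(ours, sm_level)[0, 1] > 0.99
        assert np.max(np.abs(ours - sm_level)) < 1.5  # within ~1.5 obs sd

    def test_short_pre_period_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            fit_pre_period(np.arange(5.0))

    def test_non_finite_rejected(self):
        y = np.arange(20.0)
        y[3] = np.inf
        with pytest.raises(ValueError):
            fit_pre_period(y)

    def test_scale_equivariance_of_posterior(self):
        y = simulate_local_level(80, 1.0, 0.3, seed=7, start=10.0)
        c = 50.0
        d1 = fit_pre_period(y, draws=400, burn_in=100, seed=8)
        d2 = fit_pre_period(c * y, draws=400, burn_in=100, seed=8)
        assert np.median(d2.obs_sd) / np.median(d1.obs_sd) == pytest.approx(c, rel=0.1)


class TestCounterfactualForecast:
    @staticmethod
    def degenerate_draws(level=4.0, D=100, n=20):
        return PosteriorDraws(
            obs_sd=np.zeros(D),
            level_sd=np.zeros(D),
            level_path=np.full((D, n), level),
        )

    def test_zero_variance_draws_give_flat_paths(self):
        paths = counterfactual_forecast(self.degenerate_draws(), horizon=7, seed=0)
        assert paths.shape == (100, 7)
        assert np.all(paths == 4.0)

    def test_first_step_mean_matches_kalman_one_step_forecast(self):
        """With known variances, the predictive mean of the first post
        step equals the last filtered level from a closed-form Kalman
        filter (the random walk forecast is flat)."""
        obs_var, level_var = 1.0, 0.25
        y = simulate_local_level(60, np.sqrt(obs_var), np.sqrt(level_var), seed=11)
        # closed-form filter with the true variances
        m, P = y[0], 10.0
        for t in range(1, len(y)):
            Pp = P + level_var
            K = Pp / (Pp + obs_var)
            m = m + K * (y[t] - m)
            P = (1 - K) * Pp
        D = 4000
        draws = PosteriorDraws(
            obs_sd=np.full(D, np.sqrt(obs_var)),
            level_sd=np.full(D, np.sqrt(level_var)),
            level_path=np.full((D, len(y)), m),  # condition on the filtered level
        )
        paths = counterfactual_forecast(draws, horizon=3, seed=12)
        mc_sd = np.sqrt(level_var + obs_var) / np.sqrt(D)
        assert paths[:, 0].mean() == pytest.approx(m, abs=4 * mc_sd)

    def test_predictive_variance_grows_with_horizon(self):
        D = 2000
        draws = PosteriorDraws(
            obs_sd=np.full(D, 0.5),
            level_sd=np.full(D, 0.4),
            level_path=np.zeros((D, 10)),
        )
        paths = counterfactual_forecast(draws, horizon=12, seed=13)
        v = paths.var(axis=0)
        assert v[-1] > v[0]
        expected = 0.4**2 * np.arange(1, 13) + 0.25
        assert np.allclose(v, expected, rtol=0.2)

    def test_bad_horizon_rejected(self):
        with pytest.raises(ValueError):
            counterfactual_forecast(self.degenerate_draws(), horizon=0)


class TestImpactSummary:
    def test_no_effect_when_actual_equals_predictive_mean(self):
        rng = np.random.default_rng(14)
        paths = rng.normal(10, 1, size=(2000, 8))
        actual = np.full(8, 10.0)
        s = impact_summary("heart", actual, paths)
        assert abs(s.relative_effect) < 0.02
        assert 0.3 < s.tail_p <= 0.5
        assert s.absolute_ci[0] < s.absolute_effect < s.absolute_ci[1]

    def test_saturated_effect_hits_tail_floor(self):
        rng = np.random.default_rng(15)
        paths = rng.normal(10, 1, size=(500, 6))
        actual = paths.mean(axis=0) + 100.0
        s = impact_summary("rotation", actual, paths)
        assert s.tail_p == pytest.approx(1 / 500)
        assert s.posterior_prob_pct == pytest.approx(100 * (1 - 1 / 500))
        assert s.absolute_effect == pytest.approx(600.0, rel=0.05)

    def test_posterior_prob_complements_tail_p(self):
        rng = np.random.default_rng(16)
        paths = rng.normal(0, 1, size=(400, 5))
        s = impact_summary("radula", np.ones(5), paths)
        assert s.posterior_prob_pct == pytest.approx(100 * (1 - s.tail_p))

    def test_injected_step_covered_by_credible_interval(self):
        """+delta per timepoint over horizon h: the 95% CI for the
        cumulative effect should contain delta*h in >= 90% of replicates."""
        delta, h = 2.0, 8
        covered = 0
        n_rep = 60
        for rep in range(n_rep):
            y = simulate_local_level(128, 1.0, 0.3, seed=100 + rep, start=10.0)
            pre, post_truth = y[:-h], y[-h:]
            d = fit_pre_period(pre, draws=300, burn_in=100, seed=200 + rep)
            paths = counterfactual_forecast(d, horizon=h, seed=300 + rep)
            actual = post_truth + delta
            s = impact_summary("e", actual, paths)
            lo, hi = s.absolute_ci
            covered += lo <= delta * h <= hi
        assert covered / n_rep >= 0.9

    def test_horizon_mismatch_rejected(self):
        with pytest.raises(ValueError):
            impact_summary("x", np.ones(3), np.ones((10, 4)))


class TestRunEventImpacts:
    def _series_with_step(self, onset_idx=60, n=100, delta=8.0, seed=21):
        rng = np.random.default_rng(seed)
        y = 10 + np.cumsum(rng.normal(0, 0.05, n)) + rng.normal(0, 0.3, n)
        y[onset_idx:] += delta
        return y

    def test_positive_step_gives_positive_significant_effect(self):
        y = self._series_with_step(delta=8.0)
        t = np.arange(100.0)
        out = run_event_impacts(y, t, [("rotation", 60.0)], draws=400, burn_in=100, seed=5)
        (s,) = out
        assert s.absolute_effect > 0
        assert s.posterior_prob_pct > 99

    def test_negative_step_gives_negative_effect(self):
        y = self._series_with_step(delta=-6.0)
        t = np.arange(100.0)
        (s,) = run_event_impacts(y, t, [("crawling", 60.0)], draws=400, burn_in=100, seed=6)
        assert s.absolute_effect < 0

    def test_event_at_final_timepoint_skipped_with_warning(self):
        y = self._series_with_step(delta=0.0)
        t = np.arange(100.0)
        with pytest.warns(UserWarning, match="empty post-period"):
            out = run_event_impacts(
                y, t, [("rotation", 50.0), ("radula", 99.5)], t_end=99.5,
                draws=100, burn_in=20, seed=7,
            )
        assert [s.event for s in out] == ["rotation"]

    def test_full_run_deterministic_given_seed(self):
        y = self._series_with_step()
        t = np.arange(100.0)
        events = [("rotation", 30.0), ("heart", 60.0), ("radula", 85.0)]
        a = run_event_impacts(y, t, events, draws=150, burn_in=30, seed=9)
        b = run_event_impacts(y, t, events, draws=150, burn_in=30, seed=9)
        for s1, s2 in zip(a, b):
            assert s1.actual == s2.actual
            assert s1.absolute_effect == s2.absolute_effect
            assert s1.tail_p == s2.tail_p

    def test_scale_equivariance_of_effects(self):
        y = self._series_with_step(delta=5.0)
        t = np.arange(100.0)
        c = 40.0
        (a,) = run_event_impacts(y, t, [("heart", 60.0)], draws=500, burn_in=100, seed=11)
        (b,) = run_event_impacts(c * y, t, [("heart", 60.0)], draws=500, burn_in=100, seed=11)
        assert b.absolute_effect / a.absolute_effect == pytest.approx(c, rel=0.05)
        assert b.relative_effect == pytest.approx(a.relative_effect, rel=0.05)
        assert b.tail_p == pytest.approx(a.tail_p, abs=0.02)

    def test_unsorted_events_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            run_event_impacts(
                np.ones(30), np.arange(30.0), [("b", 20.0), ("a", 10.0)]
            )
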