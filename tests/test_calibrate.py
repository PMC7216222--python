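"""Tests for the Poisson likelihood, priors, MCMC sampler and coverage."""

import datetime as dt
import math

import numpy as np
import pytest
from scipy import stats

from koreicus.calibrate import (
    ALPHA_MAX,
    CaptureData,
    MCMCConfig,
    PosteriorSample,
    PredictiveBand,
    ci_coverage,
    log_likelihood,
    log_prior,
    mcmc_sample,
    posterior_summary,
    predicted_captures,
    predictive_intervals,
)
from koreicus.popmodel import InputError, ParameterSet
from koreicus.synthdata import SynthConfig, city_temperature, gen_captures, gen_temperature


def _week(year, n):
    return tuple(dt.date(year, 6, 1) + dt.timedelta(days=7 * k) for k in range(n))


class TestCaptureData:
    def test_rejects_unordered_sessions_and_negative_counts(self):
        with pytest.raises(InputError):
            CaptureData({2018: (dt.date(2018, 6, 8), dt.date(2018, 6, 1))},
                        {2018: np.array([1.0, 2.0])})
        with pytest.raises(InputError):
            CaptureData({2018: _week(2018, 2)}, {2018: np.array([1.0, -2.0])})

    def test_trap_frame_averaging(self):
        import pandas as pd

        df = pd.DataFrame({
            "trap_id": ["A", "B", "A", "B"],
            "date": ["2018-06-01", "2018-06-01", "2018-06-08", "2018-06-08"],
            "count": [2, 4, 0, 1],
        })
        data = CaptureData.from_trap_frame(df)
        assert data.years == (2018,)
        assert list(data.n_avg[2018]) == [3.0, 0.5]


class TestLikelihood:
    def test_matches_independent_poisson_pmf_oracle(self, synth_cfg, city_temps,
                                                    synth_study):
        data, _, _ = synth_study
        psi = synth_cfg.true_params()
        preds = predicted_captures(psi, data, city_temps)
        # independent oracle on integer-rounded data
        int_data = CaptureData(data.sessions,
                               {y: np.round(v) for y, v in data.n_avg.items()})
        oracle = sum(
            float(stats.poisson.logpmf(int_data.n_avg[y], preds[y]).sum())
            for y in data.years
        )
        assert log_likelihood(psi, int_data, city_temps) == pytest.approx(
            oracle, abs=1e-10
        )

    def test_all_zero_counts_limit(self, synth_cfg, city_temps, synth_study):
        data, _, _ = synth_study
        psi = synth_cfg.true_params()
        zeros = CaptureData(data.sessions,
                            {y: np.zeros_like(v) for y, v in data.n_avg.items()})
        preds = predicted_captures(psi, zeros, city_temps)
        assert log_likelihood(psi, zeros, city_temps) == pytest.approx(
            -sum(p.sum() for p in preds.values()), rel=1e-12
        )

    def test_poisson_mle_property_single_session(self):
        # for integer n the per-session term is maximized at C = n
        from koreicus.calibrate import _poisson_loglik

        n = np.array([5.0])
        grid = np.linspace(0.5, 20.0, 500)
        lls = [_poisson_loglik(n, np.array([c])) for c in grid]
        assert abs(grid[int(np.argmax(lls))] - 5.0) < 0.05

    def test_zero_prediction_with_positive_count_is_minus_inf(self):
        from koreicus.calibrate import _poisson_loglik

        assert _poisson_loglik(np.array([2.0]), np.array([0.0])) == -math.inf

    def test_loglik_sums_across_years(self, synth_cfg, city_temps, synth_study):
        # the three yearly Poisson products multiply: log-likelihoods add
        data, _, _ = synth_study
        psi = synth_cfg.true_params()
        total = log_likelihood(psi, data, city_temps)
        parts = 0.0
        for y in data.years:
            single = CaptureData({y: data.sessions[y]}, {y: data.n_avg[y]})
            parts += log_likelihood(psi, single, {y: city_temps[y]})
        assert total == pytest.approx(parts, rel=1e-12)


class TestPrior:
    def test_outside_support_is_minus_inf(self):
        psi = ParameterSet(alpha=0.5, K_by_year={2018: 100.0})
        assert log_prior(psi) == -math.inf
        psi = ParameterSet(alpha=0.01, K_by_year={2018: 1.0})
        assert log_prior(psi) == -math.inf

    def test_flat_in_alpha(self):
        a = ParameterSet(alpha=0.01, K_by_year={2018: 100.0})
        b = ParameterSet(alpha=0.15, K_by_year={2018: 100.0})
        assert log_prior(a) == pytest.approx(log_prior(b))

    def test_log_uniform_in_K(self):
        # equal density on the log scale: p(K) dK ∝ dlogK ⇒ p(1e3)·1e3 = p(1e4)·1e4
        a = ParameterSet(alpha=0.01, K_by_year={2018: 1e3})
        b = ParameterSet(alpha=0.01, K_by_year={2018: 1e4})
        assert log_prior(a) - log_prior(b) == pytest.approx(math.log(1e4 / 1e3))


def _constant_posterior(values, n=200, years=(2017, 2018, 2019)):
    ncol = 1 + len(years)
    draws = np.tile(np.asarray(values, float), (2, n, 1))
    assert draws.shape[2] == ncol
    return PosteriorSample(
        years=tuple(years),
        chains=draws,
        log_post=np.zeros((2, n)),
        seed=0,
        acceptance=(1.0, 1.0),
        rhat={name: 1.0 for name in
              ("alpha",) + tuple(f"K{y}" for y in years)},
        template=ParameterSet(alpha=0.01, K_by_year={y: 100.0 for y in years}),
    )


class TestPosteriorSummary:
    def test_constant_chain(self):
        ps = _constant_posterior([0.02, 50.0, 60.0, 70.0])
        s = posterior_summary(ps)
        assert s.loc["alpha", "mean"] == pytest.approx(0.02)
        assert s.loc["alpha", "q2.5"] == s.loc["alpha", "q97.5"] == pytest.approx(0.02)
        assert list(s.index) == ["alpha", "K2017", "K2018", "K2019"]

    def test_percentile_rule_on_1_to_100(self):
        ps = _constant_posterior([0.02, 50.0, 60.0, 70.0], n=50)
        chains = ps.chains.copy()
        chains[:, :, 0] = np.arange(1, 101).reshape(2, 50)
        ps2 = PosteriorSample(ps.years, chains, ps.log_post, 0, ps.acceptance,
                              ps.rhat, ps.template)
        s = posterior_summary(ps2)
        assert s.loc["alpha", "mean"] == pytest.approx(50.5)
        assert s.loc["alpha", "q2.5"] == pytest.approx(3.475)
        assert s.loc["alpha", "q97.5"] == pytest.approx(97.525)

    def test_requires_enough_draws(self):
        ps = _constant_posterior([0.02, 50.0, 60.0, 70.0], n=10)
        with pytest.raises(InputError):
            posterior_summary(ps)


class TestMCMC:
    def test_prior_recovery_with_no_sessions(self, city_temps):
        # with zero observed sessions the likelihood vanishes and the
        # sampler must reproduce the alpha ~ U(0, 0.2) prior
        empty = CaptureData({2018: ()}, {2018: np.array([])})
        ps = mcmc_sample(empty, city_temps,
                         MCMCConfig(n_iter=12_000, burn_in=4_000, seed=11))
        alpha = ps.flat()[:, 0]
        q = np.percentile(alpha, [25, 50, 75])
        assert np.allclose(q, [0.05, 0.10, 0.15], atol=0.015)
        logK = np.log(ps.flat()[:, 1])
        assert abs(np.median(logK) - 0.5 * (math.log(10) + math.log(1e7))) < 1.0

    def test_same_seed_identical_chains(self, synth_study, city_temps, synth_cfg):
        data, _, _ = synth_study
        cfg = MCMCConfig(n_iter=1_500, burn_in=800, seed=5)
        t = synth_cfg.true_params()
        a = mcmc_sample(data, city_temps, cfg, template=t)
        b = mcmc_sample(data, city_temps, cfg, template=t)
        assert np.array_equal(a.chains, b.chains)
        assert a.acceptance == b.acceptance

    def test_draws_respect_prior_support(self, synth_study, city_temps, synth_cfg):
        data, _, _ = synth_study
        ps = mcmc_sample(data, city_temps,
                         MCMCConfig(n_iter=2_000, burn_in=1_000, seed=3),
                         template=synth_cfg.true_params())
        flat = ps.flat()
        assert np.all(flat[:, 0] >= 0) and np.all(flat[:, 0] <= ALPHA_MAX)
        assert np.all(flat[:, 1:] >= 10.0) and np.all(flat[:, 1:] <= 1e7)

    def test_config_validation(self):
        with pytest.raises(InputError):
            MCMCConfig(n_iter=100, burn_in=200)
        with pytest.raises(InputError):
            MCMCConfig(n_chains=1)


class TestPredictiveBands:
    def test_single_draw_no_noise_collapses_to_C(self, synth_cfg, city_temps,
                                                 synth_study):
        data, _, _ = synth_study
        psi = synth_cfg.true_params()
        ps = _constant_posterior(
            [psi.alpha] + [psi.K_for(y) for y in (2017, 2018, 2019)]
        )
        ps = PosteriorSample(ps.years, ps.chains, ps.log_post, 0, ps.acceptance,
                             ps.rhat, template=psi)
        bands = predictive_intervals(ps, city_temps, data.sessions, n_draws=5,
                                     seed=0, observation_noise=False)
        preds = predicted_captures(psi, data, city_temps)
        for y in data.years:
            assert np.allclose(bands[y].lo95, preds[y])
            assert np.allclose(bands[y].hi95, preds[y])
            assert np.allclose(bands[y].mean, preds[y])

    def test_bands_are_nested(self, synth_cfg, city_temps, synth_study):
        data, _, _ = synth_study
        ps = mcmc_sample(data, city_temps,
                         MCMCConfig(n_iter=3_000, burn_in=1_500, seed=9),
                         template=synth_cfg.true_params())
        bands = predictive_intervals(ps, city_temps, data.sessions,
                                     n_draws=200, seed=2)
        for y in data.years:
            b = bands[y]
            assert np.all(b.lo95 <= b.lo50) and np.all(b.hi50 <= b.hi95)
            assert np.all(b.lo95 >= 0)

    def test_nesting_violation_rejected(self):
        with pytest.raises(InputError):
            PredictiveBand(sessions=(dt.date(2018, 6, 1),),
                           mean=np.array([1.0]), lo95=np.array([0.5]),
                           lo50=np.array([0.2]), hi50=np.array([2.0]),
                           hi95=np.array([3.0]))


class TestCoverage:
    def _band(self, dates, lo95, lo50, hi50, hi95):
        return PredictiveBand(sessions=tuple(dates), mean=np.asarray(hi50, float),
                              lo95=np.asarray(lo95, float),
                              lo50=np.asarray(lo50, float),
                              hi50=np.asarray(hi50, float),
                              hi95=np.asarray(hi95, float))

    def test_infinite_band_covers_everything(self):
        dates = _week(2018, 4)
        data = CaptureData({2018: dates}, {2018: np.array([0.0, 5.0, 2.0, 9.0])})
        band = self._band(dates, [0] * 4, [0] * 4, [1e9] * 4, [1e9] * 4)
        cov = ci_coverage(data, {2018: band})
        assert cov == {"frac95": 1.0, "frac50": 1.0}

    def test_simple_counting(self):
        dates = _week(2018, 4)
        data = CaptureData({2018: dates}, {2018: np.array([1.0, 5.0, 2.0, 9.0])})
        band = self._band(dates, [0, 0, 0, 0], [0, 0, 0, 0],
                          [2, 2, 2, 2], [6, 6, 6, 8])
        cov = ci_coverage(data, {2018: band})
        assert cov["frac95"] == pytest.approx(3 / 4)
        assert cov["frac50"] == pytest.approx(2 / 4)

    def test_hand_enumerated_ten_sessions(self):
        dates = _week(2018, 10)
        n = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0])
        data = CaptureData({2018: dates}, {2018: n})
        lo95 = np.zeros(10)
        hi95 = np.array([5.0] * 10)          # covers n = 0..5 -> 6/10
        lo50 = np.array([1.0] * 10)
        hi50 = np.array([3.0] * 10)          # covers n = 1..3 -> 3/10
        cov = ci_coverage(data, {2018: self._band(dates, lo95, lo50, hi50, hi95)})
        assert cov["frac95"] == pytest.approx(0.6)
        assert cov["frac50"] == pytest.approx(0.3)

    def test_inclusive_endpoints(self):
        dates = _week(2018, 3)
        data = CaptureData({2018: dates}, {2018: np.array([1.0, 3.0, 2.0])})
        band = self._band(dates, [1, 1, 1], [1, 1, 1], [3, 3, 3], [3, 3, 3])
        cov = ci_coverage(data, {2018: band})
        assert cov["frac95"] == 1.0 and cov["frac50"] == 1.0

    def test_mismatched_sessions_raise(self):
        dates = _week(2018, 3)
        data = CaptureData({2018: dates}, {2018: np.array([1.0, 3.0, 2.0])})
        band = self._band(_week(2018, 4), [0] * 4, [0] * 4, [9] * 4, [9] * 4)
        with pytest.raises(InputError):
            ci_coverage(data, {2018: band})


class TestRecoverySmoke:
    def test_true_alpha_in_posterior_interval_single_replicate(self, city_temps):
        cfg = SynthConfig(seed=4)
        temps = gen_temperature(cfg)
        data, _, _ = gen_captures(cfg, temps)
        ps = mcmc_sample(data, city_temperature(temps),
                         MCMCConfig(n_iter=8_000, burn_in=3_000, seed=21),
                         template=cfg.true_params())
        s = posterior_summary(ps)
        assert s.loc["alpha", "q2.5"] <= cfg.true_alpha <= s.loc["alpha", "q97.5"]
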