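"""WG intensity math, NHPP likelihood, and the posterior sampler."""

import warnings

import numpy as np
import pytest
from scipy.integrate import quad

from rarecast.changepoint import (
    AnnualForecast,
    ChangePointSpec,
    ConvergenceWarning,
    PosteriorDraws,
    WGParams,
    expected_annual_counts,
    forecast_annual,
    nhpp_loglik,
    piecewise_cumulative,
    sample_posterior,
    wg_cumulative,
    wg_inverse_cumulative,
    wg_rate,
)
from rarecast.data import EventSeries, ORIGIN_DATE, end_of_year_offset, truncate_events


RANDOM_PARAMS = [
    WGParams(0.8, 500.0, 0.3),
    WGParams(1.0, 1000.0, 0.0),
    WGParams(1.5, 2000.0, 0.7),
    WGParams(2.5, 800.0, 0.95),
    WGParams(1.2, 5000.0, 0.5),
]


class TestWgIntensity:
    @pytest.mark.parametrize("params", RANDOM_PARAMS)
    def test_cumulative_matches_quadrature(self, params):
        for t in (100.0, 1500.0, 6000.0):
            numeric, _ = quad(
                lambda u: wg_rate(params, u), 1e-9, t, limit=400
            )
            assert wg_cumulative(params, t) == pytest.approx(numeric, rel=1e-6)

    @pytest.mark.parametrize("params", RANDOM_PARAMS)
    def test_inverse_cumulative_round_trip(self, params):
        for target in (0.5, 3.0, 20.0):
            t = wg_inverse_cumulative(params, target)
            assert wg_cumulative(params, t) == pytest.approx(target, rel=1e-9)

    def test_rate_reduces_to_weibull_when_rho_zero(self):
        params = WGParams(2.0, 100.0, 0.0)
        t = 50.0
        weibull = (2.0 / 100.0) * (t / 100.0)
        assert wg_rate(params, t) == pytest.approx(weibull)

    def test_rate_diverges_at_origin_for_small_alpha(self):
        with pytest.raises(ValueError):
            wg_rate(WGParams(0.5, 100.0, 0.0), 0.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            WGParams(-1.0, 100.0, 0.0)
        with pytest.raises(ValueError):
            WGParams(1.0, 100.0, 1.0)

    def test_piecewise_cumulative_continuity(self):
        params = [WGParams(1.0, 100.0, 0.0), WGParams(1.5, 500.0, 0.4)]
        taus = [1000.0]
        left = piecewise_cumulative(params, taus, 5000.0, 1000.0 - 1e-6)
        right = piecewise_cumulative(params, taus, 5000.0, 1000.0 + 1e-6)
        assert left == pytest.approx(right, abs=1e-3)

    def test_piecewise_single_segment_equals_plain(self):
        p = WGParams(1.3, 700.0, 0.6)
        assert piecewise_cumulative([p], [], 5000.0, 3000.0) == pytest.approx(
            wg_cumulative(p, 3000.0)
        )


class TestLikelihood:
    def test_homogeneous_closed_form(self):
        # alpha=1, rho=0: constant rate 1/beta, so
        # loglik = n*log(1/beta) - end/beta
        beta, end = 120.0, 6000.0
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(1.0, end, size=40))
        events = EventSeries(times, ORIGIN_DATE, end)
        spec = ChangePointSpec(observation_end=end, n_change_points=0)
        ll = nhpp_loglik(events, spec, [WGParams(1.0, beta, 0.0)])
        assert ll == pytest.approx(40 * np.log(1.0 / beta) - end / beta, rel=1e-12)

    def test_origin_event_excluded(self):
        end = 1000.0
        spec = ChangePointSpec(observation_end=end, n_change_points=0)
        params = [WGParams(0.9, 300.0, 0.2)]
        with_origin = EventSeries(np.array([0.0, 50.0, 400.0]), ORIGIN_DATE, end)
        without = EventSeries(np.array([50.0, 400.0]), ORIGIN_DATE, end)
        assert nhpp_loglik(with_origin, spec, params) == pytest.approx(
            nhpp_loglik(without, spec, params)
        )

    def test_changepoint_likelihood_sums_segments(self):
        end = 2000.0
        times = np.array([100.0, 600.0, 1500.0])
        events = EventSeries(times, ORIGIN_DATE, end)
        spec = ChangePointSpec(observation_end=end, n_change_points=1)
        p1, p2 = WGParams(1.0, 200.0, 0.0), WGParams(1.0, 50.0, 0.0)
        tau = 1000.0
        ll = nhpp_loglik(events, spec, [p1, p2], [tau])
        manual = (
            2 * np.log(1 / 200.0)
            - tau / 200.0
            + 1 * np.log(1 / 50.0)
            - (end - tau) / 50.0
        )
        assert ll == pytest.approx(manual, rel=1e-12)


def small_posterior(events, spec, seed=0, **kw):
    kw.setdefault("n_chains", 2)
    kw.setdefault("n_warmup", 400)
    kw.setdefault("n_draws", 400)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        return sample_posterior(events, spec, seed=seed, **kw)


class TestSampler:
    def test_prior_only_sampling_is_uniform(self):
        from scipy import stats

        end = 1000.0
        spec = ChangePointSpec(
            observation_end=end,
            n_change_points=0,
            alpha_bounds=(0.5, 2.0),
            beta_bounds=(10.0, 100.0),
        )
        events = EventSeries(np.array([10.0]), ORIGIN_DATE, end)
        draws = small_posterior(
            events, spec, seed=1, likelihood_on=False,
            n_warmup=600, n_draws=2500, thin=4,
        )
        alpha = draws.flat[:, 0]
        # thin to near-independent draws before the distributional test
        _, p = stats.kstest(alpha[::20], "uniform", args=(0.5, 1.5))
        assert p > 0.001
        assert abs(alpha.mean() - 1.25) < 0.05
        assert abs(np.quantile(alpha, 0.5) - 1.25) < 0.08

    def test_determinism(self, study_events):
        end = end_of_year_offset(2019)
        events = truncate_events(study_events, end)
        spec = ChangePointSpec(observation_end=end)
        a = small_posterior(events, spec, seed=3, n_warmup=200, n_draws=100)
        b = small_posterior(events, spec, seed=3, n_warmup=200, n_draws=100)
        assert np.array_equal(a.draws, b.draws)

    def test_nonconvergence_warns_not_raises(self, study_events):
        end = end_of_year_offset(2019)
        events = truncate_events(study_events, end)
        spec = ChangePointSpec(observation_end=end)
        with pytest.warns(ConvergenceWarning):
            draws = sample_posterior(
                events, spec, n_chains=2, n_warmup=40, n_draws=40,
                seed=0, rhat_threshold=1.0000001,
            )
        assert not draws.converged

    def test_draws_stay_in_support(self, study_events):
        end = end_of_year_offset(2019)
        events = truncate_events(study_events, end)
        spec = ChangePointSpec(observation_end=end)
        draws = small_posterior(events, spec, seed=2, n_warmup=300, n_draws=150)
        for x in draws.flat[::25]:
            assert spec.in_support(x)

    def test_to_frame_layout(self, study_events):
        end = end_of_year_offset(2019)
        events = truncate_events(study_events, end)
        spec = ChangePointSpec(observation_end=end)
        draws = small_posterior(events, spec, seed=4, n_warmup=100, n_draws=50)
        frame = draws.to_frame()
        assert list(frame.columns) == ["chain", "draw"] + spec.param_names
        assert len(frame) == 2 * 50


class TestForecast:
    @pytest.fixture(scope="class")
    def study_draws(self, study_events):
        end = end_of_year_offset(2019)
        events = truncate_events(study_events, end)
        spec = ChangePointSpec(observation_end=end)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            draws = sample_posterior(
                events, spec, n_chains=2, n_warmup=600, n_draws=600, seed=10
            )
        return draws, events

    def test_forecast_years_follow_window(self, study_draws):
        draws, events = study_draws
        fc = forecast_annual(draws, events, horizon_years=3, seed=0)
        assert list(fc.years) == [2020, 2021, 2022]
        assert np.all(fc.lower <= fc.mean)
        assert np.all(fc.mean <= fc.upper)

    def test_forecast_deterministic_under_seed(self, study_draws):
        draws, events = study_draws
        a = forecast_annual(draws, events, horizon_years=2, seed=9)
        b = forecast_annual(draws, events, horizon_years=2, seed=9)
        assert np.array_equal(a.mean, b.mean)
        assert np.array_equal(a.upper, b.upper)

    def test_forecast_validation(self, study_draws):
        draws, events = study_draws
        with pytest.raises(ValueError):
            forecast_annual(draws, events, horizon_years=0)
        with pytest.raises(ValueError):
            forecast_annual(draws, events, horizon_years=1, level=1.5)

    def test_expected_annual_counts_sum(self):
        p = WGParams(1.4, 900.0, 0.5)
        spec = ChangePointSpec(observation_end=end_of_year_offset(1970))
        per_year = expected_annual_counts(
            spec, [p], [], range(1966, 1971), ORIGIN_DATE
        )
        import datetime as dt

        total = wg_cumulative(
            p, float((dt.date(1971, 1, 1) - ORIGIN_DATE).days)
        )
        assert per_year.sum() == pytest.approx(total, rel=1e-9)
        assert np.all(per_year >= 0)
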