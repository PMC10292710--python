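"""Residual network: normalisation, gradients, training, SNC, forecasting."""

import numpy as np
import pytest

from rarecast.arima import ArimaOrder, fit_arima
from rarecast.hybrid import (
    ANNArchitecture,
    ANNWeights,
    NormalizationClipWarning,
    NormalizationSpec,
    TrainingConfig,
    ann_forward,
    ann_gradients,
    build_lag_matrix,
    denormalize,
    extract_residuals,
    fit_hybrid,
    hybrid_forecast,
    hybrid_prediction_interval,
    normalize,
    prediction_risk,
    snc_select,
    train_ann,
)
from rarecast.synthetic import HybridScenario, simulate_hybrid_series


def random_weights(n, m, seed=0):
    rng = np.random.default_rng(seed)
    return ANNWeights(
        W1=rng.normal(size=(m, n)),
        b1=rng.normal(size=m),
        W2=rng.normal(size=(1, m)),
        b2=float(rng.normal()),
    )


class TestNormalization:
    def test_round_trip(self):
        values = np.array([-2.0, 0.0, 3.0, 7.0])
        scaled, spec = normalize(values)
        assert scaled.min() == 0.0 and scaled.max() == 1.0
        assert np.allclose(denormalize(scaled, spec), values)

    def test_out_of_range_clipped_with_warning(self):
        _, spec = normalize(np.array([0.0, 10.0]))
        with pytest.warns(NormalizationClipWarning):
            scaled, _ = normalize(np.array([-5.0, 12.0]), spec)
        assert scaled[0] == 0.0 and scaled[1] == 1.0

    def test_constant_residuals_rejected(self):
        with pytest.raises(ValueError):
            NormalizationSpec(1.0, 1.0)


class TestResidualsAndLags:
    def test_extract_residuals_alignment(self, study_counts):
        fit = fit_arima(study_counts.values(), ArimaOrder(0, 1, 1))
        resid = extract_residuals(study_counts.values(), fit, start_year=1966)
        assert len(resid) == 53
        assert resid.start_year == 1967
        manual = study_counts.values()[1:] - fit.fitted_values[1:]
        assert np.allclose(resid.values, manual)

    def test_misaligned_series_rejected(self, study_counts):
        fit = fit_arima(study_counts.values(), ArimaOrder(0, 1, 1))
        with pytest.raises(ValueError):
            extract_residuals(study_counts.values()[:-3], fit)

    def test_build_lag_matrix_layout(self):
        X, y = build_lag_matrix(np.arange(6.0), 3)
        assert X.shape == (3, 3)
        # row 0 predicts value 3 from lags (2, 1, 0), most recent first
        assert np.array_equal(X[0], [2.0, 1.0, 0.0])
        assert np.array_equal(y, [3.0, 4.0, 5.0])

    def test_build_lag_matrix_validation(self):
        with pytest.raises(ValueError):
            build_lag_matrix(np.arange(5.0), 0)
        with pytest.raises(ValueError):
            build_lag_matrix(np.arange(3.0), 3)


class TestNetworkMath:
    def test_forward_bounds_and_shapes(self):
        w = random_weights(4, 3)
        X = np.random.default_rng(1).uniform(size=(7, 4))
        out, a = ann_forward(w, X)
        assert out.shape == (7,)
        assert a.shape == (7, 3)
        assert np.all((out > 0) & (out < 1))

    def test_zero_hidden_nodes_constant_output(self):
        w = ANNWeights(np.zeros((0, 1)), np.zeros(0), np.zeros((1, 0)), 0.3)
        out, _ = ann_forward(w, np.zeros((5, 1)))
        assert np.allclose(out, 1.0 / (1.0 + np.exp(-0.3)))

    def test_input_width_mismatch_rejected(self):
        w = random_weights(4, 2)
        with pytest.raises(ValueError):
            ann_forward(w, np.zeros((3, 5)))

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(5)
        n, m, I = 3, 4, 12
        X = rng.uniform(0, 1, size=(I, n))
        y = rng.uniform(0, 1, size=I)
        w = random_weights(n, m, seed=8)
        lam = 0.01
        g_W1, g_b1, g_W2, g_b2 = ann_gradients(w, X, y, lam)

        def cost(weights):
            out, _ = ann_forward(weights, X)
            J = np.mean((y - out) ** 2)
            return J + 0.5 * lam * (np.sum(weights.W1**2) + np.sum(weights.W2**2))

        eps = 1e-6
        # W1 entries
        for i in range(m):
            for j in range(n):
                wp, wm = w.copy(), w.copy()
                wp.W1[i, j] += eps
                wm.W1[i, j] -= eps
                num = (cost(wp) - cost(wm)) / (2 * eps)
                assert g_W1[i, j] == pytest.approx(num, rel=1e-5, abs=1e-8)
        # b1, W2, b2 entries
        for i in range(m):
            wp, wm = w.copy(), w.copy()
            wp.b1[i] += eps
            wm.b1[i] -= eps
            assert g_b1[i] == pytest.approx(
                (cost(wp) - cost(wm)) / (2 * eps), rel=1e-5, abs=1e-8
            )
            wp, wm = w.copy(), w.copy()
            wp.W2[0, i] += eps
            wm.W2[0, i] -= eps
            assert g_W2[0, i] == pytest.approx(
                (cost(wp) - cost(wm)) / (2 * eps), rel=1e-5, abs=1e-8
            )
        wp, wm = w.copy(), w.copy()
        wp.b2 += eps
        wm.b2 -= eps
        assert g_b2 == pytest.approx(
            (cost(wp) - cost(wm)) / (2 * eps), rel=1e-5, abs=1e-8
        )

    def test_prediction_risk_identities(self):
        arch = ANNArchitecture(4, 3)
        assert arch.weight_count == 4 * 3 + 3
        assert prediction_risk(0.02, arch, 30) == pytest.approx(
            0.02 * (1 + 2 * 15 / 30)
        )
        constant = ANNArchitecture(4, 0)
        assert constant.weight_count == 0
        assert prediction_risk(0.05, constant, 30) == pytest.approx(0.05)
        with pytest.raises(ValueError):
            prediction_risk(0.1, arch, 0)


class TestTraining:
    def test_training_reduces_cost_and_is_deterministic(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 1, size=(30, 3))
        y = rng.uniform(0.2, 0.8, size=30)
        arch = ANNArchitecture(3, 4)
        config = TrainingConfig(max_iterations=400, seed=1)
        w1, info1 = train_ann(X, y, arch, config)
        w2, info2 = train_ann(X, y, arch, config)
        assert np.array_equal(w1.W1, w2.W1)
        assert info1["J"] == info2["J"]
        # compare against the untrained starting cost
        out0, _ = ann_forward(random_weights(3, 4, seed=999), X)
        assert info1["J"] < np.mean((y - out0) ** 2)

    def test_teacher_student_recovery(self):
        teacher = random_weights(2, 3, seed=7)
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, size=(60, 2))
        y, _ = ann_forward(teacher, X)
        config = TrainingConfig(lambda_reg=0.0, max_iterations=4000, seed=0)
        _, info = train_ann(X, y, ANNArchitecture(2, 3), config)
        assert info["J"] < 1e-4

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_ann(np.zeros((0, 2)), np.zeros(0), ANNArchitecture(2, 1),
                      TrainingConfig())

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainingConfig(lambda_reg=-1.0)
        with pytest.raises(ValueError):
            TrainingConfig(max_iterations=0)


class TestSnc:
    def test_snc_report_covers_both_scans(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0, 1, size=40)
        config = TrainingConfig(max_iterations=200, seed=0)
        arch, report = snc_select(values, n_max=3, m_max=2, config=config,
                                  restarts=1)
        assert len(report["step1"]) == 3  # m in 0..2
        assert len(report["step2"]) == 3  # n in 1..3
        assert 1 <= arch.n_inputs <= 3
        assert 0 <= arch.m_hidden <= 2

    def test_snc_prefers_network_when_signal_present(self):
        # residuals with strong lag-1 structure: the constant model loses
        rng = np.random.default_rng(1)
        values = np.empty(60)
        values[0] = 0.5
        for t in range(1, 60):
            values[t] = 0.5 + 0.4 * np.sin(6.0 * values[t - 1]) + rng.normal(0, 0.02)
        values = (values - values.min()) / (values.max() - values.min())
        config = TrainingConfig(max_iterations=1500, seed=0)
        arch, _ = snc_select(values, n_max=3, m_max=4, config=config, restarts=2)
        assert arch.m_hidden > 0

    def test_snc_needs_enough_rows(self):
        with pytest.raises(ValueError):
            snc_select(np.zeros(3), n_max=5)


class TestHybridModel:
    @pytest.fixture(scope="class")
    def fitted(self):
        counts = simulate_hybrid_series(
            HybridScenario(n_years=45, nonlinear_fn="quadratic", seed=2),
            as_counts=True,
        )
        fit = fit_arima(counts.values(), ArimaOrder(0, 1, 1))
        config = TrainingConfig(max_iterations=600, seed=0)
        model = fit_hybrid(counts.values(), fit, n_max=3, m_max=3,
                           config=config, restarts=1)
        return model

    def test_forecast_first_step_matches_manual_composition(self, fitted):
        model = fitted
        points, ar = hybrid_forecast(model, 1)
        n = model.architecture.n_inputs
        scaled, _ = normalize(model.residuals, model.norm_spec)
        window = scaled[-n:][::-1]
        out, _ = ann_forward(model.weights, window[None, :])
        manual = ar.point[0] + denormalize(float(out[0]), model.norm_spec)
        assert points[0] == pytest.approx(manual)

    def test_forecast_horizon_and_finiteness(self, fitted):
        points, ar = hybrid_forecast(fitted, 4)
        assert points.shape == (4,)
        assert np.all(np.isfinite(points))
        assert ar.point.shape == (4,)

    def test_to_json_round_trips_weights(self, fitted):
        import json

        payload = json.loads(fitted.to_json())
        assert payload["architecture"]["n_inputs"] == fitted.architecture.n_inputs
        assert payload["architecture"]["m_hidden"] == fitted.architecture.m_hidden
        W1 = np.asarray(payload["weights"]["W1"]).reshape(fitted.weights.W1.shape)
        assert np.allclose(W1, fitted.weights.W1)
        assert payload["weights"]["b2"] == pytest.approx(fitted.weights.b2)


class TestIntervals:
    def test_shift_policy_translates_bounds(self):
        lo, hi = hybrid_prediction_interval(2.0, 8.0, 1.5)
        assert (lo, hi) == (3.5, 9.5)

    def test_bootstrap_policy_centres_on_point(self):
        rng = np.random.default_rng(0)
        errors = rng.normal(0, 1.0, size=400)
        lo, hi = hybrid_prediction_interval(
            0.0, 0.0, 0.0, policy="bootstrap",
            hybrid_errors=errors, point=5.0, seed=1,
        )
        assert lo < 5.0 < hi
        assert hi - lo == pytest.approx(2 * 1.96, abs=0.5)

    def test_bootstrap_requires_errors_and_point(self):
        with pytest.raises(ValueError):
            hybrid_prediction_interval(0.0, 1.0, 0.0, policy="bootstrap")

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError):
            hybrid_prediction_interval(0.0, 1.0, 0.0, policy="magic")
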