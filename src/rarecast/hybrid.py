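"""Hybrid ARIMA-ANN: a small feed-forward network over ARIMA residuals.

The annual series is decomposed as ``y_t = L_t + N_t``: the ARIMA fit
estimates the linear part ``L_t`` and a single-hidden-layer network models
the nonlinear structure left in the residuals ``e_t = y_t - L_hat_t``.  The
network maps the ``n`` most recent residuals to the current one,

    a     = Tanh(W1 x + b1)          (hidden layer, m nodes)
    N_hat = Sig(W2 a + b2)           (output layer, one node)

trained by full-batch gradient descent on the L2-regularised mean squared
error ``J + (lambda/2) * (||W1||^2 + ||W2||^2)``.  Residuals (inputs AND
targets — the sigmoid output lives in (0,1)) are min-max normalised to
[0, 1] on the training range.

Architecture is chosen by sequential network construction (SNC): with the
inputs fixed at their maximum ``n_max``, the hidden width ``m`` in 0..m_max
minimising the algebraic prediction-risk estimate

    P_hat = J * (1 + 2Q/I),   Q = n*m + m network weights, I training rows

is selected; then with ``m`` fixed, the input count ``n`` in 1..n_max is
selected the same way.  Every candidate is trained on all available rows.
Because a single training run's risk is dominated by the random weight
initialisation, each candidate is trained from several seeds and the median
risk compared (set ``restarts=1`` for single-run selection).

``m = 0`` denotes the degenerate constant model ``Sig(b2)`` with Q = 0.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .arima import ArimaFit, forecast as arima_forecast

__all__ = [
    "ResidualSeries",
    "NormalizationSpec",
    "ANNArchitecture",
    "ANNWeights",
    "TrainingConfig",
    "HybridModel",
    "NormalizationClipWarning",
    "extract_residuals",
    "normalize",
    "denormalize",
    "build_lag_matrix",
    "ann_forward",
    "ann_gradients",
    "train_ann",
    "prediction_risk",
    "snc_select",
    "hybrid_forecast",
    "hybrid_prediction_interval",
]


class NormalizationClipWarning(UserWarning):
    """A value outside the training range was clipped into [0, 1]."""


@dataclass(frozen=True)
class ResidualSeries:
    """One-step in-sample ARIMA residuals, aligned to calendar years."""

    values: np.ndarray
    start_year: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float)
        )

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class NormalizationSpec:
    """Min-max bounds learned from training residuals only."""

    min_value: float
    max_value: float

    def __post_init__(self) -> None:
        if not self.max_value > self.min_value:
            raise ValueError("max_value must exceed min_value (constant residuals?)")


def normalize(values, spec: NormalizationSpec | None = None):
    """Map to [0, 1]; out-of-range values (under a supplied spec) are
    clipped with a warning.  Returns ``(normalised, spec)``.
    """
    values = np.asarray(values, dtype=float)
    if spec is None:
        spec = NormalizationSpec(float(values.min()), float(values.max()))
    scaled = (values - spec.min_value) / (spec.max_value - spec.min_value)
    if np.any(scaled < 0) or np.any(scaled > 1):
        warnings.warn(
            "value outside the training range clipped to [0, 1]",
            NormalizationClipWarning,
            stacklevel=2,
        )
        scaled = np.clip(scaled, 0.0, 1.0)
    return scaled, spec


def denormalize(values, spec: NormalizationSpec):
    values = np.asarray(values, dtype=float)
    out = values * (spec.max_value - spec.min_value) + spec.min_value
    return out if out.ndim else float(out)


def extract_residuals(series, fit: ArimaFit, start_year: int | None = None) -> ResidualSeries:
    """``e_t = y_t - L_hat_t`` from the fit's one-step in-sample predictions.

    The first ``d`` observations initialise the differencing and carry no
    usable prediction, so a length-N series yields N - d residuals.
    """
    values = np.asarray(series, dtype=float)
    if fit.fitted_values.size != values.size:
        raise ValueError("fit and series lengths are misaligned")
    d = fit.order.d
    resid = values[d:] - fit.fitted_values[d:]
    if start_year is not None:
        start_year = start_year + d
    return ResidualSeries(resid, start_year)


def build_lag_matrix(values, n: int):
    """Supervised pairs: row i holds lags (t-1 .. t-n), target value at t.

    Returns ``(X, y)`` with ``I = len(values) - n`` rows.
    """
    values = np.asarray(values, dtype=float)
    if n < 1:
        raise ValueError("n must be >= 1")
    if values.size <= n:
        raise ValueError(f"need more than n={n} values, got {values.size}")
    I = values.size - n
    X = np.empty((I, n))
    for i in range(I):
        X[i] = values[i : i + n][::-1]  # most recent lag first
    y = values[n:]
    return X, y.copy()


@dataclass(frozen=True)
class ANNArchitecture:
    """Single-hidden-layer geometry: n inputs, m hidden nodes, one output."""

    n_inputs: int
    m_hidden: int

    def __post_init__(self) -> None:
        if self.n_inputs < 1 or self.m_hidden < 0:
            raise ValueError("need n_inputs >= 1 and m_hidden >= 0")

    @property
    def weight_count(self) -> int:
        """Q = n*m + m (hidden and output weight matrices)."""
        return self.n_inputs * self.m_hidden + self.m_hidden


@dataclass
class ANNWeights:
    W1: np.ndarray  # (m, n)
    b1: np.ndarray  # (m,)
    W2: np.ndarray  # (1, m)
    b2: float

    def architecture(self) -> ANNArchitecture:
        m, n = self.W1.shape
        return ANNArchitecture(n_inputs=max(n, 1), m_hidden=m)

    def copy(self) -> "ANNWeights":
        return ANNWeights(self.W1.copy(), self.b1.copy(), self.W2.copy(), self.b2)


@dataclass(frozen=True)
class TrainingConfig:
    """Gradient-descent settings for the residual network.

    ``lambda_reg`` is the L2 coefficient on the weight matrices (biases are
    not penalised); its default is scaled to the mean-squared-error of
    residuals normalised to [0, 1] (J is of order 0.01-0.05, so a heavier
    penalty collapses every candidate to the constant model).  Descent uses
    heavy-ball momentum with a bold-driver step size: grow after a cost
    decrease, halve and reset the velocity after an increase.
    """

    lambda_reg: float = 1e-4
    max_iterations: int = 5000
    learning_rate: float = 0.5
    momentum: float = 0.9
    max_learning_rate: float = 100.0
    seed: int = 0
    tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def ann_forward(weights: ANNWeights, X):
    """Network output for each row of ``X``; Tanh hidden, Sigmoid output.

    With no hidden nodes the output is the constant ``Sig(b2)``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    m = weights.W1.shape[0]
    if m == 0:
        a = np.zeros((X.shape[0], 0))
        z2 = np.full(X.shape[0], weights.b2)
    else:
        if X.shape[1] != weights.W1.shape[1]:
            raise ValueError(
                f"input width {X.shape[1]} != network inputs {weights.W1.shape[1]}"
            )
        a = np.tanh(X @ weights.W1.T + weights.b1)
        z2 = a @ weights.W2.ravel() + weights.b2
    return _sigmoid(z2), a


def _cost(weights: ANNWeights, X, y, lambda_reg: float):
    out, _ = ann_forward(weights, X)
    J = float(np.mean((y - out) ** 2))
    reg = 0.5 * lambda_reg * (
        float(np.sum(weights.W1**2)) + float(np.sum(weights.W2**2))
    )
    return J, J + reg


def ann_gradients(weights: ANNWeights, X, y, lambda_reg: float = 0.0):
    """Analytic gradients of the regularised cost (backpropagation)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    I = X.shape[0]
    out, a = ann_forward(weights, X)
    delta2 = (-2.0 / I) * (y - out) * out * (1.0 - out)  # (I,)
    g_b2 = float(delta2.sum())
    if weights.W1.shape[0] == 0:
        return (
            np.zeros_like(weights.W1),
            np.zeros_like(weights.b1),
            np.zeros_like(weights.W2),
            g_b2,
        )
    g_W2 = (delta2 @ a)[None, :] + lambda_reg * weights.W2
    delta1 = np.outer(delta2, weights.W2.ravel()) * (1.0 - a**2)  # (I, m)
    g_W1 = delta1.T @ X + lambda_reg * weights.W1
    g_b1 = delta1.sum(axis=0)
    return g_W1, g_b1, g_W2, g_b2


def _init_weights(arch: ANNArchitecture, rng: np.random.Generator) -> ANNWeights:
    n, m = arch.n_inputs, arch.m_hidden
    return ANNWeights(
        W1=rng.uniform(-0.5, 0.5, size=(m, n)),
        b1=rng.uniform(-0.5, 0.5, size=m),
        W2=rng.uniform(-0.5, 0.5, size=(1, m)),
        b2=float(rng.uniform(-0.5, 0.5)),
    )


def train_ann(X, y, arch: ANNArchitecture, config: TrainingConfig):
    """Full-batch backpropagation descent with momentum and bold-driver step.

    Returns ``(weights, info)`` where ``info`` holds the final ``J``,
    regularised cost and iteration count.  Identical config (seed included)
    gives identical weights.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 1:
        raise ValueError("need at least one training row")
    rng = np.random.default_rng(config.seed)
    w = _init_weights(arch, rng)
    lr = config.learning_rate
    J, cost = _cost(w, X, y, config.lambda_reg)
    v_W1 = np.zeros_like(w.W1)
    v_b1 = np.zeros_like(w.b1)
    v_W2 = np.zeros_like(w.W2)
    v_b2 = 0.0
    iterations = 0
    stall = 0
    for it in range(config.max_iterations):
        g_W1, g_b1, g_W2, g_b2 = ann_gradients(w, X, y, config.lambda_reg)
        v_W1 = config.momentum * v_W1 - lr * g_W1
        v_b1 = config.momentum * v_b1 - lr * g_b1
        v_W2 = config.momentum * v_W2 - lr * g_W2
        v_b2 = config.momentum * v_b2 - lr * g_b2
        trial = ANNWeights(w.W1 + v_W1, w.b1 + v_b1, w.W2 + v_W2, w.b2 + v_b2)
        J_new, cost_new = _cost(trial, X, y, config.lambda_reg)
        if not np.isfinite(cost_new):
            raise FloatingPointError(
                f"training diverged at iteration {it} (cost={cost_new})"
            )
        iterations = it + 1
        if cost_new <= cost:
            improvement = cost - cost_new
            w, J, cost = trial, J_new, cost_new
            lr = min(lr * 1.05, config.max_learning_rate)
            stall = stall + 1 if improvement < config.tol else 0
            if stall >= 10:  # converged: repeated negligible improvements
                break
        else:
            lr *= 0.5
            v_W1[:], v_b1[:], v_W2[:], v_b2 = 0.0, 0.0, 0.0, 0.0
            if lr < 1e-14:
                break
    return w, {"J": J, "J_regularized": cost, "iterations": iterations}


def prediction_risk(J: float, arch: ANNArchitecture, I: int) -> float:
    """Algebraic generalisation-error estimate ``J * (1 + 2Q/I)``."""
    if I <= 0:
        raise ValueError("I must be positive")
    return J * (1.0 + 2.0 * arch.weight_count / I)


def snc_select(
    normalized_residuals,
    n_max: int,
    m_max: int = 10,
    config: TrainingConfig = TrainingConfig(),
    restarts: int = 5,
):
    """Two-step sequential network construction.

    Step 1 fixes ``n = n_max`` and scans ``m`` in 0..m_max; step 2 fixes the
    chosen ``m`` and scans ``n`` in 1..n_max.  Each candidate is trained on
    all available rows from ``restarts`` seeds and compared on its median
    prediction risk.  Returns ``(architecture, report)`` where the report
    lists every candidate's risk; candidates with too few rows are skipped.
    """
    values = np.asarray(normalized_residuals, dtype=float)
    if values.size <= n_max:
        raise ValueError("not enough residuals for n_max lags")

    def median_risk(n, m):
        X, y = build_lag_matrix(values, n)
        arch = ANNArchitecture(n, m)
        risks = []
        for r in range(restarts):
            cfg = replace(config, seed=config.seed + 1000 * r)
            _, info = train_ann(X, y, arch, cfg)
            risks.append(prediction_risk(info["J"], arch, X.shape[0]))
        return float(np.median(risks))

    step1 = []
    for m in range(m_max + 1):
        step1.append({"n": n_max, "m": m, "risk": median_risk(n_max, m)})
    m_best = min(step1, key=lambda row: (row["risk"], row["m"]))["m"]

    step2 = []
    for n in range(1, n_max + 1):
        if values.size <= n:
            continue  # not enough rows for this lag depth
        step2.append({"n": n, "m": m_best, "risk": median_risk(n, m_best)})
    n_best = min(step2, key=lambda row: (row["risk"], row["n"]))["n"]

    return ANNArchitecture(n_best, m_best), {"step1": step1, "step2": step2}


# ---------------------------------------------------------------------------
# The assembled hybrid model
# ---------------------------------------------------------------------------


@dataclass
class HybridModel:
    """ARIMA fit + trained residual network + normalisation spec."""

    arima_fit: ArimaFit
    architecture: ANNArchitecture
    weights: ANNWeights
    norm_spec: NormalizationSpec
    residuals: np.ndarray  # training residuals, raw scale

    def to_json(self) -> str:
        payload = {
            "arima": {
                "order": self.arima_fit.order.as_tuple(),
                "phi": self.arima_fit.phi.tolist(),
                "theta": self.arima_fit.theta.tolist(),
                "mu": self.arima_fit.mu,
                "sigma2": self.arima_fit.sigma2,
                "trend": self.arima_fit.trend,
            },
            "architecture": {
                "n_inputs": self.architecture.n_inputs,
                "m_hidden": self.architecture.m_hidden,
            },
            "weights": {
                "W1": self.weights.W1.tolist(),
                "b1": self.weights.b1.tolist(),
                "W2": self.weights.W2.tolist(),
                "b2": self.weights.b2,
            },
            "normalization": {
                "min_value": self.norm_spec.min_value,
                "max_value": self.norm_spec.max_value,
            },
            "residuals": self.residuals.tolist(),
        }
        return json.dumps(payload, indent=2)


def fit_hybrid(
    series,
    arima_fit: ArimaFit,
    n_max: int,
    m_max: int = 10,
    config: TrainingConfig = TrainingConfig(),
    restarts: int = 5,
) -> HybridModel:
    """Residual extraction, normalisation, SNC selection, final training."""
    resid = extract_residuals(series, arima_fit)
    scaled, spec = normalize(resid.values)
    arch, _ = snc_select(scaled, n_max=n_max, m_max=m_max, config=config,
                         restarts=restarts)
    X, y = build_lag_matrix(scaled, arch.n_inputs)
    weights, _ = train_ann(X, y, arch, config)
    return HybridModel(
        arima_fit=arima_fit,
        architecture=arch,
        weights=weights,
        norm_spec=spec,
        residuals=resid.values.copy(),
    )


def hybrid_forecast(model: HybridModel, h: int, level: float = 0.95):
    """Recursive h-step hybrid forecast ``y_hat = L_hat + N_hat``.

    The network predicts the next normalised residual from its lag window;
    the prediction is appended to the window for subsequent steps.  Returns
    ``(points, arima_result)`` so interval policies can build on the ARIMA
    interval.
    """
    n = model.architecture.n_inputs
    scaled, _ = normalize(model.residuals, model.norm_spec)
    if scaled.size < n:
        raise ValueError("insufficient residual history for the lag window")
    window = list(scaled[-n:][::-1])  # most recent first
    ar = arima_forecast(model.arima_fit, h, level=level)
    points = np.empty(h)
    for j in range(h):
        out, _ = ann_forward(model.weights, np.asarray(window)[None, :])
        n_hat = denormalize(float(out[0]), model.norm_spec)
        points[j] = ar.point[j] + n_hat
        window = [float(out[0])] + window[:-1]
    return points, ar


def hybrid_prediction_interval(
    arima_lower,
    arima_upper,
    ann_adjustment,
    policy: str = "shift",
    hybrid_errors=None,
    point=None,
    level: float = 0.95,
    n_resamples: int = 10000,
    seed: int = 0,
):
    """Interval for the hybrid forecast.

    ``shift`` (default) translates the ARIMA interval by the network's
    point adjustment, preserving its width.  ``bootstrap`` centres the
    interval on the hybrid point forecast and takes percentiles of
    resampled hybrid training errors around it (seed-controlled).
    """
    arima_lower = np.asarray(arima_lower, dtype=float)
    arima_upper = np.asarray(arima_upper, dtype=float)
    adj = np.asarray(ann_adjustment, dtype=float)
    if policy == "shift":
        return arima_lower + adj, arima_upper + adj
    if policy == "bootstrap":
        if hybrid_errors is None or point is None:
            raise ValueError("bootstrap policy needs hybrid_errors and point")
        rng = np.random.default_rng(seed)
        errors = np.asarray(hybrid_errors, dtype=float)
        samples = rng.choice(errors, size=n_resamples, replace=True)
        lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2
        lo, hi = np.percentile(samples, [lo_q, hi_q])
        point = np.asarray(point, dtype=float)
        return point + lo, point + hi
    raise ValueError(f"unknown policy {policy!r}")
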