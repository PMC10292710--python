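"""ARIMA(p,d,q) fitting, order selection, and interval forecasting.

Maximum-likelihood fitting is delegated to statsmodels; what this module
owns is the order-selection procedure and the residual-sum-of-squares
approximation of the AIC used to score candidate orders,

    AIC = k * [log(2*pi*RSS/k) + 1] + 2*(p + q)

with ``k`` the number of usable observations after differencing.  Two
searches over (p, q) are provided:

* :func:`stepwise_search` — the Hyndman-Khandakar local search used by the
  standard auto-ARIMA tools (start from {(2,2),(0,0),(1,0),(0,1)}, move to
  the best-scoring neighbour until no neighbour improves).  This is the
  package default: on short noisy annual series it terminates at the
  parsimonious orders the auto-ARIMA tools report.
* :func:`grid_search` — exhaustive over the full (p, q) grid.

The differencing order ``d`` is chosen by the Augmented Dickey-Fuller test
(smallest ``d >= 1`` whose d-th difference is stationary at the 5% level).
For ``d = 1`` the model includes a drift term, matching the auto-ARIMA
default for once-differenced series; ``d >= 2`` fits without a constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ArimaOrder",
    "ArimaFit",
    "ForecastResult",
    "ArimaBoundaryWarning",
    "adf_select_d",
    "fit_arima",
    "aic",
    "grid_search",
    "stepwise_search",
    "select_order",
    "forecast",
]


class ArimaBoundaryWarning(UserWarning):
    """The MLE landed on a non-invertible or non-stationary solution."""


@dataclass(frozen=True)
class ArimaOrder:
    """Non-seasonal order (p, d, q); p, q in 0..5 and d in 1..3."""

    p: int
    d: int
    q: int

    def __post_init__(self) -> None:
        if not (0 <= self.p <= 5 and 0 <= self.q <= 5):
            raise ValueError("p and q must be between 0 and 5")
        if not (0 <= self.d <= 3):
            raise ValueError("d must be between 0 and 3")

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.p, self.d, self.q)


@dataclass
class ArimaFit:
    """A fitted ARIMA model with the quantities order selection needs.

    ``residuals`` are the one-step in-sample prediction errors after the
    first ``d`` observations (the usable series); ``rss`` is their sum of
    squares and ``aic`` the RSS-based criterion used for order selection.
    """

    order: ArimaOrder
    phi: np.ndarray
    theta: np.ndarray
    mu: float
    sigma2: float
    residuals: np.ndarray
    fitted_values: np.ndarray  # aligned with the full input series
    rss: float
    loglik: float
    aic: float
    trend: str
    _results: object = None  # statsmodels results, kept for forecasting

    @property
    def n_obs(self) -> int:
        return int(self.residuals.size)


@dataclass(frozen=True)
class ForecastResult:
    """Point forecasts with a symmetric Gaussian prediction interval."""

    horizon: int
    point: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float


def adf_select_d(series, d_max: int = 3, alpha: float = 0.05) -> int:
    """Smallest d in [1, d_max] whose d-th difference passes the ADF test.

    The search floor is d = 1 (the series the procedure targets are
    integrated counts); if no difference up to ``d_max`` is stationary at
    level ``alpha``, ``d_max`` is returned.  The test uses a constant term
    and the fixed lag order ``trunc((n-1)**(1/3))`` of the auto-ARIMA
    tools, which keeps power on short annual series where an
    information-criterion lag search saturates.
    """
    from statsmodels.tsa.stattools import adfuller

    series = np.asarray(series, dtype=float)
    if series.size < 10:
        raise ValueError("series too short for differencing selection")
    for d in range(1, d_max + 1):
        diff = np.diff(series, n=d)
        if diff.size < 8:
            raise ValueError("series too short after differencing")
        maxlag = int(np.power(diff.size - 1, 1.0 / 3.0))
        try:
            pvalue = adfuller(diff, regression="c", maxlag=maxlag, autolag=None)[1]
        except Exception:
            continue
        if pvalue < alpha:
            return d
    return d_max


def aic(rss: float, n_obs: int, p: int, q: int) -> float:
    """RSS-based AIC approximation used to rank candidate orders."""
    if rss <= 0:
        raise ValueError("RSS must be positive")
    if n_obs <= 0:
        raise ValueError("n_obs must be positive")
    return n_obs * (np.log(2.0 * np.pi * rss / n_obs) + 1.0) + 2.0 * (p + q)


def _default_trend(d: int) -> str:
    return "t" if d == 1 else ("c" if d == 0 else "n")


def fit_arima(series, order: ArimaOrder, trend: str | None = None) -> ArimaFit:
    """Fit by exact maximum likelihood (statsmodels state-space ARIMA).

    ``trend`` defaults by differencing order: drift for d = 1, a constant
    for d = 0, none for d >= 2.  A non-invertible or non-stationary MLE
    solution triggers :class:`ArimaBoundaryWarning` (the fit is returned).
    """
    from statsmodels.tsa.arima.model import ARIMA

    series = np.asarray(series, dtype=float)
    if isinstance(order, tuple):
        order = ArimaOrder(*order)
    if series.size <= order.p + order.q + order.d + 1:
        raise ValueError("series too short for the requested order")
    if trend is None:
        trend = _default_trend(order.d)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = ARIMA(series, order=order.as_tuple(), trend=trend)
        results = model.fit()
    resid = np.asarray(results.resid[order.d :], dtype=float)
    rss = float(resid @ resid)
    params = results.params
    names = list(results.param_names)
    phi = np.array([params[names.index(f"ar.L{i}")] for i in range(1, order.p + 1)])
    theta = np.array([params[names.index(f"ma.L{i}")] for i in range(1, order.q + 1)])
    mu = 0.0
    for cand in ("x1", "const", "intercept", "drift", "trend"):
        if cand in names:
            mu = float(params[names.index(cand)])
            break
    sigma2 = float(params[names.index("sigma2")]) if "sigma2" in names else float(
        resid.var()
    )
    if (order.q and np.any(np.abs(results.maroots) < 1.0 - 1e-8)) or (
        order.p and np.any(np.abs(results.arroots) < 1.0 - 1e-8)
    ):
        warnings.warn(
            f"MLE for order {order.as_tuple()} is non-invertible/non-stationary",
            ArimaBoundaryWarning,
            stacklevel=2,
        )
    return ArimaFit(
        order=order,
        phi=phi,
        theta=theta,
        mu=mu,
        sigma2=sigma2,
        residuals=resid,
        fitted_values=np.asarray(results.fittedvalues, dtype=float),
        rss=rss,
        loglik=float(results.llf),
        aic=aic(rss, resid.size, order.p, order.q),
        trend=trend,
        _results=results,
    )


def _try_fit(series, p, d, q, trend, cache):
    key = (p, q, trend)
    if key in cache:
        return cache[key]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_arima(series, ArimaOrder(p, d, q), trend=trend)
        if not np.isfinite(fit.aic):
            fit = None
    except Exception:
        fit = None
    cache[key] = fit
    return fit


def _better(candidate: ArimaFit | None, incumbent: ArimaFit | None) -> bool:
    """Smaller AIC wins; ties break toward smaller p+q, then smaller q."""
    if candidate is None:
        return False
    if incumbent is None:
        return True
    a = (candidate.aic, candidate.order.p + candidate.order.q, candidate.order.q)
    b = (incumbent.aic, incumbent.order.p + incumbent.order.q, incumbent.order.q)
    return a < b


def grid_search(
    series,
    p_max: int = 5,
    q_max: int = 5,
    d_max: int = 3,
    d: int | None = None,
) -> tuple[ArimaOrder, ArimaFit, dict]:
    """Exhaustive (p, q) search at the ADF-selected d, scored by the
    RSS-based AIC.  Returns the winner and a log of every candidate's score.
    """
    series = np.asarray(series, dtype=float)
    if d is None:
        d = adf_select_d(series, d_max=d_max)
    trend = _default_trend(d)
    cache: dict = {}
    best = None
    log = {}
    for p in range(p_max + 1):
        for q in range(q_max + 1):
            fit = _try_fit(series, p, d, q, trend, cache)
            log[(p, d, q)] = fit.aic if fit is not None else np.inf
            if _better(fit, best):
                best = fit
    if best is None:
        raise RuntimeError("every candidate order failed to fit")
    return best.order, best, {"aic": log, "n_candidates": len(log)}


def stepwise_search(
    series,
    p_max: int = 5,
    q_max: int = 5,
    d_max: int = 3,
    d: int | None = None,
    max_steps: int = 50,
) -> tuple[ArimaOrder, ArimaFit, dict]:
    """Hyndman-Khandakar stepwise (p, q) search scored by the RSS-based AIC.

    Starts from {(2,2), (0,0), (1,0), (0,1)} and repeatedly moves to the
    best admissible neighbour (p and/or q changed by one, or the drift term
    toggled when d = 1) until no neighbour improves.  This is the selection
    procedure of the standard auto-ARIMA tools.
    """
    series = np.asarray(series, dtype=float)
    if d is None:
        d = adf_select_d(series, d_max=d_max)
    base_trend = _default_trend(d)
    trends = (base_trend, "n") if base_trend != "n" else ("n",)
    cache: dict = {}
    log: dict = {}

    def score(p, q, trend):
        fit = _try_fit(series, p, d, q, trend, cache)
        log[(p, d, q, trend)] = fit.aic if fit is not None else np.inf
        return fit

    best = None
    for p, q in ((2, 2), (0, 0), (1, 0), (0, 1)):
        if p <= p_max and q <= q_max:
            fit = score(p, q, base_trend)
            if _better(fit, best):
                best = fit
    if best is None:
        raise RuntimeError("no starting candidate could be fitted")

    for _ in range(max_steps):
        p0, q0, t0 = best.order.p, best.order.q, best.trend
        candidates = []
        for dp in (-1, 0, 1):
            for dq in (-1, 0, 1):
                p, q = p0 + dp, q0 + dq
                if (dp, dq) != (0, 0) and 0 <= p <= p_max and 0 <= q <= q_max:
                    candidates.append((p, q, t0))
        for trend in trends:  # toggle the deterministic term
            if trend != t0:
                candidates.append((p0, q0, trend))
        improved = False
        for p, q, trend in candidates:
            fit = score(p, q, trend)
            if _better(fit, best):
                best = fit
                improved = True
        if not improved:
            break
    return best.order, best, {"aic": log, "n_candidates": len(log)}


def select_order(
    series,
    p_max: int = 5,
    q_max: int = 5,
    d_max: int = 3,
    method: str = "stepwise",
) -> tuple[ArimaOrder, ArimaFit, dict]:
    """Order selection entry point (``method``: 'stepwise' or 'exhaustive')."""
    if method == "stepwise":
        return stepwise_search(series, p_max=p_max, q_max=q_max, d_max=d_max)
    if method == "exhaustive":
        return grid_search(series, p_max=p_max, q_max=q_max, d_max=d_max)
    raise ValueError(f"unknown method {method!r}")


def forecast(fit: ArimaFit, h: int, level: float = 0.95) -> ForecastResult:
    """h-step point forecasts with Gaussian prediction intervals."""
    if h < 1:
        raise ValueError("h must be >= 1")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    prediction = fit._results.get_forecast(h)
    point = np.asarray(prediction.predicted_mean, dtype=float)
    se = np.asarray(prediction.se_mean, dtype=float)
    z = stats.norm.ppf(0.5 + level / 2.0)
    return ForecastResult(
        horizon=h,
        point=point,
        lower=point - z * se,
        upper=point + z * se,
        level=level,
    )
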