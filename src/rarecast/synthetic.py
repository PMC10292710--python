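"""Seeded generators for the two kinds of data the analysis consumes.

* Piecewise non-homogeneous Poisson process (NHPP) event streams with
  Weibull-geometric intensities and known parameters and change points,
  sampled exactly by inversion of the closed-form cumulative intensity.
* Annual series with an ARIMA(0,1,1) linear core, a known nonlinear signal
  in the innovations, and additive Gaussian noise — the structure the
  hybrid ARIMA-ANN model assumes.

Every generator is a pure function of its scenario (including the seed).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

from .changepoint import WGParams, piecewise_cumulative, wg_cumulative, _g, _g_inv
from .data import EventSeries, ORIGIN_DATE

__all__ = [
    "NhppScenario",
    "HybridScenario",
    "NONLINEAR_REGISTRY",
    "simulate_nhpp",
    "simulate_hybrid_series",
    "expected_count",
]


@dataclass(frozen=True)
class NhppScenario:
    """A piecewise-WG NHPP: ``segments`` is an ordered list of
    ``(WGParams, segment_end_time_days)`` whose last end equals
    ``total_horizon``.  Rates run on the global clock (no reset at a
    change point), matching the likelihood convention of the model.
    """

    segments: tuple
    total_horizon: float
    seed: int
    origin_date: _dt.date = ORIGIN_DATE

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if not self.segments:
            raise ValueError("at least one segment required")
        ends = [end for _, end in self.segments]
        if any(b <= a for a, b in zip(ends, ends[1:])) or ends[0] <= 0:
            raise ValueError("segment end times must be strictly increasing")
        if ends[-1] != self.total_horizon:
            raise ValueError("last segment end must equal total_horizon")

    @property
    def params_per_segment(self) -> list[WGParams]:
        return [p for p, _ in self.segments]

    @property
    def change_points(self) -> np.ndarray:
        return np.asarray([end for _, end in self.segments[:-1]], dtype=float)


def expected_count(scenario: NhppScenario, t: float | None = None) -> float:
    """Cumulative intensity of the scenario at ``t`` (default: horizon)."""
    t = scenario.total_horizon if t is None else t
    return piecewise_cumulative(
        scenario.params_per_segment,
        scenario.change_points,
        scenario.total_horizon,
        t,
    )


def simulate_nhpp(scenario: NhppScenario) -> EventSeries:
    """Draw one event stream by inversion of the cumulative intensity.

    The next event after time ``t`` is at ``Lambda^-1(Lambda(t) + E)`` with
    ``E ~ Exponential(1)``; the stream is truncated at the horizon.
    Inversion (rather than thinning) stays exact even when ``alpha < 1``
    makes the rate unbounded near the origin.
    """
    rng = np.random.default_rng(scenario.seed)
    params = scenario.params_per_segment
    bounds = np.concatenate(
        ([0.0], scenario.change_points, [scenario.total_horizon])
    )
    # cumulative intensity accrued at each segment boundary
    seg_offsets = np.zeros(len(params) + 1)
    for j, p in enumerate(params):
        seg_offsets[j + 1] = seg_offsets[j] + (
            wg_cumulative(p, bounds[j + 1]) - wg_cumulative(p, bounds[j])
        )

    times: list[float] = []
    m = 0.0  # current cumulative intensity
    total = seg_offsets[-1]
    while True:
        m += rng.exponential()
        if m >= total:
            break
        j = int(np.searchsorted(seg_offsets, m, side="right") - 1)
        p = params[j]
        # invert within segment j on the global clock
        target = m - seg_offsets[j] + wg_cumulative(p, bounds[j])
        s = _g_inv(target, p.rho)
        t = p.beta * s ** (1.0 / p.alpha)
        times.append(float(t))
    return EventSeries(
        np.asarray(times), scenario.origin_date, float(scenario.total_horizon)
    )


def _nl_zero(e1: float, e2: float) -> float:
    return 0.0


def _nl_quadratic(e1: float, e2: float) -> float:
    return 0.4 * e1 * e1 - 0.2 * e1 * e2


def _nl_sine(e1: float, e2: float) -> float:
    return np.sin(2.0 * e1) + 0.5 * np.cos(e2)


def _nl_threshold(e1: float, e2: float) -> float:
    return 1.0 if e1 > 0 and e2 > 0 else -0.5 if e1 < 0 else 0.0

#: Named deterministic maps applied to the two most recent innovations.
NONLINEAR_REGISTRY = {
    "zero": _nl_zero,
    "quadratic": _nl_quadratic,
    "sine": _nl_sine,
    "threshold": _nl_threshold,
}


@dataclass(frozen=True)
class HybridScenario:
    """Annual series with a linear ARIMA(0,1,1) core plus nonlinear signal.

    The level evolves as ``y_t = y_{t-1} + drift + eps_t - theta1*eps_{t-1}
    + f(eps_{t-1}, eps_{t-2})`` with ``eps ~ N(0, noise_sd^2)`` and ``f``
    drawn from :data:`NONLINEAR_REGISTRY`, so the first differences carry an
    MA(1) signature with lag-1 autocorrelation ``-theta1/(1+theta1^2)`` when
    ``f`` is zero.
    """

    n_years: int
    theta1: float = 0.5
    drift: float = 0.1
    nonlinear_fn: str = "zero"
    noise_sd: float = 1.0
    seed: int = 0
    base_level: float = 2.0

    def __post_init__(self) -> None:
        if self.n_years < 10:
            raise ValueError("n_years must be >= 10")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.nonlinear_fn not in NONLINEAR_REGISTRY:
            raise KeyError(
                f"unknown nonlinear_fn {self.nonlinear_fn!r}; "
                f"choose from {sorted(NONLINEAR_REGISTRY)}"
            )


def simulate_hybrid_series(
    scenario: HybridScenario,
    as_counts: bool = False,
    start_year: int = 1966,
):
    """Generate the annual series (real-valued, or rounded non-negative
    integer counts when ``as_counts`` is set, for count-model tests).
    """
    rng = np.random.default_rng(scenario.seed)
    f = NONLINEAR_REGISTRY[scenario.nonlinear_fn]
    eps = rng.normal(0.0, scenario.noise_sd, size=scenario.n_years + 2)
    y = np.empty(scenario.n_years)
    level = scenario.base_level
    for t in range(scenario.n_years):
        e_t, e_1, e_2 = eps[t + 2], eps[t + 1], eps[t]
        level = level + scenario.drift + e_t - scenario.theta1 * e_1 + f(e_1, e_2)
        y[t] = level
    if as_counts:
        from .data import AnnualCounts

        return AnnualCounts(start_year, np.maximum(np.rint(y), 0).astype(int))
    return y
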