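"""Rolling-origin model comparison and future-forecast harness.

Six model variants are compared on the annual series: the change-point
NHPP (posterior-mean annual counts), the AIC-selected ARIMA, and the
hybrid ARIMA-ANN at four caps on the number of input lags (3, 5, 7, 10).
The training window always starts at the first year of record; its last
year T rolls forward one year at a time, and both training-set fit and
test-set forecast accuracy are scored with RMSE and MAPE.

Zero-count years make raw MAPE undefined; the default policy excludes
zero-actual terms and reports how many were excluded (an epsilon-floor
policy is available).
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, replace as _replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import arima as _arima
from . import changepoint as _cp
from . import hybrid as _hybrid
from .data import AnnualCounts, EventSeries, day_offset, split_by_year, truncate_events

__all__ = [
    "ModelVariant",
    "MapeResult",
    "rmse",
    "mape",
    "rolling_evaluation",
    "future_forecast_comparison",
    "report",
    "VARIANT_NAMES",
]

VARIANT_NAMES = (
    "changepoint_wg",
    "arima",
    "hybrid_n3",
    "hybrid_n5",
    "hybrid_n7",
    "hybrid_n10",
)


@dataclass(frozen=True)
class ModelVariant:
    """A named model configuration used in the comparison."""

    name: str
    kind: str  # "changepoint" | "arima" | "hybrid"
    n_max: int | None = None
    seed: int = 0

    @classmethod
    def from_name(cls, name: str, seed: int = 0) -> "ModelVariant":
        if name == "changepoint_wg":
            return cls(name, "changepoint", seed=seed)
        if name == "arima":
            return cls(name, "arima", seed=seed)
        if name.startswith("hybrid_n"):
            n_max = int(name.removeprefix("hybrid_n"))
            if n_max not in (3, 5, 7, 10):
                raise ValueError(f"hybrid variants use n_max in 3/5/7/10, got {n_max}")
            return cls(name, "hybrid", n_max=n_max, seed=seed)
        raise ValueError(
            f"unknown variant {name!r}; valid names: {', '.join(VARIANT_NAMES)}"
        )


def rmse(actual, predicted) -> float:
    """Root mean squared error."""
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape or actual.size < 1:
        raise ValueError("actual and predicted must be equal-length, non-empty")
    return float(np.sqrt(np.mean((actual - predicted) ** 2)))


@dataclass(frozen=True)
class MapeResult:
    value: float
    n_excluded: int

    def __float__(self) -> float:
        return self.value


def mape(actual, predicted, zero_policy: str = "exclude_zero_actuals",
         epsilon: float = 0.5) -> MapeResult:
    """Mean absolute percentage error (in percent).

    Terms with a zero actual are either dropped (``exclude_zero_actuals``,
    the default; the number dropped is reported) or kept with the zero
    replaced by ``epsilon`` (``epsilon_floor``).
    """
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape or actual.size < 1:
        raise ValueError("actual and predicted must be equal-length, non-empty")
    zeros = actual == 0
    if zero_policy == "exclude_zero_actuals":
        if np.all(zeros):
            raise ValueError("all actual values are zero under the exclude policy")
        a, p = actual[~zeros], predicted[~zeros]
        value = float(np.mean(np.abs(a - p) / np.abs(a)) * 100.0)
        return MapeResult(value, int(zeros.sum()))
    if zero_policy == "epsilon_floor":
        denom = np.where(zeros, epsilon, np.abs(actual))
        value = float(np.mean(np.abs(actual - predicted) / denom) * 100.0)
        return MapeResult(value, 0)
    raise ValueError(f"unknown zero_policy {zero_policy!r}")


# ---------------------------------------------------------------------------
# Per-variant fit + predict on one split
# ---------------------------------------------------------------------------


def _arima_fit_for(train: AnnualCounts, arima_order=None):
    if arima_order is None:
        _, fit, _ = _arima.select_order(train.values())
    else:
        fit = _arima.fit_arima(train.values(), _arima.ArimaOrder(*arima_order))
    return fit


def _evaluate_arima(train, test, arima_order, zero_policy):
    fit = _arima_fit_for(train, arima_order)
    d = fit.order.d
    train_actual = train.values()[d:]
    train_pred = fit.fitted_values[d:]
    fc = _arima.forecast(fit, len(test))
    return {
        "train_rmse": rmse(train_actual, train_pred),
        "train_mape": mape(train_actual, train_pred, zero_policy).value,
        "test_rmse": rmse(test.values(), fc.point),
        "test_mape": mape(test.values(), fc.point, zero_policy).value,
    }


def _evaluate_hybrid(train, test, variant, arima_order, zero_policy,
                     ann_config, restarts):
    fit = _arima_fit_for(train, arima_order)
    cfg = _replace(ann_config, seed=ann_config.seed + variant.seed)
    model = _hybrid.fit_hybrid(
        train.values(), fit, n_max=variant.n_max, config=cfg, restarts=restarts
    )
    n, d = model.architecture.n_inputs, fit.order.d
    scaled, _ = _hybrid.normalize(model.residuals, model.norm_spec)
    X, _ = _hybrid.build_lag_matrix(scaled, n)
    out, _ = _hybrid.ann_forward(model.weights, X)
    n_hat = _hybrid.denormalize(out, model.norm_spec)
    # hybrid in-sample prediction exists once the lag window is full
    usable = slice(d + n, len(train))
    train_actual = train.values()[usable]
    train_pred = fit.fitted_values[usable] + n_hat
    points, _ = _hybrid.hybrid_forecast(model, len(test))
    return {
        "train_rmse": rmse(train_actual, train_pred),
        "train_mape": mape(train_actual, train_pred, zero_policy).value,
        "test_rmse": rmse(test.values(), points),
        "test_mape": mape(test.values(), points, zero_policy).value,
    }


def _evaluate_changepoint(train, test, events, variant, zero_policy, mcmc):
    end_day = day_offset(_dt.date(train.end_year, 12, 31), events.origin_date)
    fit_events = truncate_events(events, end_day)
    spec = _cp.ChangePointSpec(
        observation_end=end_day, n_change_points=mcmc.get("n_change_points", 0)
    )
    draws = _cp.sample_posterior(
        fit_events,
        spec,
        n_chains=mcmc.get("n_chains", 4),
        n_warmup=mcmc.get("n_warmup", 1500),
        n_draws=mcmc.get("n_draws", 1500),
        seed=mcmc.get("seed", 0) + variant.seed,
    )
    all_years = list(range(train.start_year, test.end_year + 1))
    per_year = np.zeros(len(all_years))
    flat = draws.flat
    for x in flat:
        segs, taus = spec.unpack(x)
        per_year += _cp.expected_annual_counts(
            spec, segs, taus, all_years, events.origin_date
        )
    per_year /= len(flat)
    k = len(train)
    return {
        "train_rmse": rmse(train.values(), per_year[:k]),
        "train_mape": mape(train.values(), per_year[:k], zero_policy).value,
        "test_rmse": rmse(test.values(), per_year[k:]),
        "test_mape": mape(test.values(), per_year[k:], zero_policy).value,
    }


def rolling_evaluation(
    counts: AnnualCounts,
    events: EventSeries | None = None,
    variants=VARIANT_NAMES,
    t_range=range(2003, 2015),
    seed: int = 0,
    arima_order=(0, 1, 1),
    zero_policy: str = "exclude_zero_actuals",
    ann_config: _hybrid.TrainingConfig | None = None,
    snc_restarts: int = 5,
    mcmc: dict | None = None,
) -> pd.DataFrame:
    """Train/test RMSE and MAPE for each variant and each training end T.

    ``arima_order=None`` re-selects the order per window by the default
    stepwise search; the fixed (0,1,1) default is the order that search
    returns on every window of the study data.  Change-point fits use the
    event series truncated at the calendar end of year T.  Fit failures are
    recorded as NaN rows, not raised.
    """
    if ann_config is None:
        ann_config = _hybrid.TrainingConfig(seed=seed)
    mcmc = dict(mcmc or {})
    mcmc.setdefault("seed", seed)
    rows = []
    for T in t_range:
        split = split_by_year(counts, T)
        for name in variants:
            variant = ModelVariant.from_name(name, seed=seed)
            try:
                if variant.kind == "arima":
                    metrics = _evaluate_arima(
                        split.train, split.test, arima_order, zero_policy
                    )
                elif variant.kind == "hybrid":
                    metrics = _evaluate_hybrid(
                        split.train, split.test, variant, arima_order,
                        zero_policy, ann_config, snc_restarts,
                    )
                elif variant.kind == "changepoint":
                    if events is None:
                        raise ValueError("changepoint variant needs an EventSeries")
                    metrics = _evaluate_changepoint(
                        split.train, split.test, events, variant, zero_policy, mcmc
                    )
                else:  # pragma: no cover
                    raise ValueError(variant.kind)
            except Exception as exc:  # recorded, not fatal
                metrics = {
                    "train_rmse": np.nan,
                    "train_mape": np.nan,
                    "test_rmse": np.nan,
                    "test_mape": np.nan,
                    "error": f"{type(exc).__name__}: {exc}",
                }
            rows.append({"variant": name, "T": T, **metrics})
    frame = pd.DataFrame(rows)
    if "error" not in frame.columns:
        frame["error"] = None
    return frame


# ---------------------------------------------------------------------------
# Forecasts beyond the record
# ---------------------------------------------------------------------------


def future_forecast_comparison(
    counts_with_final_year: AnnualCounts,
    events: EventSeries | None = None,
    variants=VARIANT_NAMES,
    seed: int = 0,
    horizon: int = 5,
    level: float = 0.95,
    arima_order=(0, 1, 1),
    ann_config: _hybrid.TrainingConfig | None = None,
    snc_restarts: int = 5,
    mcmc: dict | None = None,
) -> dict:
    """Five-year forecasts from the full record, with and without its final
    year, plus first-year prediction intervals for each variant.

    The input series must include the post-study final year (2020 for the
    embedded data); the comparison runs each variant on the series without
    it and on the full series.
    """
    if ann_config is None:
        ann_config = _hybrid.TrainingConfig(seed=seed)
    mcmc = dict(mcmc or {})
    mcmc.setdefault("seed", seed)
    full = counts_with_final_year
    shorter = AnnualCounts(full.start_year, full.counts[:-1])
    out: dict = {"windows": {}, "level": level}
    for label, train in (("without_final_year", shorter), ("with_final_year", full)):
        first_forecast_year = train.end_year + 1
        window: dict = {
            "train_years": [train.start_year, train.end_year],
            "forecast_years": list(
                range(first_forecast_year, first_forecast_year + horizon)
            ),
            "variants": {},
        }
        for name in variants:
            variant = ModelVariant.from_name(name, seed=seed)
            entry: dict = {}
            if variant.kind == "arima":
                fit = _arima_fit_for(train, arima_order)
                fc = _arima.forecast(fit, horizon, level=level)
                entry["point"] = fc.point.tolist()
                entry["interval_first_year"] = [float(fc.lower[0]), float(fc.upper[0])]
            elif variant.kind == "hybrid":
                fit = _arima_fit_for(train, arima_order)
                cfg = _replace(ann_config, seed=ann_config.seed + variant.seed)
                model = _hybrid.fit_hybrid(
                    train.values(), fit, n_max=variant.n_max,
                    config=cfg, restarts=snc_restarts,
                )
                points, ar = _hybrid.hybrid_forecast(model, horizon, level=level)
                adj = points[0] - ar.point[0]
                lo, hi = _hybrid.hybrid_prediction_interval(
                    ar.lower[0], ar.upper[0], adj
                )
                entry["point"] = points.tolist()
                entry["interval_first_year"] = [float(lo), float(hi)]
                entry["architecture"] = {
                    "n_inputs": model.architecture.n_inputs,
                    "m_hidden": model.architecture.m_hidden,
                }
            elif variant.kind == "changepoint":
                if events is None:
                    raise ValueError("changepoint variant needs an EventSeries")
                end_day = day_offset(
                    _dt.date(train.end_year, 12, 31), events.origin_date
                )
                fit_events = truncate_events(events, end_day)
                spec = _cp.ChangePointSpec(
                    observation_end=end_day,
                    n_change_points=mcmc.get("n_change_points", 0),
                )
                draws = _cp.sample_posterior(
                    fit_events,
                    spec,
                    n_chains=mcmc.get("n_chains", 4),
                    n_warmup=mcmc.get("n_warmup", 1500),
                    n_draws=mcmc.get("n_draws", 1500),
                    seed=mcmc["seed"],
                )
                fc = _cp.forecast_annual(
                    draws, fit_events, horizon_years=horizon,
                    level=level, seed=mcmc["seed"] + 1,
                )
                entry["point"] = fc.mean.tolist()
                entry["interval_first_year"] = [float(fc.lower[0]), float(fc.upper[0])]
                entry["rhat_max"] = float(max(draws.rhat.values()))
            window["variants"][name] = entry
        out["windows"][label] = window
    return out


def report(
    metric_table: pd.DataFrame | None,
    comparison: dict | None,
    out_dir,
    manifest: dict | None = None,
    plots: bool = False,
) -> list[str]:
    """Write the comparison artefacts (CSV metrics, JSON forecasts, run
    manifest, optional figures) under ``out_dir``; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    if metric_table is not None:
        path = out / "metrics.csv"
        metric_table.to_csv(path, index=False)
        written.append(str(path))
    if comparison is not None:
        path = out / "future_forecasts.json"
        path.write_text(json.dumps(comparison, indent=2))
        written.append(str(path))
    manifest = dict(manifest or {})
    manifest.setdefault("written_at", "deterministic-run")
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    written.append(str(path))
    if plots and metric_table is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for metric in ("train_rmse", "test_rmse", "train_mape", "test_mape"):
            fig, ax = plt.subplots(figsize=(7, 4))
            for name, group in metric_table.groupby("variant"):
                ax.plot(group["T"], group[metric], marker="o", label=name)
            ax.set_xlabel("last training year T")
            ax.set_ylabel(metric)
            ax.legend(fontsize=7)
            fig.tight_layout()
            fig_path = out / f"{metric}.png"
            fig.savefig(fig_path, dpi=120)
            plt.close(fig)
            written.append(str(fig_path))
    return written
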