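# rarecast

Forecasting annual counts of rare events — specifically U.S. public mass
shootings, 1966–2020 — with three model families, and comparing them under a
rolling-origin evaluation:

1. **Bayesian change-point NHPP** — a non-homogeneous Poisson process on the
   raw event times with a Weibull-geometric intensity whose parameters may
   switch at unknown change points, fit by MCMC.
2. **ARIMA** — AIC-selected order on the annual counts (the selection lands
   on ARIMA(0,1,1) with drift on every training window), with Gaussian
   prediction intervals.
3. **Hybrid ARIMA–ANN** — a small feed-forward network trained by
   backpropagation on the ARIMA residuals, with its architecture chosen by a
   prediction-risk criterion (sequential network construction), added to the
   ARIMA forecast.

The study data are embedded: an event-time table (173 events, days since
1966-08-01) and an annual-count table (1966–2019 plus the single 2020 event).
The two tables disagree slightly; the package keeps both verbatim and reports
the differences (`rarecast.data.consistency_report()`). See
[docs/methods.md](docs/methods.md) for model assumptions, parameterisations,
design choices, and limitations.

## Worked example

ARIMA on the annual counts — order selection and the 2020 interval:

```python
from rarecast.data import load_annual_fixture
from rarecast.arima import select_order, forecast

counts = load_annual_fixture()          # annual counts, 1966-2019
order, fit, _ = select_order(counts.values())
fc = forecast(fit, 1)                   # one step ahead: calendar year 2020
print("selected order:", order.as_tuple())
print(f"2020 point forecast: {fc.point[0]:.2f}")
print(f"95% interval: [{fc.lower[0]:.2f}, {fc.upper[0]:.2f}]")
```

prints

```text
selected order: (0, 1, 1)
2020 point forecast: 6.00
95% interval: [3.33, 8.67]
```

The change-point NHPP on the raw event times:

```python
from rarecast.data import load_event_fixture, truncate_events, end_of_year_offset
from rarecast.changepoint import ChangePointSpec, sample_posterior, forecast_annual

events = truncate_events(load_event_fixture(), end_of_year_offset(2019))
spec = ChangePointSpec(observation_end=events.observation_end)
draws = sample_posterior(events, spec, seed=0)     # 4 chains, adaptive RW Metropolis
fc = forecast_annual(draws, events, horizon_years=1, seed=1)
print(f"max split-R-hat: {max(draws.rhat.values()):.3f}")
print(f"2020 posterior-predictive mean: {fc.mean[0]:.2f}")
print(f"95% interval: [{fc.lower[0]:.0f}, {fc.upper[0]:.0f}]")
```

prints

```text
max split-R-hat: 1.026
2020 posterior-predictive mean: 5.89
95% interval: [2, 11]
```

The hybrid model, with its architecture selected automatically:

```python
from rarecast.arima import ArimaOrder, fit_arima
from rarecast.hybrid import TrainingConfig, fit_hybrid, hybrid_forecast

arima = fit_arima(counts.values(), ArimaOrder(0, 1, 1))
model = fit_hybrid(counts.values(), arima, n_max=5,
                   config=TrainingConfig(seed=0), restarts=3)
points, _ = hybrid_forecast(model, 1)
print(f"selected architecture: n={model.architecture.n_inputs}, "
      f"m={model.architecture.m_hidden}")
print(f"2020 hybrid point forecast: {points[0]:.2f}")
```

prints

```text
selected architecture: n=5, m=3
2020 hybrid point forecast: 4.46
```

## Command line

Every stage is also a `rarecast` subcommand; each run writes its outputs and
a reproducibility manifest under `--out`:

```bash
rarecast fit-arima --out results/arima
rarecast fit-changepoint --chains 4 --seed 0 --out results/changepoint
rarecast fit-hybrid --nmax 5 --seed 0 --out results/hybrid
rarecast evaluate --variants arima --variants hybrid_n5 --t-range 2003 2014
rarecast forecast-future --variants arima
rarecast simulate --kind nhpp --seed 7 --out results/sim   # synthetic data
```

## Repository layout

- `src/rarecast/` — the library: `data` (containers, embedded study data,
  CSV I/O), `synthetic` (seeded generators), `changepoint` (WG-NHPP model and
  sampler), `arima` (fitting and order selection), `hybrid` (residual
  network), `evaluation` (metrics and rolling comparison), `cli`.
- `analysis/` — numbered driver scripts reproducing the study pipeline;
  each writes to a matching directory under `results/`.
- `scripts/acceptance.py` — computes the headline numerical results as JSON.
- `tests/` — unit, property, and acceptance tests.
- `docs/methods.md` — methods and design-decision notes.

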