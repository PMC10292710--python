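# Methods

This note records the modelling assumptions, the parameterisations, and the
design choices behind `rarecast`, together with their known limitations.

## Data

Two embedded representations of the same record of rare events (U.S. public
mass shootings, Violence Project definition) are used:

- **Event times**: 173 occurrence times in days since 1966-08-01, the last
  falling on 2020-02-14. The observation window closes at the last event.
- **Annual counts**: events per calendar year, 1966–2019 (sum 171), plus the
  single event recorded for 2020.

The two tables are *not* mutually consistent: the counts sum to 171 while the
event table has 173 rows, and six calendar years disagree between the printed
counts and the binned event times. Both tables are kept verbatim;
`rarecast.data.consistency_report()` quantifies the differences rather than
"fixing" them. Model fits "through end-2019" truncate the event series at
2019-12-31 (day 19510, keeping 172 events).

## Change-point NHPP with Weibull-geometric intensity

Events are modelled as a non-homogeneous Poisson process (NHPP) with rate

    lambda(t) = (alpha/beta) (t/beta)^(alpha-1) / (1 - rho e^(-(t/beta)^alpha))

with shape `alpha > 0`, scale `beta > 0` (days), and mixing parameter
`rho in [0, 1)`; `rho = 0` recovers the plain Weibull intensity. The
cumulative intensity has the closed form

    Lambda(t) = s + log[(1 - rho e^(-s)) / (1 - rho)],   s = (t/beta)^alpha,

used for the likelihood, expected annual counts, and exact inversion sampling.
A change-point extension lets the three parameters switch at `k` ordered times;
segments run on a single global clock (a clock-reset convention is available
behind a switch). The event recorded at exactly t = 0 defines the origin and
is excluded from the likelihood product — with `alpha < 1` the rate diverges
at 0, so this is also the only finite-likelihood convention.

**Number of change points.** The default is `k = 0` (configurable 0–2). The
WG intensity is itself time-varying and captures the accelerating event rate
smoothly. On the study data the `k = 1` posterior is label-degenerate: the
change point drifts toward the window edge, the first segment covers few or
no events, and its parameters revert to the prior, which leaves split-R-hat
far above any usable threshold (the `k = 1` fit is retained in the analysis
scripts to document exactly this behaviour). With `k = 0` the sampler
converges (split-R-hat ≤ 1.03 across four chains) and the 2020
posterior-predictive 95% interval is [2, 11–12].

**Priors and sampling.** Independent uniform priors on every parameter
(`alpha` on (0.001, 10), `beta` on (1, 10·T_end), `rho` on (0, 0.999), ordered
change points uniform on the window). Sampling is random-walk Metropolis:
warm-up first adapts per-coordinate step sizes (target acceptance 0.44), then
switches to a joint Gaussian proposal whose covariance is estimated from the
warm-up history (target 0.234, scale 2.38/sqrt(d)); the proposal is frozen
after warm-up, with occasional per-coordinate sweeps retained for robustness.
The joint phase matters: alpha, beta and rho are strongly correlated in the
posterior and coordinate-wise moves alone leave split-R-hat around 1.2–1.4.
Split-R-hat and effective sample size are computed per parameter;
non-convergence emits a warning and flags the result rather than raising.
Chains start from a jittered single-segment MAP estimate.

**Forecasting.** For each posterior draw, the count of an NHPP on a future
year interval is exactly Poisson with mean `Lambda(b) − Lambda(a)` under the
final segment's parameters, so annual counts are drawn directly from those
Poisson laws — distributionally identical to simulating event times forward
and binning them, at a fraction of the cost. Intervals are central
percentiles of the simulated integer counts. Training-set fitted values are
posterior-mean expected annual counts.

## ARIMA

Fitting is exact maximum likelihood (statsmodels state-space ARIMA). Order
selection is scored by an RSS-based AIC,

    AIC = k [log(2 pi RSS / k) + 1] + 2 (p + q),

with `k` the number of usable observations after differencing and RSS the sum
of squared one-step in-sample residuals (the first `d` residuals are dropped).

- **Differencing.** The smallest `d ≥ 1` whose d-th difference passes the
  augmented Dickey–Fuller test at the 5% level, with a constant term and the
  fixed lag order `trunc((n−1)^(1/3))` used by the standard auto-ARIMA tools.
  On short annual windows an information-criterion lag search saturates and
  loses power, pushing `d` to 2; the fixed lag convention selects `d = 1` on
  every study window.
- **Search.** The default is the Hyndman–Khandakar stepwise search (start
  from {(2,2), (0,0), (1,0), (0,1)}, repeatedly move to the best-scoring
  neighbour, with the drift term toggleable), which terminates at
  ARIMA(0,1,1) on every rolling window of the study data. An exhaustive
  (p, q) grid search is also provided; on this series it prefers the less
  parsimonious (0,1,4), which the stepwise search never visits.
- **Deterministic terms.** Drift for `d = 1` (matching the auto-ARIMA
  default for once-differenced series), a constant for `d = 0`, none for
  `d ≥ 2`. With drift, ARIMA(0,1,1) on 1966–2019 gives the 95% one-step
  interval [3.33, 8.67] for 2020, and [2.80, 8.68] for 2021 after appending
  the 2020 count.
- **Intervals.** Gaussian, point ± z·(forecast standard error).

## Hybrid ARIMA–ANN

The annual series is decomposed as `y_t = L_t + N_t`: ARIMA estimates the
linear part and a single-hidden-layer feed-forward network models what is
left in the one-step residuals `e_t = y_t − L̂_t`. The network maps the `n`
most recent residuals to the current one with a Tanh hidden layer (`m` nodes)
and a sigmoid output; because the sigmoid lives in (0, 1), residuals — inputs
*and* targets — are min-max normalised to [0, 1] on the training range
(values outside the range at forecast time are clipped with a warning).

**Training.** Full-batch backpropagation on the L2-regularised mean squared
error `J + (lambda/2)(||W1||² + ||W2||²)` (biases unpenalised), using
heavy-ball momentum with a bold-driver step size: after a cost decrease the
step grows 5%, after an increase it halves and the velocity is reset. The
default `lambda = 1e-4` is scaled to the size of the objective: on residuals
normalised to [0, 1] the unregularised cost is itself only ~0.01–0.05, so a
penalty of 0.01 would dominate the objective and collapse every candidate
network to the constant model. Momentum is likewise load-bearing: plain
gradient descent plateaus around J ≈ 0.01 on this objective, while momentum
reaches J ≈ 1e-4 within 5000 iterations, which is what lets larger hidden
layers justify their parameter count in selection.

**Architecture selection (SNC).** Sequential network construction compares
candidates on the algebraic prediction-risk estimate

    P̂ = J (1 + 2Q/I),   Q = n·m + m weights, I training rows.

Step 1 fixes `n = n_max` and scans `m` in 0..10; step 2 fixes the selected
`m` and scans `n` in 1..n_max. Every candidate is trained on all available
rows; because a single run's risk is dominated by the random initialisation,
each candidate is trained from several seeds and the median risk is compared.
`m = 0` denotes the constant model `Sig(b2)` with Q = 0. Four lag caps are
studied (`n_max` in {3, 5, 7, 10}).

**Forecasting.** Recursive: the network predicts the next normalised
residual from its lag window, the prediction is appended to the window, and
the hybrid point forecast is the ARIMA point forecast plus the denormalised
network output. The default interval policy shifts the ARIMA interval by the
network's point adjustment (preserving its width); a bootstrap policy that
resamples hybrid training errors around the hybrid point is also available.

## Evaluation

Rolling-origin design: training windows 1966–T for T = 2003..2014, testing
on T+1 through the end of the record, scored by RMSE and MAPE on both the
training fit and the test forecasts. Training years 1971, 1974 and 1979 have
zero counts, which makes raw MAPE undefined; the default policy excludes
zero-actual terms and reports how many were excluded (an epsilon-floor
policy is available). ARIMA/hybrid train metrics use in-sample one-step
fitted values (the hybrid's only where the lag window is full); change-point
train metrics use posterior-mean expected annual counts. Change-point fits
truncate the event series at the calendar end of year T. Fit failures are
recorded as NaN rows with the error message, never silently dropped.

## Limitations

- The two embedded data representations disagree; results from the two model
  families are therefore not fit to byte-identical data. This mirrors the
  source record and is reported, not repaired.
- MAPE with zero-actual exclusion is not comparable across windows with
  different numbers of exclusions.
- The shift interval policy for the hybrid assumes the network adjustment is
  a pure location shift with no variance contribution.
- The stepwise order search is a local search by construction; it reproduces
  the standard tool's selection but not the global AIC optimum on this data.
- With `k ≥ 1` change points and data generated by a smooth intensity, the
  change-point location is weakly identified and the sampler may legitimately
  fail to converge; the diagnostics surface this instead of hiding it.
- No covariates, no comparison against alternative incident databases.
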