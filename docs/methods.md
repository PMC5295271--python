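# Methods

`qrascreen` ranks urban-expressway segments by the expected monetized social
cost of their crashes — a quantitative risk assessment (QRA) criterion
`R_i = N_i × E[loss per crash]` — rather than by expected crash frequency
alone. This note documents the model, its assumptions, the numerical
choices, and what the synthetic data generator does and does not emulate.

## Model

### Probability side: empirical-Bayes expected crash frequency

Each segment's expected annual crash frequency combines a model prediction
with the observed mean annual count:

```
N_i = [β·Ñ_i + (1−β)·N̄_i] × [1 − n_y·(α/100)]
β   = 1 / (1 + V(Ñ)/E(Ñ))
```

- `Ñ_i` comes from the crash prediction model (CPM), a log-linear
  negative-binomial safety performance function
  `Ñ = LM · ADT^0.8410 · exp(−12.17 + 2.822·CI + 0.792·MR)` with segment
  length LM (m) as a fixed exposure, ADT in pcu/day exactly as calibrated
  (the large negative intercept absorbs the units), CI the congestion index
  and MR the merging ratio. Fitting uses frequentist maximum-likelihood NB2
  (variance = μ + μ²/θ) via statsmodels with `log(LM)` as offset.
- `β` is a **single global weight** computed from the cross-segment sample
  variance (n−1) and mean of the predictions — not the classical per-site EB
  weight derived from the NB dispersion. This is a deliberate fidelity
  choice: the screening method is defined with one shared shrinkage factor.
  On heterogeneous networks V(Ñ)/E(Ñ) is large and β is small (order 0.01),
  so the estimate is dominated by the observed mean.
- `α` is a **signed** percentage entering the trend multiplier literally:
  positive α means an assumed annual reduction. The source method's text is
  internally inconsistent here (it describes an 8%/yr *increase* yet plugs
  α = 8 into the reduction-form multiplier, giving 1 − 3·0.08 = 0.76 over a
  three-year study). We implement the multiplier exactly as written and
  expose α's sign to the user; choose α's sign to match your intent.

### Consequence side: direct plus congestion losses per crash

A crash's occurrence hour `t` (hour-of-day bin) and type `s` (single-, two-,
multi-vehicle) are assumed independent of each other and of location, so the
joint is the product of empirical marginals, `P(s,t) = Ps(s)·Pt(t)`, with
zero mass outside the active operating hours (default 6:00–24:00; the
network closes overnight for maintenance).

The **indirect loss** is the non-recurrent congestion delay from a
deterministic queuing diagram. While a type-`s` crash blocks lanes for
duration `t1`, capacity drops from `C` to `Q2 = k_s·C`; vehicles arrive at
the approach rate `Q1`, and `Q0 = (L/V̄)·Q̄` vehicles are already on the
segment when the crash starts. The screening formula is

```
NCD = [ (Q1−Q2)(C−Q2)·t1² + 2·Q0·(C−Q2)·t1 ] / [ 2·(C−Q1) ]   (vehicle-hours)
```

Delay is monetized at the value of time `c/(t_d·t_h)` yuan per vehicle-hour
(annual income over annual working hours, one occupant per vehicle; defaults
c = 80,000 yuan, t_d = 250 days, t_h = 8 h → 40 yuan/veh-h). The **direct
loss** is a per-type lookup (defaults 2000 / 4000 / 6000 yuan for single /
two / multi). The expected loss per crash sums `(IDL(i,s,t) + DL(s))·P(s,t)`
over the joint support, either exactly or by seeded Monte-Carlo sampling of
(s, t) events; the two agree to the law-of-large-numbers error (< 2% at 10⁵
draws in the tests).

Hotspots are ranked by descending risk `R_i` (QRA) or descending `N_i` (EB
baseline); ties break by ascending segment id. The EB ranking is invariant
to all economic parameters; the QRA ranking is invariant to uniformly
scaling them.

## Numerical and design choices

- **Verbatim queuing formula, independent oracle.** For `Q0 = 0` the closed
  form is the exact triangle area between the cumulative arrival and
  departure curves, and the discrete simulation oracle
  (`simulate_queue_delay`, trapezoidal integration at dt = 1 s) agrees
  within 0.5% on randomized valid scenarios. For `Q0 > 0` the closed form
  equals the cumulative-curve area only up to the point where the *incident*
  backlog clears; it ignores the extension needed to discharge `Q0` itself
  and therefore undercounts the exact area (by ≈5% on the canonical
  two-lane worked incident: 107.42 vs 113.27 veh-h). The formula is kept
  verbatim as the screening statistic; the oracle quantifies the gap rather
  than patching the method. The widely cited 98.68 veh-h figure for that
  worked incident is not recoverable from the printed formula under any
  reading of its inputs (direct evaluation gives 107.42 veh-h with t1 = 10
  min and 100.57 with t1 = 575 s); we report the formula's own value.
- **Unit reconciliation in monetization.** The published monetization
  formula divides by `t_d·t_h·3600`, which implies delay in vehicle-seconds,
  while the delay formula's worked value is reported in hours. NCD is kept
  in vehicle-hours end to end, so the value of time is `c/(t_d·t_h)` per
  vehicle-hour and the 3600 is dropped. t_d and t_h are not given in the
  source and are config-exposed assumptions.
- **Negative closed-form delays** (possible when `Q2 > Q1` with a small
  `Q0`, routine in off-peak hours) are clamped to zero with a one-time
  warning. An approach flow at or above capacity raises an explicit
  unbounded-queue error; nothing is silently capped.
- **Crash duration** defaults to nearest-minute rounding of the logged
  interval (a 575 s record reads as 10 min), matching incident-log
  conventions; a raw-seconds mode is kept for sensitivity analysis. The
  `t1` entering the expected-loss integral is the per-type mean duration
  from the crash history, with the global mean as fallback for unseen types.
- **Capacity-reduction factors** `k_s` default to {single 0.58, two 0.45,
  multi 0.32}: more vehicles involved → more lanes blocked → less residual
  capacity. Only the multi-vehicle 0.32 has an empirical anchor (the
  two-lane lane-blocking worked incident); the others are placeholders the
  user should calibrate locally.
- **Fractional expected counts** are rounded half-up to whole events for
  sampling; exact-expectation mode (the pipeline default — deterministic and
  auditable) needs no rounding. The draw count per replicate is `round(N_i)`
  rather than a Poisson draw because the screening treats `N_i` as
  deterministic.
- **Global weight variance**: the n−1 sample variance is used; with ~167
  segments the choice is immaterial to ranking.

## Synthetic data generator

No deposited network/crash dataset exists, so `qrascreen.synthetic`
generates one with the documented statistical structure of a metropolitan
expressway system, and the whole pipeline is exercised and tested on it:

- 167 ramp-to-ramp segments over 3 years (defaults), covariates uniform on
  LM ∈ [300, 2000] m, ADT ∈ [20k, 70k] pcu/day, CI ∈ [0.05, 0.4],
  MR ∈ [0, 0.2] — chosen so the CPM-truth means put the three-year crash
  total near the ~50k scale of a large urban network (the generated default
  history has ≈57k crashes, ~115 per segment-year).
- Annual counts are NB2 around the CPM-truth mean (θ = 5) with an 8%/yr
  multiplicative growth trend; types follow the 12/87/1 single/two/multi
  mixture; durations are lognormal with a 10-minute median (σ = 0.5 on the
  log scale).
- The hour-of-day distribution is a two-Gaussian mixture over active hours
  (bumps at 8:30 and 17:30, sd 2 h) rescaled so the mass in the default peak
  windows (7–10 and 16–19) equals the 70% peak share **exactly** — only the
  peak share of the real pattern is documented, not the full histogram.
- Hourly traffic is a bimodal day shape scaled to ADT and capped below
  capacity; speeds are anticorrelated with the volume/capacity ratio;
  approach flows track volume with noise and stay strictly below capacity,
  so every queuing scenario is well-posed by construction.

What it does **not** emulate: within-hour timing, day-of-week and seasonal
effects, spatial correlation between adjacent segments, queue spillback, or
raw 20-s loop-detector noise. Consequently, passing tests demonstrate the
estimators' internal correctness and calibration under the stated structure,
not performance on a real surveillance feed.

## Problem sizes used in the test suite

Parameter-recovery tests fit the CPM on 500-segment single-year networks
(20 replicates for the interval-coverage property); sampler calibration uses
10⁵ draws; the oracle-agreement property uses 120 randomized scenarios at a
1 s step; the end-to-end pipeline runs on the full 167-segment default
network in exact-expectation mode.

## Known limitations

- The global-weight EB variant under-shrinks high-count sites compared to
  the classical per-site EB weight; it is implemented as specified.
- The queuing model is deterministic and single-segment (no kinematic-wave
  dynamics, no spillback to upstream segments).
- Crash severity is not modeled (the motivating data record no severity);
  direct losses are type-level property-damage figures.
- Losses condition on the hour bin only; traffic conditions within the hour
  are not re-sampled.
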