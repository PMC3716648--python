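# Methods

This note documents the models and procedures implemented in `icuglyc`, the
assumptions behind them, the parameters that matter, and what the synthetic
workbench does and does not establish about real bedside data.

## 1. Synthetic ICU glycemic simulator (`icuglyc.synthetic`)

### Dynamics

Serum glucose is generated on the 5-minute CGM grid by a discrete-time
additive model:

```
G(t+1) = G(t) + r·(S(t) + C(t) − G(t)) − I(t) + D(t) + P(t) + ε(t)
```

| term | meaning | default |
|------|---------|---------|
| `r` | per-step reversion toward the setpoint | 0.35 / step |
| `S(t)` | hidden glycemic-regime setpoint | normo = `basal_glucose_mgdl` (110), hypo = 52, hyper = 185 mg/dL |
| `C(t)` | circadian modulation, sinusoid with trough near 08:00 | amplitude 8 mg/dL |
| `I(t)` | insulin action: each dose acts after a 2-step (10-min) onset delay with exponential decay over 6 steps; mean per-step drop = `insulin_sensitivity` × units | sensitivity 1.5 mg/dL·U⁻¹·step⁻¹ |
| `D(t)` | dextrose effect = `dextrose_gain` × infusion rate | 0.05 mg/dL per (mL/h) per step |
| `P(t)` | stress pulses, Poisson onsets, 15–35 mg/dL released over 40 min | 2 / day |
| `ε(t)` | AR(1) noise, φ = 0.6, stationary SD = `ar_noise_sd_mgdl` | 3 mg/dL |

Glucose is floored at 40 mg/dL (survivable physiology; keeps MAD%
denominators sane).  The floor adjustment is logged as its own component so
the **conservation invariant** holds exactly: for every step,
`G(t+1) == G(t) + sum(component_log row t)` bit for bit.

### Regime schedule and state composition

The hypo/normo/hyper occupancy is controlled by `target_composition`
(default 4.5 / 83.8 / 11.7 %).  Step quotas for hypo and hyper are split into
episodes — brief hypoglycemic dips of 40–60 min (they are caught and treated
quickly in an ICU) and sustained stress-hyperglycemia episodes of 2–3.3 h —
placed at random non-overlapping positions.  The setpoint path is then
smoothed with a 25-minute moving average: physiological excursions build and
resolve gradually rather than stepwise, which also means an excursion already
underway is partially predictable from its early trend.  Because reversion
takes longer to pull glucose *into* the hypo band than out of it, each hypo
episode is padded by 2 steps.  Setpoints, reversion rate and padding were
calibrated against the state counter so that a default 24-h patient lands
within ±5 percentage points of the target composition (worst deviation over
30 seeds: hypo 4.5, normo 4.1, hyper 1.6 points).  A patient whose achieved
composition misses the target by more than 10 points carries a
`composition_warning` flag rather than failing.

### Observation channels

- **CGM**: serum delayed by `interstitial_lag_minutes` (default 12.5 — half a
  sample off-grid, realized by fractional-grid linear interpolation; before
  the transient the initial serum value is held), plus Gaussian sensor noise
  (SD 2 mg/dL), clipped to the 40–400 mg/dL device range.
- **POC glucose**: checks at gaps uniform in 60–120 min starting at
  admission; value = concurrent serum × (1 + 5% Gaussian noise).  The 5% SD
  is consistent in magnitude with reported CGM-vs-POC disagreement without
  asserting it.
- **Insulin**: each POC value is pushed through a sliding-scale protocol
  (ordered, gap-free, left-closed glucose bands with non-decreasing doses;
  default 0 U below 150, then 2/4/6/8 U stepping at 200/250/300 mg/dL; doses
  ≥ 6 U run as infusions, smaller ones subcutaneously) with a 5-minute nurse
  response latency.
- **Vitals**: heart rate charted every 15 min, positively coupled to serum
  glucose (+0.15 bpm per mg/dL above basal); body temperature hourly,
  depressed during hypoglycemia (−0.05 °C per mg/dL below 70); respiratory
  rate every 15 min, autonomous noise.  Because heart rate reflects *serum*
  while CGM lags it by 12.5 min, vitals carry a small genuine lead over the
  CGM channel — the premise for multivariate forecasting.
- **Dextrose**: nutrition episodes (≈3/day, 1–3 h, 20–60 mL/h) plus a
  30 mL/h rescue drip during hypoglycemic regimes, charted as rate-change
  events.

All randomness flows from one `numpy` generator seeded by `SimConfig.seed`;
identical configs give bit-identical outputs.  Cohorts derive per-patient
seeds via `SeedSequence([master_seed, index])` (rule recorded in the
manifest header).

### Couplings and the open/closed loop distinction

Raising one step's dextrose infusion can never lower any later serum value,
and raising insulin can never raise one — **in the open-loop dynamics**
(fixed schedules), because the update is affine in `G` with slope
`1 − r ∈ [0, 1)` and the floor is monotone.  Under the *closed loop*, a
dextrose bump can push a POC value over a protocol threshold and trigger
extra insulin, legitimately lowering later glucose; that is clinical
reality, not a bug.  The monotonicity property is therefore stated and
tested on the open-loop integrator.

### What the simulator does not emulate

No pharmacokinetic ODEs (insulin/glucose compartments), no meals-vs-drip
distinction, no sensor dropout or recalibration artifacts, no ventilation,
sepsis, medication interactions, or inter-patient parameter heterogeneity
beyond demographics.  Patient covariates (age, BMI, diabetes) are metadata
and do not enter the dynamics.  Nutrition schedules are plausible
placeholders, not estimates of any study's conditions.  Consequently,
passing tests show the *pipeline machinery* is correct and that the model
class can recover dynamics of this kind at these noise levels — they do not
certify accuracy on real ICU data.

## 2. Records and design matrices (`icuglyc.records`)

Events carry one of 15 charting categories; files are plain CSV (timestamps
ISO-8601 at minute resolution, glucose written with one decimal).  Reading
validates monotone timestamps and a gap-free 5-minute grid and names the
first offending row; gaps are never silently filled.

The default input vector per origin `t`: current CGM value; its glycemic
state one-hot (hypo ≤ 70, hyper ≥ 150 mg/dL); time of day as a fraction of
24 h; last-observation-carried-forward heart rate, respiratory rate,
temperature; minutes since the last POC check and its value; insulin units
in the trailing half-open window `(t−60 min, t]` (an event exactly 60 min
old has left the window, so each dose is counted for exactly 60 min of
origins) with an infusion-route flag; and the current dextrose rate
(0 before the first charting).  Targets are the next 15 CGM values, so a
gap-free trace of `n` samples yields `n − 15` rows; origins lacking a
required prior observation are dropped and counted in an exclusion report.
Every input at origin `t` is a function of data timestamped ≤ `t` — the
property that makes streaming replay and batch assembly agree.

An optional synthetic sensor-current channel (proportional to glucose) can
be enabled in the schema; the schema object is deliberately configurable so
richer input sets can be represented.

## 3. GA predictor selection (`icuglyc.ga`)

Fitness of a candidate mask is RMSECV: contiguous time-block folds (no
shuffling across time, respecting the serial dependence of CGM data), per
fold an intercept-augmented ordinary least squares fit of every target
column on the masked inputs, squared residuals pooled over folds and
columns, square-rooted.  Rank-deficient subsets fall back to ridge with
λ = 1e−6 and are flagged.  OLS is the simplest faithful choice of regression
family; the function is pluggable.

The GA is generational: tournament selection of size 2, uniform crossover
(rate 0.8), per-bit mutation (default 1/n), elitism (2), population 40,
60 generations.  Ties on fitness break toward smaller masks, then
lexicographically — with the seeded generator this makes runs exactly
reproducible, and elitism makes the best-fitness history monotone
non-increasing (asserted at runtime).  An all-zero child is repaired by
setting one random bit.  Hyperparameters are declared defaults from standard
GA practice, not reconstructions of any reference.

## 4. Feed-forward forecaster (`icuglyc.network`)

Three layers: inputs → tanh hidden layer (default 30 units in the pipeline)
→ linear output layer with 15 units, one per 5-minute step of the 75-minute
horizon (a single multi-output network, not 15 models).  Inputs are
standardized per column; targets centered and scaled by one scalar pair —
statistics always computed on the fitting rows only.  Outputs are mapped
back to mg/dL and clamped to the 40–400 device range.

Training minimizes the MSE over all 15 outputs by backpropagation with the
classic momentum update `Δw ← μ·Δw_prev − η·∇L`, per-sample (order
reshuffled each epoch from the training seed) or full-batch.  Defaults:
η = 0.002, μ = 0.9, ≤ 800 epochs, early stopping with patience 100 on a
held-out validation set, returning the weights with the best validation MSE.
For a single series the validation set is the last 15% of rows
(time-ordered); when training pools several patients the pipeline holds out
the tail 30% of *each* patient instead, which is still causal within
patient and much less sensitive to which patient happens to sit last.
Scaled-space loss above 1e6 (or non-finite) aborts with the epoch named.
Weight init is symmetric-uniform scaled by fan-in; all seeds explicit.

Training defaults were chosen by desk experiments on simulated low-noise
cohorts (4 train / 2 test patients, 24 h each): per-sample training with a
small learning rate and per-patient validation tails was the most reliable
at matching the linear-regression baseline while keeping the short-horizon
error low.

## 5. Streaming replay (`icuglyc.replay`)

Replays the deployed cycle: each 5-minute tick reveals one more CGM sample
and all events up to the tick, assembles the input vector from revealed data
only, and emits a 15-step forecast from the frozen model (weights are
digest-checked before and after).  Ticks whose vector cannot be assembled
(cold start) are skipped and counted; origins within 75 minutes of the trace
end still emit forecasts but are flagged unscorable.  Because the replay and
batch paths share the causal row-assembly code and evaluate the network
row-at-a-time (batched BLAS sums in a different order), the scorable replay
log equals batch prediction **exactly**, element for element — the module's
central contract.  Per-tick wall time is logged; a tick costs milliseconds
against the 5-minute budget.

## 6. Evaluation battery (`icuglyc.evaluation`)

- **MAD%** = mean of |predicted − actual| / actual × 100 over pairs; scale
  invariant; zero iff identical.
- **Clarke Error Grid**: the published piecewise boundaries, applied in the
  order A, E, C, D, else B, so boundary points resolve to the more favorable
  zone; reference and predicted must lie in (0, 1000) mg/dL.  Zone A is
  within-20% agreement (or both values ≤ 70); A+B is "clinically
  acceptable"; D marks dangerous failure to detect hypoglycemia; E marks
  treatment confusion between hypo- and hyperglycemia.
- **State recall**: per state, the share of actual values in the state whose
  forecast lands in the same state; a state with no actual pairs is reported
  *absent*, never zero.
- **Paired device error**: each POC value pairs with the nearest CGM sample
  within 2.5 min (half the sampling interval, so pairing is unambiguous;
  ties break earlier); MAD% uses POC as denominator.
- Evaluation pools all 15 horizon steps of every origin (per-step MAD% also
  emitted); counts follow origins × steps.  Internal values keep full
  precision; percents are rounded half away from zero to one decimal only at
  report formatting.  A thinning helper (every k-th pair, default 20) serves
  plotting, and a Clarke-grid plot with the boundary segments is available.

## 7. Pipeline and problem sizes

`run_pipeline` wires simulate → assemble → select → train → replay →
evaluate with per-stage seeds derived from the master seed via
`SeedSequence([master, stage])`; identical configs are bit-identical,
including all written artifacts.  The default study design is 14 training
and 5 held-out test patients at 24 h each (≈ 5.5 k training rows); the test
suite exercises the same machinery at 2–6 patients per cohort and the
acceptance script at the full 19.  These sizes were chosen so a complete run
takes about a minute on one CPU while leaving every stage's statistics
stable.

## 8. Known limitations

- Hypoglycemic and hyperglycemic recall are intrinsically poor under the
  default composition — rare-state regression to the mean.  This is a
  property the package is designed to exhibit and measure, not to fix; no
  resampling or cost-weighting is implemented.
- The forecaster carries no recurrent state and sees no lagged CGM values
  beyond the current one, so an excursion is only predictable once its ramp
  is visible in the inputs.
- RMSECV uses OLS; strongly collinear candidate sets lean on the flagged
  ridge fallback.
- The replay engine reassembles the full prefix each tick (O(n²) per
  patient) — simple and obviously causal; fine at ICU scales.
- Timestamps are minute-resolution by construction; sub-minute charting
  would collide.
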