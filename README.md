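# icuglyc

Real-time neural forecasting of glucose for critically ill surgical patients,
packaged with a synthetic ICU data workbench.

## The problem

Glycemic control in the surgical ICU runs on point-of-care (POC) fingerstick
glucose checks every 1–2 hours, leaving clinicians blind to excursions in
between.  Subcutaneous continuous glucose monitors (CGM) report interstitial
glucose every 5 minutes, but only up to "now" (and physiologically ~12.5 min
behind serum).  A forecaster that projects glucose **75 minutes ahead** —
emitted as 15 values at 5-minute steps — covers exactly the monitoring gap
between POC checks and gives time to adjust insulin or dextrose.

`icuglyc` implements that system end to end, for researchers in physiological
time-series forecasting and critical-care informatics:

- **`icuglyc.synthetic`** — an ICU patient simulator with known ground truth:
  serum glucose follows a discrete-time additive model
  `G(t+1) = G(t) + r·(S(t)+C(t)−G(t)) − I(t) + D(t) + P(t) + ε(t)`
  (regime setpoint `S`, circadian `C`, delayed sliding-scale insulin `I`,
  dextrose `D`, stress pulses `P`, AR(1) noise `ε`), with a lagged noisy CGM
  channel, POC checks, protocol-driven insulin, and glucose-coupled vitals.
  The hypo/normo/hyper state composition is controllable (default
  4.5 / 83.8 / 11.7 %).
- **`icuglyc.records`** — the 15-category clinical event schema, delimited-text
  I/O, and x-block/y-block design-matrix assembly on the 5-minute grid
  (inputs at origin *t* use only data timestamped ≤ *t*).
- **`icuglyc.ga`** — genetic-algorithm predictor selection minimizing RMSECV,
  the root mean squared error of cross-validation of an OLS regression of the
  y-block on the candidate subset, with contiguous time-block folds.
- **`icuglyc.network`** — a three-layer feed-forward network (tanh hidden
  layer, linear 15-unit output) trained from scratch by error backpropagation
  with gradient descent with momentum (`Δw ← μ·Δw_prev − η·∇L`; MSE loss in
  standardized space), early stopping on a held-out time-ordered tail.
- **`icuglyc.replay`** — a frozen-weight streaming engine replaying the
  5-minute real-time cycle; its replay log provably equals batch prediction
  element for element.
- **`icuglyc.evaluation`** — MAD% (mean |predicted−actual|/actual × 100),
  Clarke Error Grid Analysis (zones A–E; A+B = clinically acceptable),
  per-state recall with hypo ≤ 70, normo 70–150 exclusive, hyper ≥ 150 mg/dL,
  composition statistics, and paired CGM-vs-POC device error.

## Worked example

Train on one simulated 24-hour patient, then replay a second patient the
model has never seen through the frozen-weight real-time cycle:

```python
from icuglyc import (SimConfig, PatientProfile, simulate_patient, assemble_design,
                     init_network, train, TrainConfig, run_replay, evaluate)

profile = PatientProfile("demo", "trauma", age_years=52.0, bmi_kg_m2=31.0,
                         diabetic=False, los_days=6.0)
_, cgm_train, events_train = simulate_patient(profile, SimConfig(seed=11, duration_hours=24.0))
_, cgm_test, events_test = simulate_patient(profile, SimConfig(seed=12, duration_hours=24.0))

design = assemble_design(cgm_train, events_train)           # 273 rows x 13 inputs, 15 targets
model = init_network(n_inputs=len(design.column_names), n_hidden=30, seed=0)
model, history = train(model, design, TrainConfig())

log = run_replay(model, cgm_test, events_test)              # one forecast per 5-min tick
report = evaluate(log.scorable_prediction_set())
```

Printing the formatted report gives:

```
pairs scored      : 4095
MAD%              : 11.7
zones A/B/C/D/E   : 82.6/15.2/0.0/2.2/0.0
clinically OK (A+B): 97.8%
state recall      : {'hypo': 0.0, 'normo': 95.2, 'hyper': 62.6}
```

Reading: 273 scorable origins × 15 steps = 4095 forecast/actual pairs; mean
relative error 11.7%; 97.8% of forecasts fall in Clarke zones A or B, i.e.
would not trigger inappropriate treatment; normoglycemia is predicted almost
always, while the rarer hyperglycemic state (≈12% of training data) is caught
only ~63% of the time and the very rare hypoglycemic dips are missed — the
class-imbalance signature expected when a regression model is trained on
mostly-normal data.

The same stages are scriptable from the shell:

```bash
icuglyc simulate --n-patients 19 --hours 24 --seed 1 --out cohort/
icuglyc assemble --cgm cohort/patient_01.cgm.csv --events cohort/patient_01.events.csv --out design.csv
icuglyc select-features --design design.csv --folds 5 --seed 1 --out mask.json
icuglyc train --design design.csv --mask mask.json --hidden 30 --seed 1 --out model.json
icuglyc replay --model model.json --cgm cohort/patient_15.cgm.csv --events cohort/patient_15.events.csv --out log.csv
icuglyc evaluate --predictions log.csv --out report.json
icuglyc run-all --config pipeline.yaml   # all of the above, seeded end to end
```

## Layout

```
src/icuglyc/      library (simulator, records, GA, network, replay, evaluation, pipeline, CLI)
tests/            pytest suite, including end-to-end acceptance checks
scripts/          acceptance script
docs/methods.md   model, assumptions, parameter choices, limitations
```
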