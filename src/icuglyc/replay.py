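"""Frozen-weight streaming replay of the 5-minute prediction cycle.

Every 5 minutes the clock advances one grid tick, the input vector is
assembled from revealed data only (the CGM prefix and events timestamped at
or before the tick), and the trained network emits a fresh 75-minute
forecast.  Weights are never updated during the run.  The module's central
theorem is stream/batch equivalence: the replay log restricted to scorable
ticks equals the batch ``predict_set`` on the same design rows
element-for-element, because both paths share the causal row-assembly code.

Forecast origins too close to the end of the trace to be fully scored are
retained but flagged unscorable — a deployed system always predicts past
its latest observation.  Cold-start ticks whose input vector cannot be
assembled (e.g. before the first vitals chart) are skipped and counted.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, SchemaError
from .network import NetworkModel, PredictionSet, forward, model_digest
from .records import (ClinicalRecordSet, DEFAULT_INPUT_SCHEMA, GlucoseTrace,
                      InputSchema, assemble_x, horizon_steps)


@dataclass
class ReplayLog:
    """Append-only prediction log from one streaming replay."""

    frame: pd.DataFrame  # origin, step_1.., scorable, actual_1..
    skipped_ticks: int
    latencies: np.ndarray  # seconds per emitted tick
    n_steps: int

    def __len__(self) -> int:
        return len(self.frame)

    def scorable_prediction_set(self) -> PredictionSet:
        sc = self.frame[self.frame["scorable"]]
        if sc.empty:
            raise DataError("replay log has no scorable rows")
        pred = sc[[f"step_{k + 1}" for k in range(self.n_steps)]].to_numpy(dtype=float)
        act = sc[[f"actual_{k + 1}" for k in range(self.n_steps)]].to_numpy(dtype=float)
        return PredictionSet(pd.DatetimeIndex(sc["origin"]), pred, act)

    def to_csv(self, path) -> None:
        df = self.frame.copy()
        df["origin"] = pd.DatetimeIndex(df["origin"]).strftime("%Y-%m-%dT%H:%M")
        df.to_csv(path, index=False)


def run_replay(model: NetworkModel, trace: GlucoseTrace,
               records: ClinicalRecordSet,
               schema: InputSchema = DEFAULT_INPUT_SCHEMA,
               horizon_minutes: float = 75.0) -> ReplayLog:
    """Iterate the clock over the grid and emit one forecast per tick.

    The model's input names must be a subset of the schema's columns; the
    assembled row is restricted to them in training order.  Model weights
    are bit-identical before and after the run (asserted via digest).
    """
    steps = horizon_steps(horizon_minutes, trace.sample_minutes)
    if model.n_outputs != steps:
        raise SchemaError(
            f"model has {model.n_outputs} outputs but the horizon needs {steps}"
        )
    input_names = model.input_names or schema.column_names
    missing = [c for c in input_names if c not in schema.column_names]
    if missing:
        raise SchemaError(f"schema lacks model inputs {missing}")

    digest_before = model_digest(model)
    n = len(trace)
    rows: list[dict] = []
    latencies: list[float] = []
    skipped = 0

    for i in range(n):
        t0 = time.perf_counter()
        prefix_records = records.before(trace.times[i])
        if i == 0:
            # a single-sample prefix cannot form a GlucoseTrace; assemble on a
            # two-sample stub and keep only the first row (causal by LOCF)
            stub = GlucoseTrace(trace.patient_id, trace.times[:2], trace.values[:2])
            X_all, complete = assemble_x(stub, prefix_records, schema)
            row_x, ok = X_all.iloc[0], complete[0]
        else:
            prefix_trace = GlucoseTrace(
                trace.patient_id, trace.times[:i + 1], trace.values[:i + 1])
            X_all, complete = assemble_x(prefix_trace, prefix_records, schema)
            row_x, ok = X_all.iloc[-1], complete[-1]
        if not ok:
            skipped += 1
            continue
        pred = forward(model, row_x[input_names].to_numpy(dtype=float))
        scorable = i + steps <= n - 1
        rec = {"origin": trace.times[i], "scorable": scorable}
        for k in range(steps):
            rec[f"step_{k + 1}"] = pred[k]
        for k in range(steps):
            rec[f"actual_{k + 1}"] = (trace.values[i + k + 1] if scorable else np.nan)
        rows.append(rec)
        latencies.append(time.perf_counter() - t0)

    assert model_digest(model) == digest_before, "replay mutated model weights"
    cols = (["origin", "scorable"] + [f"step_{k + 1}" for k in range(steps)]
            + [f"actual_{k + 1}" for k in range(steps)])
    frame = pd.DataFrame(rows, columns=cols)
    return ReplayLog(frame, skipped, np.array(latencies), steps)


def latency_report(log: ReplayLog) -> dict:
    """Per-tick wall-time summary confirming each cycle fits a 5-minute budget."""
    if len(log.latencies) == 0:
        raise DataError("replay log is empty; no latencies to summarize")
    lat = log.latencies
    return {
        "n_ticks": int(len(lat)),
        "mean_s": float(np.mean(lat)),
        "median_s": float(np.median(lat)),
        "max_s": float(np.max(lat)),
        "min_s": float(np.min(lat)),
        "budget_s": 300.0,
    }
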