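"""Clinical record schema, delimited-text I/O, and design-matrix assembly.

The unit of analysis is a continuous glucose monitoring (CGM) trace sampled
every 5 minutes in mg/dL, paired with a table of timestamped clinical events
(point-of-care glucose checks, insulin deliveries, dextrose infusions, vital
signs) charted under a fixed set of 15 ICU record categories.  From these two
streams this module assembles the supervised-learning matrices: for every
grid origin `t` an input vector (x-block) built only from data timestamped
at or before `t`, and a target row (y-block) of the next 15 CGM values, i.e.
a 75-minute forecast horizon at 5-minute resolution.

All carried-forward inputs use last-observation-carried-forward (LOCF)
semantics, matching how asynchronous ICU charting is read at the bedside;
trailing-window aggregations use half-open intervals so events on a grid
boundary are never counted twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, DomainError, FormatError, SchemaError

#: The 15 ICU charting categories events may carry.
RECORD_CATEGORIES: tuple[str, ...] = (
    "vital_signs",
    "poc_glucose",
    "insulin_delivery",
    "iv_infusions",
    "medications",
    "nutrition",
    "laboratory",
    "ventilation",
    "neurological",
    "intake_output",
    "demographics",
    "wound_care",
    "procedures",
    "assessment",
    "notes",
)

#: Glycemic state thresholds, mg/dL.  Hypoglycemia <= 70; hyperglycemia >= 150.
HYPO_MAX = 70.0
HYPER_MIN = 150.0

STATES = ("hypo", "normo", "hyper")

EVENT_COLUMNS = ("timestamp", "category", "variable", "value", "units")


def classify_state(glucose: float) -> str:
    """Glycemic state of a single glucose value in mg/dL.

    The three states partition the positive axis: hypoglycemia at or below
    70 mg/dL, hyperglycemia at or above 150 mg/dL, normoglycemia strictly
    between.  Non-positive input raises :class:`DomainError`.
    """
    if not glucose > 0:
        raise DomainError(f"glucose must be positive, got {glucose!r}")
    if glucose <= HYPO_MAX:
        return "hypo"
    if glucose >= HYPER_MIN:
        return "hyper"
    return "normo"


def classify_states(values: np.ndarray) -> np.ndarray:
    """Vectorized :func:`classify_state`; returns an array of state strings."""
    values = np.asarray(values, dtype=float)
    if not np.all(values > 0):
        idx = int(np.argmin(values > 0))
        raise DomainError(f"glucose must be positive, got {values[idx]!r} at index {idx}")
    out = np.full(values.shape, "normo", dtype=object)
    out[values <= HYPO_MAX] = "hypo"
    out[values >= HYPER_MIN] = "hyper"
    return out.astype(str)


def horizon_steps(horizon_minutes: float, sample_minutes: float) -> int:
    """Number of forecast steps in a horizon (75 min at 5 min -> 15)."""
    steps = horizon_minutes / sample_minutes
    if abs(steps - round(steps)) > 1e-9 or steps < 1:
        raise DataError(
            f"horizon {horizon_minutes} min is not a positive multiple of the "
            f"{sample_minutes}-min sampling interval"
        )
    return int(round(steps))


@dataclass
class GlucoseTrace:
    """Uniformly sampled interstitial glucose series (mg/dL)."""

    patient_id: str
    times: pd.DatetimeIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = pd.DatetimeIndex(self.times)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise DataError("times and values lengths differ")
        if len(self.times) < 2:
            raise DataError("a glucose trace needs at least two samples")
        diffs = np.diff(self.times.asi8)
        if np.any(diffs <= 0):
            # diffs[i] concerns the (i+2)-th file line counting a header line
            row = int(np.argmax(diffs <= 0)) + 3
            raise FormatError(f"non-increasing timestamp at data row {row}")
        if np.any(diffs != diffs[0]):
            row = int(np.argmax(diffs != diffs[0])) + 3
            raise FormatError(
                f"gap in the uniform grid at data row {row}; gaps are not filled"
            )
        if not np.all(self.values > 0):
            idx = int(np.argmin(self.values > 0))
            raise DomainError(f"non-positive glucose {self.values[idx]} at row {idx + 2}")

    @property
    def sample_minutes(self) -> float:
        return float((self.times[1] - self.times[0]) / pd.Timedelta(minutes=1))

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ClinicalRecordSet:
    """Timestamped clinical events across the 15 ICU record categories."""

    patient_id: str
    events: pd.DataFrame

    def __post_init__(self) -> None:
        ev = self.events
        missing = [c for c in EVENT_COLUMNS if c not in ev.columns]
        if missing:
            raise FormatError(f"events table missing columns {missing}")
        ev = ev.copy()
        ev["timestamp"] = pd.DatetimeIndex(ev["timestamp"])
        bad = ~ev["category"].isin(RECORD_CATEGORIES)
        if bad.any():
            name = ev.loc[bad, "category"].iloc[0]
            raise SchemaError(
                f"unknown record category {name!r}; expected one of the "
                f"{len(RECORD_CATEGORIES)} declared categories"
            )
        ev = ev.sort_values(["timestamp", "category", "variable"], kind="stable")
        self.events = ev.reset_index(drop=True)

    def subset(self, category: str, variable: str | None = None) -> pd.DataFrame:
        ev = self.events
        m = ev["category"] == category
        if variable is not None:
            m &= ev["variable"] == variable
        return ev.loc[m]

    def before(self, timestamp: pd.Timestamp) -> "ClinicalRecordSet":
        """Events at or before ``timestamp`` (the revealed prefix in a replay)."""
        out = ClinicalRecordSet.__new__(ClinicalRecordSet)
        out.patient_id = self.patient_id
        out.events = self.events[self.events["timestamp"] <= timestamp]
        return out


# ---------------------------------------------------------------------------
# Delimited-text I/O


def write_cgm(trace: GlucoseTrace, path) -> None:
    """Write a CGM trace: columns timestamp (ISO-8601, minute resolution),
    glucose_mgdl (one decimal)."""
    with open(path, "w") as fh:
        fh.write("timestamp,glucose_mgdl\n")
        for t, v in zip(trace.times, trace.values):
            fh.write(f"{t.strftime('%Y-%m-%dT%H:%M')},{v:.1f}\n")


def read_cgm(path, patient_id: str | None = None) -> GlucoseTrace:
    """Read a CGM file; validates monotone timestamps and a gap-free grid."""
    df = pd.read_csv(path)
    if list(df.columns) != ["timestamp", "glucose_mgdl"]:
        raise FormatError(f"unexpected CGM columns {list(df.columns)} in {path}")
    try:
        times = pd.DatetimeIndex(pd.to_datetime(df["timestamp"], format="ISO8601"))
    except (ValueError, TypeError) as exc:
        raise FormatError(f"unparsable timestamp in {path}: {exc}") from exc
    pid = patient_id if patient_id is not None else str(path)
    return GlucoseTrace(pid, times, df["glucose_mgdl"].to_numpy(dtype=float))


def write_events(records: ClinicalRecordSet, path) -> None:
    ev = records.events.copy()
    ev["timestamp"] = ev["timestamp"].dt.strftime("%Y-%m-%dT%H:%M")
    ev.to_csv(path, index=False, columns=list(EVENT_COLUMNS))


def read_events(path, patient_id: str | None = None) -> ClinicalRecordSet:
    df = pd.read_csv(path, dtype={"value": object})
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"events file {path} missing columns {missing}")
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"unparsable timestamp in {path}: {exc}") from exc
    pid = patient_id if patient_id is not None else str(path)
    return ClinicalRecordSet(pid, df)


# ---------------------------------------------------------------------------
# Input schema and design-matrix assembly


@dataclass(frozen=True)
class InputSchema:
    """Which predictor columns the x-block carries.

    The default contains the variables the source system charted explicitly:
    the current CGM value and its glycemic state (one-hot), time of day on a
    24-hour scale, carried-forward vital signs, the last point-of-care (POC)
    glucose and minutes since it was taken, insulin delivered in the trailing
    hour with a delivery-route flag, and the current dextrose infusion rate.
    ``include_sensor_current`` adds a synthetic CGM sensor-current channel
    derived proportionally from the glucose signal.
    """

    vitals: tuple[str, ...] = ("heart_rate", "respiratory_rate", "temperature_c")
    include_poc: bool = True
    insulin_window_minutes: float = 60.0
    include_dextrose: bool = True
    include_sensor_current: bool = False

    @property
    def column_names(self) -> list[str]:
        cols = ["cgm", "state_hypo", "state_normo", "state_hyper", "time_of_day"]
        cols += list(self.vitals)
        if self.include_poc:
            cols += ["minutes_since_poc", "last_poc_value"]
        cols += ["insulin_units_trailing", "insulin_route_infusion"]
        if self.include_dextrose:
            cols += ["dextrose_rate_mlh"]
        if self.include_sensor_current:
            cols += ["sensor_current_na"]
        return cols


DEFAULT_INPUT_SCHEMA = InputSchema()


def _locf(origin_ns: np.ndarray, ev_ns: np.ndarray, ev_vals: np.ndarray) -> np.ndarray:
    """Last observation at or before each origin; NaN where none exists."""
    out = np.full(len(origin_ns), np.nan)
    if len(ev_ns) == 0:
        return out
    idx = np.searchsorted(ev_ns, origin_ns, side="right") - 1
    ok = idx >= 0
    out[ok] = ev_vals[idx[ok]]
    return out


def assemble_x(trace: GlucoseTrace, records: ClinicalRecordSet,
               schema: InputSchema = DEFAULT_INPUT_SCHEMA) -> tuple[pd.DataFrame, np.ndarray]:
    """Input vectors for *every* grid point of ``trace``.

    Returns ``(X, complete)`` where ``X`` is indexed by origin timestamp and
    ``complete`` marks rows with no missing required input.  Every entry in
    row ``t`` depends only on data timestamped at or before ``t`` (LOCF and
    trailing half-open windows), which is what makes streaming replay and
    batch assembly agree.
    """
    times = trace.times
    span_lo = times[0] - pd.Timedelta(hours=1)
    span_hi = times[-1] + pd.Timedelta(hours=1)
    ev_times = records.events["timestamp"]
    if len(ev_times) and (ev_times.min() < span_lo or ev_times.max() > span_hi):
        raise FormatError(
            "event timestamps fall outside the trace span by more than 1 hour"
        )

    origin_ns = times.asi8
    X = pd.DataFrame(index=times)
    X["cgm"] = trace.values
    states = classify_states(trace.values)
    for s in STATES:
        X[f"state_{s}"] = (states == s).astype(float)
    X["time_of_day"] = (times.hour * 60 + times.minute) / 1440.0

    for v in schema.vitals:
        sub = records.subset("vital_signs", v)
        X[v] = _locf(origin_ns, sub["timestamp"].to_numpy().astype("i8"),
                     sub["value"].to_numpy(dtype=float))

    if schema.include_poc:
        sub = records.subset("poc_glucose", "glucose")
        poc_ns = sub["timestamp"].to_numpy().astype("i8")
        poc_vals = sub["value"].to_numpy(dtype=float)
        X["last_poc_value"] = _locf(origin_ns, poc_ns, poc_vals)
        last_t = _locf(origin_ns, poc_ns, poc_ns.astype(float))
        X["minutes_since_poc"] = (origin_ns - last_t) / 60e9

    # insulin: units in the trailing (t - window, t] interval, plus a flag for
    # whether the most recent dose in that window was an infusion
    sub = records.subset("insulin_delivery", "units_delivered")
    ins_ns = sub["timestamp"].to_numpy().astype("i8")
    ins_units = sub["value"].to_numpy(dtype=float)
    route_sub = records.subset("insulin_delivery", "route")
    route_by_ns = dict(zip(route_sub["timestamp"].to_numpy().astype("i8"),
                           route_sub["value"].astype(str)))
    window_ns = int(schema.insulin_window_minutes * 60e9)
    cs = np.concatenate([[0.0], np.cumsum(ins_units)])
    hi = np.searchsorted(ins_ns, origin_ns, side="right")
    lo = np.searchsorted(ins_ns, origin_ns - window_ns, side="right")
    X["insulin_units_trailing"] = cs[hi] - cs[lo]
    flag = np.zeros(len(times))
    has_dose = hi > lo
    last_idx = hi - 1
    for i in np.nonzero(has_dose)[0]:
        route = route_by_ns.get(ins_ns[last_idx[i]], "subcutaneous")
        flag[i] = 1.0 if route == "infusion" else 0.0
    X["insulin_route_infusion"] = flag

    if schema.include_dextrose:
        sub = records.subset("iv_infusions", "dextrose_rate")
        rate = _locf(origin_ns, sub["timestamp"].to_numpy().astype("i8"),
                     sub["value"].to_numpy(dtype=float))
        X["dextrose_rate_mlh"] = np.where(np.isnan(rate), 0.0, rate)

    if schema.include_sensor_current:
        # synthetic proportional ISIG-style channel derived from the glucose signal
        X["sensor_current_na"] = trace.values / 18.0

    X = X[schema.column_names]
    complete = ~X.isna().any(axis=1).to_numpy()
    return X, complete


@dataclass
class DesignMatrix:
    """Per-origin input vectors (x-block) paired with future CGM targets (y-block)."""

    origins: pd.DatetimeIndex
    X: pd.DataFrame
    Y: pd.DataFrame
    state_labels: np.ndarray
    sample_minutes: float
    horizon_minutes: float
    exclusions: dict = field(default_factory=dict)

    @property
    def column_names(self) -> list[str]:
        return list(self.X.columns)

    @property
    def n_rows(self) -> int:
        return len(self.X)

    def select_columns(self, names: list[str]) -> "DesignMatrix":
        missing = [n for n in names if n not in self.X.columns]
        if missing:
            raise SchemaError(f"design matrix lacks columns {missing}")
        return DesignMatrix(self.origins, self.X[list(names)], self.Y,
                            self.state_labels, self.sample_minutes,
                            self.horizon_minutes, dict(self.exclusions))


def assemble_design(trace: GlucoseTrace, records: ClinicalRecordSet,
                    schema: InputSchema = DEFAULT_INPUT_SCHEMA,
                    horizon_minutes: float = 75.0) -> DesignMatrix:
    """Assemble the x-block/y-block design matrix on the 5-minute grid.

    Origins whose full forecast window would run past the end of the trace
    are excluded, so a gap-free trace of ``n`` samples yields ``n - 15`` rows
    at the default 75-minute horizon.  Origins lacking a required prior
    observation (e.g. before the first vitals chart) are dropped and counted
    in ``exclusions``.
    """
    steps = horizon_steps(horizon_minutes, trace.sample_minutes)
    n = len(trace)
    n_rows = n - steps
    if n_rows < 1:
        raise DataError(
            f"trace has {n} samples; at least {steps + 1} are needed for a "
            f"{horizon_minutes}-minute horizon"
        )
    X_all, complete = assemble_x(trace, records, schema)
    X = X_all.iloc[:n_rows]
    keep = complete[:n_rows]
    vals = trace.values
    Y = pd.DataFrame(
        {f"target_{int((k + 1) * trace.sample_minutes)}": vals[k + 1:k + 1 + n_rows]
         for k in range(steps)},
        index=X.index,
    )
    excluded = int((~keep).sum())
    dm = DesignMatrix(
        origins=X.index[keep],
        X=X.loc[keep],
        Y=Y.loc[keep],
        state_labels=classify_states(vals[:n_rows][keep]),
        sample_minutes=trace.sample_minutes,
        horizon_minutes=horizon_minutes,
        exclusions={"n_excluded": excluded, "reason": "missing prior observation"},
    )
    return dm


def concat_designs(designs: list[DesignMatrix]) -> DesignMatrix:
    """Stack per-patient design matrices (time-ordered within each patient)."""
    if not designs:
        raise DataError("no design matrices to concatenate")
    cols = designs[0].column_names
    for d in designs[1:]:
        if d.column_names != cols:
            raise SchemaError("design matrices have differing columns")
    X = pd.concat([d.X for d in designs])
    Y = pd.concat([d.Y for d in designs])
    return DesignMatrix(
        origins=X.index,
        X=X,
        Y=Y,
        state_labels=np.concatenate([d.state_labels for d in designs]),
        sample_minutes=designs[0].sample_minutes,
        horizon_minutes=designs[0].horizon_minutes,
        exclusions={"n_excluded": sum(d.exclusions.get("n_excluded", 0) for d in designs)},
    )


def split_tail(design: DesignMatrix, fraction: float) -> tuple[DesignMatrix, DesignMatrix]:
    """Split off the time-ordered tail ``fraction`` of rows (for validation)."""
    if not 0 < fraction < 1:
        raise DataError("fraction must lie strictly between 0 and 1")
    n = design.n_rows
    cut = n - max(1, int(round(fraction * n)))
    if cut < 1:
        raise DataError("tail split would leave no head rows")

    def take(sl):
        return DesignMatrix(design.origins[sl], design.X.iloc[sl], design.Y.iloc[sl],
                            design.state_labels[sl], design.sample_minutes,
                            design.horizon_minutes, dict(design.exclusions))

    return take(slice(None, cut)), take(slice(cut, None))


def write_design(design: DesignMatrix, path) -> None:
    """Write a design matrix to delimited text with a header naming every column."""
    df = pd.concat([design.X, design.Y], axis=1)
    df.insert(0, "state", design.state_labels)
    df.insert(0, "origin", design.origins.strftime("%Y-%m-%dT%H:%M"))
    df.to_csv(path, index=False)


def read_design(path, sample_minutes: float = 5.0,
                horizon_minutes: float = 75.0) -> DesignMatrix:
    df = pd.read_csv(path)
    if "origin" not in df.columns or "state" not in df.columns:
        raise FormatError(f"design file {path} lacks origin/state columns")
    origins = pd.DatetimeIndex(pd.to_datetime(df.pop("origin")))
    states = df.pop("state").to_numpy(dtype=str)
    ycols = [c for c in df.columns if c.startswith("target_")]
    xcols = [c for c in df.columns if c not in ycols]
    X = df[xcols].astype(float)
    Y = df[ycols].astype(float)
    X.index = origins
    Y.index = origins
    return DesignMatrix(origins, X, Y, states, sample_minutes, horizon_minutes)
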