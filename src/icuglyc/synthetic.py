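"""Synthetic surgical-ICU glycemic trajectories with known ground truth.

Because no bedside dataset is deposited, every downstream stage (feature
selection, network training, streaming replay, evaluation) is exercised on
simulated patients whose generating process is fully known.  The serum
glucose trajectory follows a discrete-time additive model on the 5-minute
grid:

    G(t+1) = G(t) + r*(S(t) + C(t) - G(t)) - I(t) + D(t) + P(t) + eps(t)

where ``S`` is a hidden glycemic-regime setpoint (hypo / normo / hyper
episodes scheduled to hit a target state composition), ``C`` a circadian
modulation, ``I`` the delayed effect of sliding-scale insulin doses, ``D``
the effect of intravenous dextrose, ``P`` stress pulses, and ``eps`` AR(1)
noise.  Serum glucose is floored at 40 mg/dL.  The CGM channel is the serum
signal delayed by the interstitial lag (default 12.5 min, fractional-grid
linear interpolation) plus sensor noise; point-of-care (POC) glucose checks
occur at random 60-120 minute intervals and drive a sliding-scale insulin
protocol; heart rate is positively coupled to glucose and body temperature
drops during hypoglycemia, giving the learnable covariate structure the
forecasting model is meant to exploit.

Every per-step contribution is logged so tests can verify exact conservation
(``G[t+1] == G[t] + sum(contributions at t)``) and the direction of the
insulin/dextrose couplings.
"""

from __future__ import annotations

import dataclasses
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, ProtocolError
from .records import ClinicalRecordSet, GlucoseTrace, classify_states

# Dynamics constants (not exposed in SimConfig): per-step pull toward the
# regime setpoint, the hypo/hyper setpoints, AR(1) noise correlation, and the
# physiological floor.
REVERSION_PER_STEP = 0.35
HYPO_SETPOINT = 52.0
HYPER_SETPOINT = 185.0
AR_PHI = 0.6
GLUCOSE_FLOOR = 40.0
SETPOINT_RAMP_STEPS = 5  # 25-minute onset/offset ramp for regime excursions

#: Insulin action kernel: a 2-step (10-minute) onset delay then exponential
#: decay over 6 steps; scaled so the mean per-step drop is
#: insulin_sensitivity * units.
_k = np.exp(-np.arange(6) / 2.0)
INSULIN_KERNEL = 6.0 * _k / _k.sum()
INSULIN_DELAY_STEPS = 2

COMPONENT_COLUMNS = ("reversion", "circadian", "insulin", "dextrose",
                     "pulse", "noise", "clamp")


@dataclass(frozen=True)
class PatientProfile:
    patient_id: str
    admission_type: str  # "trauma" or "cardiothoracic"
    age_years: float
    bmi_kg_m2: float
    diabetic: bool
    los_days: float

    def __post_init__(self) -> None:
        if self.admission_type not in ("trauma", "cardiothoracic"):
            raise ConfigError(f"unknown admission type {self.admission_type!r}")
        if self.age_years < 18:
            raise ConfigError("inclusion criterion: age_years >= 18")
        if self.bmi_kg_m2 <= 0 or self.los_days <= 0:
            raise ConfigError("bmi_kg_m2 and los_days must be positive")


@dataclass(frozen=True)
class SlidingScaleProtocol:
    """Ordered glucose bands [lower, upper) with insulin doses in units.

    Bands must tile (0, inf) without gaps or overlaps and doses must be
    monotone non-decreasing in glucose.  Doses at or above
    ``infusion_threshold_units`` are delivered as a continuous infusion,
    smaller doses as subcutaneous injections.
    """

    bands: tuple[tuple[float, float, float], ...] = (
        (0.0, 150.0, 0.0),
        (150.0, 200.0, 2.0),
        (200.0, 250.0, 4.0),
        (250.0, 300.0, 6.0),
        (300.0, math.inf, 8.0),
    )
    infusion_threshold_units: float = 6.0

    def __post_init__(self) -> None:
        if not self.bands:
            raise ProtocolError("protocol needs at least one band")
        if self.bands[0][0] != 0.0 or self.bands[-1][1] != math.inf:
            raise ProtocolError("bands must start at 0 and end at infinity")
        prev_dose = -math.inf
        for i, (lo, hi, dose) in enumerate(self.bands):
            if hi <= lo:
                raise ProtocolError(f"band {i} is empty or inverted: [{lo}, {hi})")
            if i > 0 and lo != self.bands[i - 1][1]:
                raise ProtocolError(
                    f"bands {i - 1} and {i} are gapped or overlapping at {lo}"
                )
            if dose < prev_dose:
                raise ProtocolError("doses must be monotone non-decreasing")
            prev_dose = dose

    def dose(self, poc_value: float) -> tuple[float, str]:
        if not poc_value > 0:
            raise ConfigError(f"POC glucose must be positive, got {poc_value}")
        for lo, hi, dose in self.bands:
            if lo <= poc_value < hi:
                route = ("infusion" if dose >= self.infusion_threshold_units
                         else "subcutaneous")
                return dose, route
        raise ProtocolError(f"no band contains {poc_value}")  # pragma: no cover


DEFAULT_PROTOCOL = SlidingScaleProtocol()


def sliding_scale_insulin(poc_value: float,
                          protocol: SlidingScaleProtocol = DEFAULT_PROTOCOL
                          ) -> tuple[float, str]:
    """Dose (units) and route for a POC glucose under a sliding-scale protocol."""
    return protocol.dose(poc_value)


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    duration_hours: float = 24.0
    sample_minutes: float = 5.0
    basal_glucose_mgdl: float = 110.0
    circadian_amplitude_mgdl: float = 8.0
    insulin_sensitivity: float = 1.5  # mg/dL drop per unit per step
    dextrose_gain: float = 0.05  # mg/dL rise per (mL/h) per step
    stress_pulse_rate_per_day: float = 2.0
    ar_noise_sd_mgdl: float = 3.0
    sensor_noise_sd_mgdl: float = 2.0
    interstitial_lag_minutes: float = 12.5
    poc_interval_minutes: tuple[float, float] = (60.0, 120.0)
    target_composition: tuple[float, float, float] = (0.045, 0.838, 0.117)
    start_time: str = "2013-03-04T00:00"

    def __post_init__(self) -> None:
        if self.duration_hours <= 0 or self.sample_minutes <= 0:
            raise ConfigError("duration_hours and sample_minutes must be positive")
        n = self.duration_hours * 60.0 / self.sample_minutes
        if abs(n - round(n)) > 1e-9:
            raise ConfigError("sample_minutes must divide the duration evenly")
        lo, hi = self.poc_interval_minutes
        if not (0 < lo <= hi):
            raise ConfigError("poc_interval_minutes must be an increasing positive pair")
        comp = self.target_composition
        if len(comp) != 3 or any(not 0 <= c <= 1 for c in comp):
            raise ConfigError("target_composition fractions must lie in [0, 1]")
        if abs(sum(comp) - 1.0) > 1e-9:
            raise ConfigError("target_composition must sum to 1")
        for name in ("basal_glucose_mgdl",):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("circadian_amplitude_mgdl", "insulin_sensitivity",
                     "dextrose_gain", "stress_pulse_rate_per_day",
                     "ar_noise_sd_mgdl", "sensor_noise_sd_mgdl",
                     "interstitial_lag_minutes"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration_hours * 60.0 / self.sample_minutes))


@dataclass
class Schedules:
    """Pre-drawn exogenous inputs to the dynamics core (all per-step arrays)."""

    setpoint: np.ndarray
    circadian: np.ndarray
    dextrose_rate: np.ndarray
    pulse: np.ndarray
    noise: np.ndarray
    poc_times_min: np.ndarray
    poc_noise: np.ndarray
    regimes: np.ndarray
    insulin_override: np.ndarray | None = None  # fixed per-step drops; bypasses protocol


@dataclass
class TruthTrace:
    """Ground-truth serum series with an exact per-step contribution log."""

    times: pd.DatetimeIndex
    serum: np.ndarray
    component_log: pd.DataFrame  # n-1 rows, COMPONENT_COLUMNS
    regimes: np.ndarray
    composition: dict
    composition_warning: bool = False


def _regime_schedule(n: int, composition: tuple[float, float, float],
                     rng: np.random.Generator) -> np.ndarray:
    """Hidden-state path hitting the target occupancy via step quotas.

    Hypo and hyper time is split into short excursions (30-50 min and
    40-80 min respectively) placed at random positions separated by normo
    stretches; the remaining steps are normoglycemic.
    """
    p_hypo, _, p_hyper = composition
    quotas = {"hypo": int(round(n * p_hypo)), "hyper": int(round(n * p_hyper))}
    # hypo events are short (caught and treated within the hour); stress
    # hyperglycemia is sustained for hours
    bounds = {"hypo": (8, 12), "hyper": (24, 40)}
    # the reversion transit into a hypo excursion outlasts the transit out by
    # about two steps, so pad each hypo episode to keep the occupancy on target
    pads = {"hypo": 2, "hyper": 0}
    episodes: list[tuple[str, int]] = []
    for state in ("hypo", "hyper"):
        remaining = quotas[state]
        lo, hi = bounds[state]
        while remaining > 0:
            length = int(rng.integers(lo, hi + 1))
            if remaining - length < 3:
                length = remaining
            episodes.append((state, length + pads[state]))
            remaining -= length
    if not episodes:
        return np.full(n, "normo", dtype=object).astype(str)
    order = rng.permutation(len(episodes))
    episodes = [episodes[i] for i in order]
    k = len(episodes)
    total_exc = sum(length for _, length in episodes)
    free = n - total_exc
    if free < k + 1:
        raise ConfigError("target composition leaves no room for normo stretches")
    gap_min = min(6, free // (k + 1))
    extra = free - gap_min * (k + 1)
    gaps = gap_min + rng.multinomial(extra, np.full(k + 1, 1.0 / (k + 1)))
    regimes = np.full(n, "normo", dtype=object)
    pos = 0
    for i, (state, length) in enumerate(episodes):
        pos += int(gaps[i])
        regimes[pos:pos + length] = state
        pos += length
    return regimes.astype(str)


def build_schedules(config: SimConfig, rng: np.random.Generator) -> Schedules:
    """Draw all exogenous inputs in a fixed order (determinism contract)."""
    n = config.n_steps
    dt = config.sample_minutes
    duration_min = config.duration_hours * 60.0

    regimes = _regime_schedule(n, config.target_composition, rng)
    setpoint = np.where(regimes == "hypo", HYPO_SETPOINT,
                        np.where(regimes == "hyper", HYPER_SETPOINT,
                                 config.basal_glucose_mgdl)).astype(float)
    # physiological excursions build and resolve gradually: ramp the setpoint
    # path with a short moving average instead of switching stepwise
    if n > SETPOINT_RAMP_STEPS:
        pad = SETPOINT_RAMP_STEPS // 2
        padded = np.pad(setpoint, pad, mode="edge")
        kernel = np.ones(SETPOINT_RAMP_STEPS) / SETPOINT_RAMP_STEPS
        setpoint = np.convolve(padded, kernel, mode="valid")[:n]

    start = pd.Timestamp(config.start_time)
    hod = (start.hour + start.minute / 60.0 + np.arange(n) * dt / 60.0) % 24.0
    circadian = config.circadian_amplitude_mgdl * np.sin(2 * np.pi * (hod - 8.0) / 24.0)

    # stress pulses: Poisson count, uniform onset, exponential release over 8 steps
    pulse = np.zeros(n)
    n_pulses = rng.poisson(config.stress_pulse_rate_per_day * config.duration_hours / 24.0)
    onsets = np.sort(rng.uniform(0, n - 1, size=n_pulses).astype(int))
    totals = rng.uniform(15.0, 35.0, size=n_pulses)
    pk = np.exp(-np.arange(8) / 2.0)
    pk /= pk.sum()
    for onset, total in zip(onsets, totals):
        hi = min(8, n - onset)
        pulse[onset:onset + hi] += total * pk[:hi]

    # dextrose: nutrition episodes plus a rescue drip during hypo regimes
    rate = np.zeros(n)
    n_epi = rng.poisson(3.0 * config.duration_hours / 24.0)
    starts = rng.uniform(0, duration_min, size=n_epi)
    durs = rng.uniform(60.0, 180.0, size=n_epi)
    levels = rng.uniform(20.0, 60.0, size=n_epi)
    for s, d, lvl in zip(starts, durs, levels):
        i0, i1 = int(s / dt), min(n, int((s + d) / dt) + 1)
        rate[i0:i1] = np.maximum(rate[i0:i1], lvl)
    rate[regimes == "hypo"] += 30.0

    innov = rng.normal(0.0, 1.0, size=n)
    noise = np.zeros(n)
    scale = config.ar_noise_sd_mgdl * math.sqrt(1.0 - AR_PHI ** 2)
    for t in range(1, n):
        noise[t] = AR_PHI * noise[t - 1] + scale * innov[t]

    # POC check times: first at admission, then gaps uniform in the configured
    # interval, rounded to the minute
    lo, hi = config.poc_interval_minutes
    poc_times = [0.0]
    while True:
        nxt = poc_times[-1] + rng.uniform(lo, hi)
        if nxt >= duration_min:
            break
        poc_times.append(nxt)
    poc_times_min = np.round(np.array(poc_times))
    poc_noise = rng.normal(0.0, 1.0, size=len(poc_times_min))

    return Schedules(setpoint=setpoint, circadian=circadian, dextrose_rate=rate,
                     pulse=pulse, noise=noise, poc_times_min=poc_times_min,
                     poc_noise=poc_noise, regimes=regimes)


def integrate(schedules: Schedules, config: SimConfig,
              protocol: SlidingScaleProtocol = DEFAULT_PROTOCOL
              ) -> tuple[np.ndarray, np.ndarray, list, list]:
    """Step the additive dynamics; returns (serum, component_log, poc, insulin).

    ``poc`` is a list of (time_min, value); ``insulin`` a list of
    (time_min, units, route).  When ``schedules.insulin_override`` is given
    the sliding-scale feedback loop is bypassed and the override array is
    used as the per-step insulin drop — this open-loop path is monotone in
    each exogenous input, which is what the coupling-direction tests check.
    """
    n = config.n_steps
    dt = config.sample_minutes
    G = np.empty(n)
    G[0] = schedules.setpoint[0]
    comp = np.zeros((n - 1, len(COMPONENT_COLUMNS)))
    ins_effect = np.zeros(n + INSULIN_DELAY_STEPS + len(INSULIN_KERNEL))
    poc_log: list[tuple[float, float]] = []
    ins_log: list[tuple[float, float, str]] = []
    poc_times = schedules.poc_times_min
    poc_idx = 0
    override = schedules.insulin_override
    r = REVERSION_PER_STEP

    for t in range(n - 1):
        while poc_idx < len(poc_times) and poc_times[poc_idx] < (t + 1) * dt:
            tm = poc_times[poc_idx]
            value = G[t] * (1.0 + 0.05 * schedules.poc_noise[poc_idx])
            value = max(value, GLUCOSE_FLOOR)
            poc_log.append((tm, value))
            if override is None:
                units, route = protocol.dose(value)
                if units > 0:
                    dose_min = tm + 5.0  # nurse response latency
                    start = int(dose_min // dt) + INSULIN_DELAY_STEPS
                    for k, w in enumerate(INSULIN_KERNEL):
                        ins_effect[start + k] += units * config.insulin_sensitivity * w
                    ins_log.append((dose_min, units, route))
            poc_idx += 1

        drop = override[t] if override is not None else ins_effect[t]
        parts = np.array([
            r * (schedules.setpoint[t] - G[t]),
            r * schedules.circadian[t],
            -drop,
            config.dextrose_gain * schedules.dextrose_rate[t],
            schedules.pulse[t],
            schedules.noise[t],
            0.0,
        ])
        total = parts.sum()
        if G[t] + total < GLUCOSE_FLOOR:
            parts[-1] = GLUCOSE_FLOOR - (G[t] + total)
            total = parts.sum()
        G[t + 1] = G[t] + total
        comp[t] = parts

    return G, comp, poc_log, ins_log


def simulate_patient(profile: PatientProfile, config: SimConfig,
                     protocol: SlidingScaleProtocol = DEFAULT_PROTOCOL
                     ) -> tuple[TruthTrace, GlucoseTrace, ClinicalRecordSet]:
    """Simulate one patient: serum truth, lagged noisy CGM, clinical events.

    The CGM series is the serum signal delayed by
    ``config.interstitial_lag_minutes`` via linear interpolation between grid
    points (before the lag transient it holds the initial serum value), plus
    Gaussian sensor noise, clipped to the 40-400 mg/dL device range.  Same
    seed, profile and config give bit-identical outputs.
    """
    if config.duration_hours < 2:
        raise ConfigError("simulation needs a duration of at least 2 hours")
    rng = np.random.default_rng(config.seed)
    sched = build_schedules(config, rng)
    serum, comp, poc_log, ins_log = integrate(sched, config, protocol)

    n = config.n_steps
    dt = config.sample_minutes
    start = pd.Timestamp(config.start_time)
    times = pd.DatetimeIndex([start + pd.Timedelta(minutes=i * dt) for i in range(n)])
    t_min = np.arange(n) * dt

    cgm_vals = np.interp(t_min - config.interstitial_lag_minutes, t_min, serum)
    cgm_vals = cgm_vals + rng.normal(0.0, config.sensor_noise_sd_mgdl, size=n)
    cgm_vals = np.clip(cgm_vals, GLUCOSE_FLOOR, 400.0)

    # vitals: HR charted every 15 min (positively coupled to glucose), RR every
    # 15 min (autonomous), temperature hourly (drops during hypoglycemia)
    events: list[dict] = []

    def add(minute: float, category: str, variable: str, value, units: str) -> None:
        events.append({
            "timestamp": start + pd.Timedelta(minutes=float(np.floor(minute))),
            "category": category, "variable": variable,
            "value": value, "units": units,
        })

    hr_times = np.arange(0.0, config.duration_hours * 60.0, 15.0)
    hr_noise = rng.normal(0.0, 2.0, size=len(hr_times))
    rr_noise = rng.normal(0.0, 1.5, size=len(hr_times))
    tm_times = np.arange(0.0, config.duration_hours * 60.0, 60.0)
    tm_noise = rng.normal(0.0, 0.08, size=len(tm_times))
    for tm, eps_hr, eps_rr in zip(hr_times, hr_noise, rr_noise):
        g = serum[int(tm / dt)]
        hr = 72.0 + 0.15 * (g - config.basal_glucose_mgdl) + eps_hr
        add(tm, "vital_signs", "heart_rate", round(hr, 1), "bpm")
        add(tm, "vital_signs", "respiratory_rate", round(16.0 + eps_rr, 1), "breaths/min")
    for tm, eps in zip(tm_times, tm_noise):
        g = serum[int(tm / dt)]
        temp = 37.0 - 0.05 * max(0.0, 70.0 - g) + eps
        add(tm, "vital_signs", "temperature_c", round(temp, 2), "degC")

    for tm, value in poc_log:
        add(tm, "poc_glucose", "glucose", round(value, 1), "mg/dL")
    for tm, units, route in ins_log:
        add(tm, "insulin_delivery", "units_delivered", units, "U")
        add(tm, "insulin_delivery", "route", route, "")

    # chart dextrose rate changes (LOCF reconstructs the piecewise-constant rate)
    rate = sched.dextrose_rate
    prev = None
    for i in range(n):
        if prev is None or rate[i] != prev:
            add(i * dt, "iv_infusions", "dextrose_rate", round(float(rate[i]), 1), "mL/h")
            prev = rate[i]

    add(0.0, "demographics", "admission_type", profile.admission_type, "")
    add(0.0, "demographics", "age_years", profile.age_years, "yr")
    add(0.0, "demographics", "bmi", profile.bmi_kg_m2, "kg/m2")
    add(0.0, "demographics", "diabetic", str(profile.diabetic), "")

    records = ClinicalRecordSet(profile.patient_id, pd.DataFrame(events))
    cgm = GlucoseTrace(profile.patient_id, times, cgm_vals)

    states = classify_states(serum)
    composition = {s: 100.0 * float(np.mean(states == s)) for s in ("hypo", "normo", "hyper")}
    target = dict(zip(("hypo", "normo", "hyper"),
                      (100.0 * c for c in config.target_composition)))
    warning = any(abs(composition[s] - target[s]) > 10.0 for s in composition)

    truth = TruthTrace(
        times=times, serum=serum,
        component_log=pd.DataFrame(comp, columns=list(COMPONENT_COLUMNS)),
        regimes=sched.regimes, composition=composition,
        composition_warning=warning,
    )
    return truth, cgm, records


# ---------------------------------------------------------------------------
# Cohorts

#: Per-patient seed rule, also recorded in the manifest header.
SEED_RULE = "patient seed = SeedSequence([master_seed, patient_index]).generate_state(1)[0] & 0x7fffffff"


def _child_seed(master_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] & 0x7FFFFFFF)


def _draw_profile(patient_id: str, rng: np.random.Generator) -> PatientProfile:
    """Demographics emulating a mixed trauma / cardiothoracic SICU cohort."""
    trauma = rng.random() < 8.0 / 14.0
    if trauma:
        age = float(np.clip(rng.normal(47.7, 14.9), 18.0, 95.0))
        bmi = float(np.clip(rng.normal(33.1, 3.6), 16.0, 55.0))
        los = float(max(1.0, rng.normal(9.0, 3.0)))
        diabetic = False
    else:
        age = float(np.clip(rng.normal(74.6, 6.4), 18.0, 95.0))
        bmi = float(np.clip(rng.normal(27.7, 4.2), 16.0, 55.0))
        los = float(max(1.0, rng.normal(4.0, 1.5)))
        diabetic = True
    return PatientProfile(patient_id, "trauma" if trauma else "cardiothoracic",
                          age, bmi, diabetic, los)


@dataclass
class PatientSim:
    profile: PatientProfile
    truth: TruthTrace
    cgm: GlucoseTrace
    records: ClinicalRecordSet
    seed: int
    split: str  # "train" or "test"


@dataclass
class CohortResult:
    patients: list[PatientSim]
    manifest: pd.DataFrame

    def split(self, name: str) -> list[PatientSim]:
        return [p for p in self.patients if p.split == name]


def generate_cohort(n_patients: int, config: SimConfig, seed: int,
                    n_train: int | None = None, out_dir=None,
                    overwrite: bool = False,
                    protocol: SlidingScaleProtocol = DEFAULT_PROTOCOL) -> CohortResult:
    """Simulate ``n_patients`` independent patients with derived sub-seeds.

    The first ``n_train`` patients are flagged "train", the rest "test"
    (default split mirrors a 14-of-19 training design).  With ``out_dir``
    set, per-patient CGM and event files plus a manifest are written; an
    existing directory is refused unless ``overwrite`` is passed.  The same
    master seed always yields byte-identical manifests.
    """
    if n_patients < 1:
        raise ConfigError("n_patients must be at least 1")
    if n_train is None:
        n_train = int(round(n_patients * 14.0 / 19.0))
    if not 0 <= n_train <= n_patients:
        raise ConfigError("n_train must lie in [0, n_patients]")

    if out_dir is not None:
        out_dir = os.fspath(out_dir)
        if os.path.exists(out_dir) and os.listdir(out_dir) and not overwrite:
            raise ConfigError(
                f"output directory {out_dir!r} exists; pass overwrite=True to replace"
            )
        os.makedirs(out_dir, exist_ok=True)

    patients: list[PatientSim] = []
    rows: list[dict] = []
    for i in range(n_patients):
        pid = f"patient_{i + 1:02d}"
        pseed = _child_seed(seed, i)
        profile = _draw_profile(pid, np.random.default_rng(
            np.random.SeedSequence([seed, i, 7])))
        pconfig = dataclasses.replace(config, seed=pseed)
        truth, cgm, records = simulate_patient(profile, pconfig, protocol)
        split = "train" if i < n_train else "test"
        sim = PatientSim(profile, truth, cgm, records, pseed, split)
        patients.append(sim)
        row = {
            "patient_id": pid, "split": split,
            "admission_type": profile.admission_type,
            "age_years": f"{profile.age_years:.1f}",
            "bmi_kg_m2": f"{profile.bmi_kg_m2:.1f}",
            "diabetic": profile.diabetic,
            "seed": pseed, "n_samples": len(cgm),
            "pct_hypo": f"{truth.composition['hypo']:.1f}",
            "pct_normo": f"{truth.composition['normo']:.1f}",
            "pct_hyper": f"{truth.composition['hyper']:.1f}",
            "composition_warning": truth.composition_warning,
        }
        if out_dir is not None:
            from .records import write_cgm, write_events

            cgm_path = os.path.join(out_dir, f"{pid}.cgm.csv")
            ev_path = os.path.join(out_dir, f"{pid}.events.csv")
            write_cgm(cgm, cgm_path)
            write_events(records, ev_path)
            row["cgm_file"] = os.path.basename(cgm_path)
            row["events_file"] = os.path.basename(ev_path)
        rows.append(row)

    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        path = os.path.join(out_dir, "manifest.csv")
        with open(path, "w") as fh:
            fh.write(f"# master_seed={seed}; {SEED_RULE}\n")
            manifest.to_csv(fh, index=False)
    return CohortResult(patients, manifest)
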