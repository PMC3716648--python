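"""Forecast performance battery: MAD%, Clarke Error Grid, state recall.

MAD% is the mean absolute difference percent between predicted and actual
glucose, |predicted - actual| / actual x 100 averaged over pairs.  Clarke
Error Grid Analysis (CEGA) partitions the (reference, predicted) plane into
zones A (within 20% or both hypoglycemic), B (benign error), C (would
trigger unnecessary treatment), D (dangerous failure to detect), and E
(treatment confusion between hypo- and hyperglycemia); A+B is the
"clinically acceptable" fraction.  State recall scores, per glycemic state,
the fraction of actual values in the state whose prediction lands in the
same state; a state with no actual pairs is reported absent, not zero.

Evaluation pools all 15 horizon steps of every origin; per-step MAD% is
also emitted for diagnostics.  Internal values keep full precision — percent
rounding (half away from zero, one decimal) is applied only when a report
is formatted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, DomainError
from .network import PredictionSet
from .records import ClinicalRecordSet, GlucoseTrace, STATES, classify_states

ZONES = ("A", "B", "C", "D", "E")


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (100.05 -> 100.1), unlike banker's rounding."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def mad_percent(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Mean absolute difference percent of predicted vs actual glucose."""
    actual = np.asarray(actual, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if actual.size != predicted.size:
        raise DataError("actual and predicted lengths differ")
    if actual.size == 0:
        raise DataError("need at least one pair")
    if not np.all(actual > 0):
        idx = int(np.argmin(actual > 0))
        raise DomainError(f"non-positive actual glucose at index {idx}")
    return float(np.mean(np.abs(predicted - actual) / actual) * 100.0)


def clarke_zones(reference: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    """Vectorized Clarke zone classification.

    Piecewise boundaries of the published grid, applied in the order
    A, E, C, D, else B, so boundary points resolve to the earlier (more
    favorable) rule.  Both inputs must lie in (0, 1000) mg/dL.
    """
    r = np.asarray(reference, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if r.shape != p.shape:
        raise DataError("reference and predicted shapes differ")
    for name, v in (("reference", r), ("predicted", p)):
        if not np.all((v > 0) & (v < 1000)):
            bad = v[~((v > 0) & (v < 1000))].ravel()[0]
            raise DomainError(f"{name} glucose {bad} outside (0, 1000) mg/dL")
    A = ((r <= 70) & (p <= 70)) | ((p >= 0.8 * r) & (p <= 1.2 * r))
    E = ((r >= 180) & (p <= 70)) | ((r <= 70) & (p >= 180))
    C = ((r >= 70) & (r <= 290) & (p >= r + 110)) | \
        ((r >= 130) & (r <= 180) & (p <= (7.0 / 5.0) * r - 182.0))
    D = ((r >= 240) & (p >= 70) & (p <= 180)) | \
        ((r <= 175.0 / 3.0) & (p >= 70) & (p <= 180)) | \
        ((r >= 175.0 / 3.0) & (r <= 70) & (p >= (6.0 / 5.0) * r))
    return np.select([A, E, C, D], ["A", "E", "C", "D"], default="B").astype(str)


def clarke_zone(reference: float, predicted: float) -> str:
    """Zone of a single (reference, predicted) pair."""
    return str(clarke_zones(np.asarray([reference]), np.asarray([predicted]))[0])


def cega_report(prediction_set: PredictionSet) -> dict:
    """Zone tallies over all origins and horizon steps of a prediction set."""
    actual, predicted = prediction_set.pairs()
    if actual.size == 0:
        raise DataError("empty prediction set")
    try:
        zones = clarke_zones(actual, predicted)
    except DomainError as exc:
        raise DomainError(f"{exc} (while classifying pooled pairs)") from exc
    counts = {z: int(np.sum(zones == z)) for z in ZONES}
    n = actual.size
    percents = {z: 100.0 * counts[z] / n for z in ZONES}
    return {
        "n_pairs": int(n),
        "zone_counts": counts,
        "zone_percents": percents,
        "clinically_acceptable_percent": percents["A"] + percents["B"],
    }


def state_recall(prediction_set: PredictionSet) -> dict:
    """Per-state recall: share of actual values in a state predicted in-state.

    States with no actual pairs are omitted from the result, mirroring how a
    test set without hypoglycemia simply has no hypoglycemic recall.
    """
    actual, predicted = prediction_set.pairs()
    if actual.size == 0:
        raise DataError("empty prediction set")
    a_state = classify_states(actual)
    p_state = classify_states(predicted)
    out = {}
    for s in STATES:
        denom = int(np.sum(a_state == s))
        if denom == 0:
            continue
        hits = int(np.sum((a_state == s) & (p_state == s)))
        out[s] = 100.0 * hits / denom
    return out


def composition(labels: np.ndarray) -> dict:
    """State percentages of a label sequence; always reports all three states."""
    labels = np.asarray(labels, dtype=str)
    if labels.size == 0:
        raise DataError("empty label sequence")
    return {s: 100.0 * float(np.mean(labels == s)) for s in STATES}


def paired_device_error(cgm: GlucoseTrace, poc_events: ClinicalRecordSet,
                        max_pair_gap_minutes: float = 2.5) -> tuple[int, float | None]:
    """CGM accuracy against POC glucose: (n_pairs, MAD% with POC denominator).

    Each POC event pairs with the nearest CGM sample within the gap; ties
    break toward the earlier sample.  No pairable events gives ``(0, None)``.
    """
    sub = poc_events.subset("poc_glucose", "glucose")
    poc_ns = sub["timestamp"].to_numpy().astype("i8").astype(float)
    poc_vals = sub["value"].to_numpy(dtype=float)
    grid_ns = cgm.times.asi8.astype(float)
    gap_ns = max_pair_gap_minutes * 60e9
    pairs_poc, pairs_cgm = [], []
    for t, v in zip(poc_ns, poc_vals):
        idx = int(np.searchsorted(grid_ns, t))
        best = None
        for j in (idx - 1, idx):
            if 0 <= j < len(grid_ns):
                d = abs(grid_ns[j] - t)
                # strict < keeps the earlier sample on a tie
                if best is None or d < best[0]:
                    best = (d, j)
        if best is not None and best[0] <= gap_ns:
            pairs_poc.append(v)
            pairs_cgm.append(cgm.values[best[1]])
    if not pairs_poc:
        return 0, None
    return len(pairs_poc), mad_percent(np.array(pairs_poc), np.array(pairs_cgm))


def resample_for_plot(prediction_set: PredictionSet, every_k: int = 20
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Thin the pooled (actual, predicted) pairs to indices 0, k, 2k, ..."""
    if every_k < 1:
        raise DataError("every_k must be at least 1")
    actual, predicted = prediction_set.pairs()
    return actual[::every_k], predicted[::every_k]


@dataclass
class EvaluationReport:
    n_pairs: int
    mad_percent: float
    zone_counts: dict
    zone_percents: dict
    clinically_acceptable_percent: float
    state_recall: dict
    composition: dict
    per_step_mad_percent: list = field(default_factory=list)

    def formatted(self) -> dict:
        """Report with percents rounded half away from zero to one decimal."""
        r = round_half_away
        return {
            "n_pairs": self.n_pairs,
            "mad_percent": r(self.mad_percent),
            "zone_counts": dict(self.zone_counts),
            "zone_percents": {z: r(v) for z, v in self.zone_percents.items()},
            "clinically_acceptable_percent": r(self.clinically_acceptable_percent),
            "state_recall": {s: r(v) for s, v in self.state_recall.items()},
            "composition": {s: r(v) for s, v in self.composition.items()},
            "per_step_mad_percent": [r(v) for v in self.per_step_mad_percent],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.formatted(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def evaluate(prediction_set: PredictionSet) -> EvaluationReport:
    """Full performance battery over a prediction set (all steps pooled)."""
    actual, predicted = prediction_set.pairs()
    cega = cega_report(prediction_set)
    per_step = [
        mad_percent(prediction_set.actual[:, k], prediction_set.predicted[:, k])
        for k in range(prediction_set.n_steps)
    ]
    return EvaluationReport(
        n_pairs=cega["n_pairs"],
        mad_percent=mad_percent(actual, predicted),
        zone_counts=cega["zone_counts"],
        zone_percents=cega["zone_percents"],
        clinically_acceptable_percent=cega["clinically_acceptable_percent"],
        state_recall=state_recall(prediction_set),
        composition=composition(classify_states(actual)),
        per_step_mad_percent=per_step,
    )


def plot_clarke_grid(prediction_set: PredictionSet, path,
                     every_k: int = 20) -> None:
    """Scatter the (thinned) pairs over the Clarke zone boundary segments."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    actual, predicted = resample_for_plot(prediction_set, every_k)
    fig, ax = plt.subplots(figsize=(6, 6))
    lim = 400
    ax.plot([0, lim], [0, lim], "k:", lw=0.8)
    ax.plot([0, lim], [0, 1.2 * lim], "k-", lw=0.8)
    ax.plot([0, lim], [0, 0.8 * lim], "k-", lw=0.8)
    ax.plot([70, 70], [0, 56], "k-", lw=0.8)
    ax.plot([0, 70], [180, 180], "k-", lw=0.8)
    ax.plot([180, lim], [70, 70], "k-", lw=0.8)
    ax.plot([240, 240], [70, 180], "k-", lw=0.8)
    ax.plot([240, lim], [180, 180], "k-", lw=0.8)
    ax.plot([130, 180], [0, 70], "k-", lw=0.8)
    ax.plot([70, 290], [180, lim], "k-", lw=0.8)
    ax.scatter(actual, predicted, s=8, alpha=0.6)
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    ax.set_xlabel("reference glucose (mg/dL)")
    ax.set_ylabel("predicted glucose (mg/dL)")
    ax.set_title("Clarke Error Grid")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
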