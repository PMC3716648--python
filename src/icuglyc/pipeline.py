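"""End-to-end pipeline: simulate -> assemble -> select -> train -> replay -> evaluate.

Mirrors a multi-patient study design: a cohort is simulated, training
patients' design matrices are stacked, the GA prunes the input set, the
network is trained on the pruned x-block, and the frozen model is replayed
tick-by-tick over each held-out test patient; pooled scorable forecasts feed
the evaluation battery.  Every stage seed derives deterministically from the
master seed, so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import evaluation as ev
from .errors import ConfigError
from .ga import GAConfig, reduction_percent, select_inputs
from .network import PredictionSet, TrainConfig, init_network, save_model, train
from .records import (DEFAULT_INPUT_SCHEMA, InputSchema, assemble_design,
                      concat_designs, split_tail)
from .replay import run_replay
from .synthetic import SimConfig, generate_cohort

log = logging.getLogger("icuglyc")


def derive_seed(master: int, stage: int) -> int:
    """Stage seed from the master seed (stable splitting rule, < 2**31)."""
    return int(np.random.SeedSequence([master, stage]).generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    n_train: int = 14
    n_test: int = 5
    duration_hours: float = 24.0
    hidden_units: int = 30
    validation_tail_fraction: float = 0.3  # per-patient tail held out for early stopping
    ga_enabled: bool = True
    overwrite: bool = False
    make_plot: bool = False
    sim: SimConfig = field(default_factory=SimConfig)
    ga: GAConfig = field(default_factory=GAConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    schema: InputSchema = field(default_factory=InputSchema)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "out_dir" not in doc:
            raise ConfigError(f"config {path} lacks required key 'out_dir'")
        kwargs = {}
        for key in ("out_dir", "seed", "n_train", "n_test", "duration_hours",
                    "hidden_units", "ga_enabled", "overwrite", "make_plot"):
            if key in doc:
                kwargs[key] = doc[key]
        for key, klass in (("sim", SimConfig), ("ga", GAConfig),
                           ("train", TrainConfig), ("schema", InputSchema)):
            if key in doc:
                sub = dict(doc[key])
                for tup in ("poc_interval_minutes", "target_composition", "vitals"):
                    if tup in sub and isinstance(sub[tup], list):
                        sub[tup] = tuple(sub[tup])
                try:
                    kwargs[key] = klass(**sub)
                except TypeError as exc:
                    raise ConfigError(f"bad '{key}' section in {path}: {exc}") from exc
        return cls(**kwargs)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns a summary dict and writes artifacts to out_dir."""
    t_start = time.perf_counter()
    out = os.fspath(config.out_dir)
    os.makedirs(out, exist_ok=True)

    def stage(name):
        log.info("stage %-16s starting", name)
        return time.perf_counter()

    t0 = stage("simulate")
    n_total = config.n_train + config.n_test
    sim_cfg = dataclasses.replace(config.sim, duration_hours=config.duration_hours)
    cohort = generate_cohort(
        n_total, sim_cfg, seed=derive_seed(config.seed, 0),
        n_train=config.n_train, out_dir=os.path.join(out, "data"),
        overwrite=True,
    )
    log.info("stage simulate done in %.1fs", time.perf_counter() - t0)

    t0 = stage("assemble")
    heads, tails = [], []
    for p in cohort.split("train"):
        full = assemble_design(p.cgm, p.records, config.schema)
        head, tail = split_tail(full, config.validation_tail_fraction)
        heads.append(head)
        tails.append(tail)
    design = concat_designs(heads)
    val_design = concat_designs(tails)
    log.info("stage assemble done in %.1fs (%d rows, %d candidates)",
             time.perf_counter() - t0, design.n_rows, len(design.column_names))

    t0 = stage("select")
    n_before = len(design.column_names)
    if config.ga_enabled:
        ga_cfg = dataclasses.replace(config.ga, seed=derive_seed(config.seed, 1))
        mask, history = select_inputs(design, ga_cfg)
        selected = history["selected"]
        with open(os.path.join(out, "mask.json"), "w") as fh:
            json.dump({"selected": selected,
                       "rmsecv_best": history["best"][-1],
                       "n_before": n_before, "n_after": len(selected),
                       "reduction_percent": reduction_percent(n_before, len(selected))},
                      fh, indent=2)
        design = design.select_columns(selected)
        val_design = val_design.select_columns(selected)
    else:
        selected = design.column_names
    reduction = reduction_percent(n_before, len(selected))
    log.info("stage select done in %.1fs (%d -> %d inputs)",
             time.perf_counter() - t0, n_before, len(selected))

    t0 = stage("train")
    train_cfg = dataclasses.replace(config.train, seed=derive_seed(config.seed, 2))
    model = init_network(len(selected), config.hidden_units,
                         seed=derive_seed(config.seed, 3))
    model, history = train(model, design, train_cfg, val_design=val_design)
    save_model(model, os.path.join(out, "model.json"))
    log.info("stage train done in %.1fs (%d epochs, final val MSE %.4g)",
             time.perf_counter() - t0, len(history["train_mse"]),
             history["val_mse"][-1] if history["val_mse"] else float("nan"))

    t0 = stage("replay")
    pred_sets = []
    for p in cohort.split("test"):
        rlog = run_replay(model, p.cgm, p.records, config.schema)
        rlog.to_csv(os.path.join(out, f"{p.profile.patient_id}.replay.csv"))
        pred_sets.append(rlog.scorable_prediction_set())
    predictions = PredictionSet.concat(pred_sets)
    predictions.to_csv(os.path.join(out, "predictions.csv"))
    log.info("stage replay done in %.1fs (%d origins)",
             time.perf_counter() - t0, len(predictions.origins))

    t0 = stage("evaluate")
    report = ev.evaluate(predictions)
    report.to_json(os.path.join(out, "report.json"))
    n_poc = 0
    poc_mads = []
    for p in cohort.split("train"):
        n_i, mad_i = ev.paired_device_error(p.cgm, p.records)
        if mad_i is not None:
            n_poc += n_i
            poc_mads.append((n_i, mad_i))
    device_mad = (sum(n_i * m for n_i, m in poc_mads) / n_poc) if n_poc else None
    if config.make_plot:
        ev.plot_clarke_grid(predictions, os.path.join(out, "clarke_grid.png"))
    log.info("stage evaluate done in %.1fs", time.perf_counter() - t0)

    summary = {
        "seed": config.seed,
        "n_train_patients": config.n_train,
        "n_test_patients": config.n_test,
        "n_train_rows": design.n_rows,
        "input_reduction_percent": reduction,
        "selected_inputs": selected,
        "n_predictions": report.n_pairs,
        "mad_percent": report.mad_percent,
        "zone_percents": report.zone_percents,
        "clinically_acceptable_percent": report.clinically_acceptable_percent,
        "state_recall": report.state_recall,
        "composition": report.composition,
        "cgm_poc_n_pairs": n_poc,
        "cgm_poc_mad_percent": device_mad,
    }
    with open(os.path.join(out, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("pipeline complete in %.1fs", time.perf_counter() - t_start)
    return summary
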