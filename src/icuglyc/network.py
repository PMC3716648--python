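"""Three-layer feed-forward network for multi-step glucose forecasting.

One input layer, one hidden layer (tanh or logistic), and a linear output
layer of 15 units — one per 5-minute step of the 75-minute prediction
horizon.  Training minimizes the mean squared error over all 15 outputs in
standardized space by error backpropagation with the classic gradient
descent with momentum update

    dw <- momentum * dw_prev - learning_rate * gradient,  w <- w + dw

in either per-sample or full-batch mode, with early stopping on a held-out
time-ordered tail of the training rows.  Inputs are standardized per column
and targets centered/scaled by training-set statistics only; forecasts are
mapped back to mg/dL and clamped to the 40-400 mg/dL CGM reporting range.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, NumericalError, SchemaError
from .records import DesignMatrix

CLAMP_LO = 40.0
CLAMP_HI = 400.0


def _act(name: str):
    if name == "tanh":
        return np.tanh, lambda h: 1.0 - h ** 2
    if name == "logistic":
        return (lambda z: 1.0 / (1.0 + np.exp(-z))), lambda h: h * (1.0 - h)
    raise ConfigError(f"unknown hidden activation {name!r}")


@dataclass
class NetworkModel:
    n_inputs: int
    n_hidden: int
    n_outputs: int
    hidden_activation: str
    W1: np.ndarray  # (n_inputs, n_hidden)
    b1: np.ndarray  # (n_hidden,)
    W2: np.ndarray  # (n_hidden, n_outputs)
    b2: np.ndarray  # (n_outputs,)
    x_center: np.ndarray
    x_scale: np.ndarray
    y_center: float = 0.0
    y_scale: float = 1.0
    input_names: list[str] | None = None

    def params(self) -> dict:
        return {"W1": self.W1, "b1": self.b1, "W2": self.W2, "b2": self.b2}

    def set_params(self, p: dict) -> None:
        self.W1, self.b1 = p["W1"], p["b1"]
        self.W2, self.b2 = p["W2"], p["b2"]


def init_network(n_inputs: int, n_hidden: int, seed: int, n_outputs: int = 15,
                 hidden_activation: str = "tanh") -> NetworkModel:
    """Fresh network with fan-in-scaled symmetric-uniform weights, zero biases.

    Each layer's weights are drawn from U(-1/sqrt(fan_in), 1/sqrt(fan_in));
    identical seeds give identical weights.  Scalings start at identity and
    are set by :func:`train`.
    """
    if n_inputs < 1 or n_hidden < 1 or n_outputs < 1:
        raise ConfigError("layer sizes must be at least 1")
    _act(hidden_activation)
    rng = np.random.default_rng(seed)
    lim1 = 1.0 / np.sqrt(n_inputs)
    lim2 = 1.0 / np.sqrt(n_hidden)
    return NetworkModel(
        n_inputs=n_inputs, n_hidden=n_hidden, n_outputs=n_outputs,
        hidden_activation=hidden_activation,
        W1=rng.uniform(-lim1, lim1, size=(n_inputs, n_hidden)),
        b1=np.zeros(n_hidden),
        W2=rng.uniform(-lim2, lim2, size=(n_hidden, n_outputs)),
        b2=np.zeros(n_outputs),
        x_center=np.zeros(n_inputs), x_scale=np.ones(n_inputs),
    )


def _forward_scaled(model: NetworkModel, Xs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    act, _ = _act(model.hidden_activation)
    H = act(Xs @ model.W1 + model.b1)
    return H, H @ model.W2 + model.b2


def forward(model: NetworkModel, x: np.ndarray) -> np.ndarray:
    """Forecast in mg/dL for one input vector or a matrix of vectors.

    Pure function of (model, x): standardize, run the network, invert the
    target scaling, clamp to [40, 400] mg/dL.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != model.n_inputs:
        raise SchemaError(
            f"input has {X.shape[1]} features, model expects {model.n_inputs}"
        )
    Xs = (X - model.x_center) / model.x_scale
    _, out = _forward_scaled(model, Xs)
    pred = np.clip(out * model.y_scale + model.y_center, CLAMP_LO, CLAMP_HI)
    return pred[0] if single else pred


def loss_and_grad(model: NetworkModel, Xs: np.ndarray, Ys: np.ndarray
                  ) -> tuple[float, dict]:
    """MSE (mean over samples and outputs, scaled space) and its gradients."""
    n = Xs.shape[0]
    act, dact = _act(model.hidden_activation)
    H, out = _forward_scaled(model, Xs)
    R = out - Ys
    loss = float(np.mean(R ** 2))
    dOut = 2.0 * R / R.size
    gW2 = H.T @ dOut
    gb2 = dOut.sum(axis=0)
    dH = (dOut @ model.W2.T) * dact(H)
    gW1 = Xs.T @ dH
    gb1 = dH.sum(axis=0)
    return loss, {"W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2}


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.002
    momentum: float = 0.9
    max_epochs: int = 800
    batch_mode: str = "per-sample"  # or "full-batch"
    early_stop_patience: int = 100
    validation_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if not 0 <= self.momentum < 1:
            raise ConfigError("momentum must lie in [0, 1)")
        if self.max_epochs < 0:
            raise ConfigError("max_epochs must be non-negative")
        if self.batch_mode not in ("per-sample", "full-batch"):
            raise ConfigError(f"unknown batch_mode {self.batch_mode!r}")
        if not 0 <= self.validation_fraction <= 0.5:
            raise ConfigError("validation_fraction must lie in [0, 0.5]")


def train(model: NetworkModel, design: DesignMatrix, config: TrainConfig,
          val_design: DesignMatrix | None = None) -> tuple[NetworkModel, dict]:
    """Train by backpropagation with momentum; returns (model, history).

    By default the last ``validation_fraction`` of rows (time-ordered) is
    held out for early stopping; when training spans several patients a
    caller can instead pass ``val_design`` (e.g. the tail of every training
    patient) and all of ``design`` is then used for fitting.  The returned
    model carries the weights achieving the best validation MSE.  Scalings
    come from the fitting rows only.  Divergence (scaled-space loss above
    1e6 or non-finite) aborts with a :class:`NumericalError` naming the
    epoch.
    """
    X = design.X.to_numpy(dtype=float)
    Y = design.Y.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 20:
        raise DataError(f"training needs at least 20 design rows, got {n}")
    if np.isnan(X).any() or np.isnan(Y).any():
        raise DataError("design matrix contains missing cells")
    if X.shape[1] != model.n_inputs or Y.shape[1] != model.n_outputs:
        raise SchemaError("design shape does not match the model's layer sizes")

    model = copy.deepcopy(model)
    model.input_names = design.column_names
    if val_design is not None:
        if val_design.column_names != design.column_names:
            raise SchemaError("validation design columns differ from training design")
        n_fit, n_val = n, len(val_design.X)
    else:
        n_val = int(round(config.validation_fraction * n))
        n_fit = n - n_val

    model.x_center = X[:n_fit].mean(axis=0)
    scale = X[:n_fit].std(axis=0)
    model.x_scale = np.where(scale < 1e-12, 1.0, scale)
    model.y_center = float(Y[:n_fit].mean())
    y_scale = float(Y[:n_fit].std())
    model.y_scale = y_scale if y_scale > 1e-12 else 1.0

    Xs = (X - model.x_center) / model.x_scale
    Ys = (Y - model.y_center) / model.y_scale
    Xf, Yf = Xs[:n_fit], Ys[:n_fit]
    if val_design is not None:
        Xv = (val_design.X.to_numpy(dtype=float) - model.x_center) / model.x_scale
        Yv = (val_design.Y.to_numpy(dtype=float) - model.y_center) / model.y_scale
    else:
        Xv, Yv = Xs[n_fit:], Ys[n_fit:]

    rng = np.random.default_rng(config.seed)
    vel = {k: np.zeros_like(v) for k, v in model.params().items()}
    history = {"train_mse": [], "val_mse": []}
    best = {k: v.copy() for k, v in model.params().items()}
    best_val = np.inf
    stale = 0

    def epoch_step() -> None:
        if config.batch_mode == "full-batch":
            _, grads = loss_and_grad(model, Xf, Yf)
            for k, v in vel.items():
                v *= config.momentum
                v -= config.learning_rate * grads[k]
            model.set_params({k: model.params()[k] + vel[k] for k in vel})
        else:
            for i in rng.permutation(n_fit):
                _, grads = loss_and_grad(model, Xf[i:i + 1], Yf[i:i + 1])
                for k, v in vel.items():
                    v *= config.momentum
                    v -= config.learning_rate * grads[k]
                model.set_params({k: model.params()[k] + vel[k] for k in vel})

    for epoch in range(config.max_epochs):
        epoch_step()
        train_mse, _ = loss_and_grad(model, Xf, Yf)
        if not np.isfinite(train_mse) or train_mse > 1e6:
            raise NumericalError(
                f"training diverged at epoch {epoch + 1} (scaled MSE {train_mse:.3g})"
            )
        if n_val > 0:
            val_mse, _ = loss_and_grad(model, Xv, Yv)
        else:
            val_mse = train_mse
        history["train_mse"].append(train_mse)
        history["val_mse"].append(val_mse)
        if val_mse < best_val - 1e-15:
            best_val = val_mse
            best = {k: v.copy() for k, v in model.params().items()}
            stale = 0
        else:
            stale += 1
            if config.early_stop_patience and stale >= config.early_stop_patience:
                break

    if config.max_epochs > 0:
        model.set_params(best)
    return model, history


@dataclass
class PredictionSet:
    """Per-origin 15-step forecasts paired with the actual future CGM values."""

    origins: pd.DatetimeIndex
    predicted: np.ndarray  # (n, steps), mg/dL
    actual: np.ndarray  # (n, steps), mg/dL

    def __post_init__(self) -> None:
        self.predicted = np.atleast_2d(np.asarray(self.predicted, dtype=float))
        self.actual = np.atleast_2d(np.asarray(self.actual, dtype=float))
        if self.predicted.shape != self.actual.shape:
            raise DataError("predicted and actual shapes differ")
        if len(self.origins) != self.predicted.shape[0]:
            raise DataError("origins length does not match prediction rows")

    @property
    def n_steps(self) -> int:
        return self.predicted.shape[1]

    @property
    def n_pairs(self) -> int:
        return int(self.predicted.size)

    def pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened (actual, predicted) pairs pooling all origins and steps."""
        return self.actual.ravel(), self.predicted.ravel()

    def to_frame(self) -> pd.DataFrame:
        steps = self.n_steps
        df = pd.DataFrame({"origin_timestamp": self.origins.strftime("%Y-%m-%dT%H:%M")})
        for k in range(steps):
            df[f"step_{k + 1}"] = self.predicted[:, k]
        for k in range(steps):
            df[f"actual_{k + 1}"] = self.actual[:, k]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PredictionSet":
        df = pd.read_csv(path)
        steps = sum(c.startswith("step_") for c in df.columns)
        origins = pd.DatetimeIndex(pd.to_datetime(df["origin_timestamp"]))
        pred = df[[f"step_{k + 1}" for k in range(steps)]].to_numpy(dtype=float)
        act = df[[f"actual_{k + 1}" for k in range(steps)]].to_numpy(dtype=float)
        return cls(origins, pred, act)

    @classmethod
    def concat(cls, sets: list["PredictionSet"]) -> "PredictionSet":
        if not sets:
            raise DataError("no prediction sets to concatenate")
        return cls(
            sets[0].origins.append([s.origins for s in sets[1:]]),
            np.vstack([s.predicted for s in sets]),
            np.vstack([s.actual for s in sets]),
        )


def predict_set(model: NetworkModel, design: DesignMatrix) -> PredictionSet:
    """One 15-step forecast per design row, paired with the y-block.

    Refuses with the differing column names if the design was assembled with
    a different input schema than the model was trained on.
    """
    if model.input_names is not None and design.column_names != model.input_names:
        missing = [c for c in model.input_names if c not in design.column_names]
        extra = [c for c in design.column_names if c not in model.input_names]
        raise SchemaError(
            f"design columns differ from the model's inputs "
            f"(missing {missing}, unexpected {extra})"
        )
    X = design.X.to_numpy(dtype=float)
    # row-at-a-time on purpose: the streaming replay engine evaluates one
    # origin per tick, and batched BLAS matmul sums in a different order, so
    # this is what makes stream and batch forecasts bit-identical
    pred = np.vstack([forward(model, row) for row in X])
    return PredictionSet(design.origins, pred, design.Y.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# Persistence (structured text, full precision)


def save_model(model: NetworkModel, path) -> None:
    doc = {
        "n_inputs": model.n_inputs, "n_hidden": model.n_hidden,
        "n_outputs": model.n_outputs,
        "hidden_activation": model.hidden_activation,
        "W1": model.W1.tolist(), "b1": model.b1.tolist(),
        "W2": model.W2.tolist(), "b2": model.b2.tolist(),
        "x_center": model.x_center.tolist(), "x_scale": model.x_scale.tolist(),
        "y_center": model.y_center, "y_scale": model.y_scale,
        "input_names": model.input_names,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> NetworkModel:
    with open(path) as fh:
        doc = json.load(fh)
    return NetworkModel(
        n_inputs=doc["n_inputs"], n_hidden=doc["n_hidden"],
        n_outputs=doc["n_outputs"], hidden_activation=doc["hidden_activation"],
        W1=np.array(doc["W1"]), b1=np.array(doc["b1"]),
        W2=np.array(doc["W2"]), b2=np.array(doc["b2"]),
        x_center=np.array(doc["x_center"]), x_scale=np.array(doc["x_scale"]),
        y_center=doc["y_center"], y_scale=doc["y_scale"],
        input_names=doc["input_names"],
    )


def model_digest(model: NetworkModel) -> str:
    """SHA-256 of the serialized model; used to assert weight immutability."""
    import hashlib
    import io

    buf = io.StringIO()
    json.dump({
        "W1": model.W1.tolist(), "b1": model.b1.tolist(),
        "W2": model.W2.tolist(), "b2": model.b2.tolist(),
        "x_center": model.x_center.tolist(), "x_scale": model.x_scale.tolist(),
        "y_center": model.y_center, "y_scale": model.y_scale,
    }, buf)
    return hashlib.sha256(buf.getvalue().encode()).hexdigest()
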