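"""The fully connected dual-output dihedral regressor.

A plain feed-forward network maps the one-hot window encoding
(420 inputs by default) through ReLU hidden layers (four layers of 713
units by default) to two linear outputs, the phi and psi angles in
degrees. Training minimizes the mean periodic absolute error
``AE = min(D, |360 - D|)`` over the batch and both outputs — the loss is
piecewise linear in the prediction, so its subgradient is simply the
sign of the wrapped residual. Optimization uses Adadelta (per-parameter
adaptive steps from running RMS of gradients and updates) with early
stopping on the validation loss and best-epoch weight restoration.

Everything here is deliberately framework-free numpy: the model is small
enough that explicit forward/backward passes stay readable and exactly
reproducible on one thread.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .geometry import absolute_angular_error, angular_error_sign, wrap_angle

__all__ = [
    "FCNN",
    "ModelConfig",
    "TrainingConfig",
    "build_model",
    "count_connection_weights",
    "load_model",
    "predict",
    "save_model",
    "train",
    "validation_mae",
]


@dataclass(frozen=True)
class ModelConfig:
    """Network topology: input width, hidden widths, dual linear output."""

    input_dim: int = 420
    hidden_widths: tuple[int, ...] = (713, 713, 713, 713)
    output_dim: int = 2

    def __post_init__(self) -> None:
        if self.input_dim < 1 or self.output_dim < 1:
            raise ValueError("input_dim and output_dim must be positive")
        if len(self.hidden_widths) == 0:
            raise ValueError("at least one hidden layer is required")
        if any(w < 1 for w in self.hidden_widths):
            raise ValueError(f"hidden widths must be positive, got {self.hidden_widths}")

    @property
    def layer_widths(self) -> tuple[int, ...]:
        return (self.input_dim, *self.hidden_widths, self.output_dim)


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings.

    ``learning_rate`` scales the Adadelta update (0.5 by default);
    ``rho``/``epsilon`` are the usual Adadelta accumulator decay and
    stabilizer. Training stops after ``early_stop_patience`` epochs
    without validation-loss improvement and restores the best epoch's
    weights.

    Because the periodic-MAE loss is piecewise linear, its subgradients
    do not shrink near an optimum; a subgradient method therefore needs
    diminishing steps to settle. ``plateau_decay`` multiplies the
    learning rate after ``plateau_patience`` consecutive epochs without
    validation improvement (reduce-on-plateau; a decay of 1.0 disables
    it).
    """

    learning_rate: float = 0.5
    rho: float = 0.95
    epsilon: float = 1e-6
    early_stop_patience: int = 4
    batch_size: int = 1024
    max_epochs: int = 200
    plateau_decay: float = 0.5
    plateau_patience: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.early_stop_patience < 1:
            raise ValueError("patience must be >= 1")


def count_connection_weights(config: ModelConfig) -> int:
    """Network size as the sum over adjacent layers of width products.

    Counts inter-layer connection weights only; biases are excluded.
    """
    widths = config.layer_widths
    return int(sum(a * b for a, b in zip(widths[:-1], widths[1:])))


class FCNN:
    """Weights, config and training history of the dihedral regressor."""

    def __init__(self, config: ModelConfig, weights: list[np.ndarray], biases: list[np.ndarray]):
        self.config = config
        self.weights = weights
        self.biases = biases
        self.history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
        self.best_epoch: Optional[int] = None
        self.trained = False

    def forward(self, x: np.ndarray, keep_activations: bool = False):
        """Linear output in degrees (unwrapped); optionally returns the
        per-layer ReLU activations for backprop."""
        acts = [x]
        h = x
        n_layers = len(self.weights)
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if i < n_layers - 1:
                np.maximum(h, 0.0, out=h)
            if keep_activations:
                acts.append(h)
        return (h, acts) if keep_activations else h


def build_model(config: ModelConfig = ModelConfig(), seed: int = 0) -> FCNN:
    """Initialize an untrained network with Glorot-uniform weights.

    Deterministic for a given seed: two builds with the same seed have
    identical initial weights.
    """
    rng = np.random.default_rng(seed)
    widths = config.layer_widths
    weights, biases = [], []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(np.float32))
        biases.append(np.zeros(fan_out, dtype=np.float32))
    return FCNN(config, weights, biases)


def _batch_loss_and_grad(model: FCNN, x: np.ndarray, y: np.ndarray):
    """Mean periodic AE over the batch and both outputs, and its
    subgradients with respect to every weight and bias."""
    pred, acts = model.forward(x, keep_activations=True)
    err = absolute_angular_error(pred, y)
    loss = float(err.mean())
    # dL/dpred: sign of the wrapped residual, averaged over batch x outputs
    delta = (angular_error_sign(pred, y) / err.size).astype(np.float32)
    grads_w, grads_b = [], []
    n_layers = len(model.weights)
    for i in range(n_layers - 1, -1, -1):
        grads_w.append(acts[i].T @ delta)
        grads_b.append(delta.sum(axis=0))
        if i > 0:
            delta = delta @ model.weights[i].T
            delta[acts[i] <= 0] = 0.0
    grads_w.reverse()
    grads_b.reverse()
    return loss, grads_w, grads_b


class _Adadelta:
    """Per-parameter adaptive steps from running RMS of gradients/updates."""

    def __init__(self, params: list[np.ndarray], lr: float, rho: float, eps: float):
        self.lr, self.rho, self.eps = lr, rho, eps
        self.acc_g = [np.zeros_like(p) for p in params]
        self.acc_dx = [np.zeros_like(p) for p in params]

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        for p, g, ag, ad in zip(params, grads, self.acc_g, self.acc_dx):
            ag *= self.rho
            ag += (1 - self.rho) * g * g
            dx = -np.sqrt((ad + self.eps) / (ag + self.eps)) * g
            ad *= self.rho
            ad += (1 - self.rho) * dx * dx
            p += self.lr * dx


def validation_mae(model: FCNN, x: np.ndarray, y: np.ndarray, batch_size: int = 8192):
    """(MAE(phi), MAE(psi)) in degrees over a dataset, batched."""
    err_sum = np.zeros(2)
    for start in range(0, x.shape[0], batch_size):
        xb = x[start : start + batch_size]
        pred = model.forward(np.asarray(xb, dtype=np.float32))
        err_sum += absolute_angular_error(pred, y[start : start + batch_size]).sum(axis=0)
    return tuple(err_sum / x.shape[0])


def train(
    model: FCNN,
    train_xy: tuple[np.ndarray, np.ndarray],
    val_xy: tuple[np.ndarray, np.ndarray],
    tc: TrainingConfig = TrainingConfig(),
    epoch_callback=None,
) -> FCNN:
    """Fit the network with Adadelta on the periodic-MAE loss.

    The validation loss recorded per epoch is MAE(phi) + MAE(psi); early
    stopping halts after ``tc.early_stop_patience`` consecutive epochs
    without improvement and the best epoch's weights are restored.
    ``epoch_callback(epoch, val_loss)`` is invoked after every epoch;
    returning True aborts training (used by the hyperparameter search's
    pruner).
    """
    x_train, y_train = train_xy
    x_val, y_val = val_xy
    if x_train.shape[0] == 0 or x_val.shape[0] == 0:
        raise ValueError("training and validation sets must be non-empty")
    if x_train.shape[1] != model.config.input_dim:
        raise ValueError(
            f"feature width {x_train.shape[1]} does not match model input_dim "
            f"{model.config.input_dim}"
        )
    x_train = np.ascontiguousarray(x_train, dtype=np.float32)
    y_train = np.ascontiguousarray(y_train, dtype=np.float32)
    rng = np.random.default_rng(tc.seed)
    params = model.weights + model.biases
    opt = _Adadelta(params, tc.learning_rate, tc.rho, tc.epsilon)

    best_val = np.inf
    best_state = None
    best_epoch = -1
    epochs_since_improvement = 0
    n = x_train.shape[0]
    for epoch in range(tc.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, tc.batch_size):
            idx = order[start : start + tc.batch_size]
            loss, gw, gb = _batch_loss_and_grad(model, x_train[idx], y_train[idx])
            opt.step(params, gw + gb)
            epoch_loss += loss * len(idx)
        val_phi, val_psi = validation_mae(model, x_val, y_val)
        val_loss = val_phi + val_psi
        model.history["train_loss"].append(epoch_loss / n)
        model.history["val_loss"].append(float(val_loss))
        if val_loss < best_val:
            best_val = val_loss
            best_state = ([w.copy() for w in model.weights], [b.copy() for b in model.biases])
            best_epoch = epoch
            epochs_since_improvement = 0
        else:
            epochs_since_improvement += 1
            if epochs_since_improvement % tc.plateau_patience == 0:
                opt.lr *= tc.plateau_decay
            if epochs_since_improvement >= tc.early_stop_patience:
                break
        if epoch_callback is not None and epoch_callback(epoch, float(val_loss)):
            break
    if best_state is not None:
        model.weights, model.biases = best_state
    model.best_epoch = best_epoch
    model.trained = True
    return model


def predict(model: FCNN, features: np.ndarray) -> np.ndarray:
    """Predicted (phi, psi) pairs in degrees, wrapped to [-180, 180).

    Deterministic given the weights; raises on an untrained model.
    """
    if not model.trained:
        raise RuntimeError("model has not been trained; call train() first")
    raw = model.forward(np.asarray(features, dtype=np.float32))
    return wrap_angle(raw.astype(float))


def save_model(model: FCNN, path) -> None:
    """Checkpoint to a single .npz: config JSON plus weight arrays."""
    payload = {
        "config": np.frombuffer(
            json.dumps(
                {**asdict(model.config), "trained": model.trained, "best_epoch": model.best_epoch,
                 "history": model.history}
            ).encode(),
            dtype=np.uint8,
        )
    }
    for i, (w, b) in enumerate(zip(model.weights, model.biases)):
        payload[f"w{i}"] = w
        payload[f"b{i}"] = b
    np.savez(Path(path), **payload)


def load_model(path) -> FCNN:
    """Load a checkpoint written by :func:`save_model`."""
    data = np.load(Path(path))
    meta = json.loads(bytes(data["config"].tobytes()).decode())
    config = ModelConfig(
        input_dim=meta["input_dim"],
        hidden_widths=tuple(meta["hidden_widths"]),
        output_dim=meta["output_dim"],
    )
    n_layers = len(config.layer_widths) - 1
    weights = [data[f"w{i}"] for i in range(n_layers)]
    biases = [data[f"b{i}"] for i in range(n_layers)]
    model = FCNN(config, weights, biases)
    model.trained = meta["trained"]
    model.best_epoch = meta["best_epoch"]
    model.history = meta["history"]
    return model
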