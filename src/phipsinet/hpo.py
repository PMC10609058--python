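"""Sequential model-based search over network depth and width.

The search minimizes the summed validation loss MAE(phi) + MAE(psi)
over two integer dimensions — the hidden-layer count (1 to 5) and the
per-layer neuron count (26 to 840, i.e. one sixteenth to twice the 420
input features) — across a fixed trial budget (30 by default).

Sampling follows the tree-structured Parzen estimator idea: after a
random startup phase, observed trials are split at the gamma-quantile
of the objective into a "good" and a "bad" set; each dimension gets a
Gaussian Parzen mixture over each set, candidate points are drawn from
the good density, and the candidate maximizing the density ratio
l(x)/g(x) is evaluated next. A median-rule pruner aborts a trial whose
intermediate validation loss exceeds the median of earlier trials at
the same epoch.

All randomness is driven by one seed, so a study is exactly repeatable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .model import (
    FCNN,
    ModelConfig,
    TrainingConfig,
    build_model,
    count_connection_weights,
    train,
    validation_mae,
)

__all__ = [
    "SearchSpace",
    "TrialResult",
    "load_study",
    "loss_vs_size_table",
    "optimize",
    "save_study",
]


@dataclass(frozen=True)
class SearchSpace:
    """Ranges (inclusive) and budget of the architecture search."""

    n_layers: tuple[int, int] = (1, 5)
    width: tuple[int, int] = (26, 840)
    n_trials: int = 30
    max_epochs_per_trial: int = 15
    subsample: Optional[int] = None  # cap on training rows per trial

    def __post_init__(self) -> None:
        if self.n_layers[0] > self.n_layers[1] or self.width[0] > self.width[1]:
            raise ValueError("empty search range")
        if self.n_trials < 1:
            raise ValueError("need at least one trial")


@dataclass
class TrialResult:
    """One evaluated architecture and its objective."""

    number: int
    n_layers: int
    width: int
    objective: float  # validation MAE(phi) + MAE(psi), degrees; inf if pruned
    connection_weight_count: int
    pruned: bool
    epoch_losses: list[float] = field(default_factory=list)

    @property
    def config(self) -> ModelConfig:
        return ModelConfig(hidden_widths=(self.width,) * self.n_layers)


class _Parzen1D:
    """Gaussian mixture over observed integer values with a uniform prior
    component, truncated to [lo, hi]."""

    def __init__(self, obs: np.ndarray, lo: float, hi: float):
        self.obs = np.asarray(obs, dtype=float)
        self.lo, self.hi = lo, hi
        spread = hi - lo
        # wider kernels when few observations; never below 1 unit
        self.bw = max(1.0, spread / max(np.sqrt(len(self.obs)), 1.0) / 2.0)

    def sample(self, rng: np.random.Generator) -> int:
        if len(self.obs) == 0 or rng.random() < 1.0 / (len(self.obs) + 1):
            value = rng.uniform(self.lo, self.hi)
        else:
            center = rng.choice(self.obs)
            value = rng.normal(center, self.bw)
        return int(round(np.clip(value, self.lo, self.hi)))

    def log_pdf(self, x: float) -> float:
        uniform = 1.0 / (self.hi - self.lo + 1.0)
        if len(self.obs) == 0:
            return float(np.log(uniform))
        z = (x - self.obs) / self.bw
        kernel = np.exp(-0.5 * z * z) / (self.bw * np.sqrt(2 * np.pi))
        n = len(self.obs)
        density = (uniform + kernel.sum()) / (n + 1)
        return float(np.log(density + 1e-300))


def _tpe_suggest(
    rng: np.random.Generator,
    trials: list[TrialResult],
    space: SearchSpace,
    n_candidates: int = 24,
    gamma: float = 0.25,
) -> tuple[int, int]:
    completed = [t for t in trials if not t.pruned]
    if len(completed) < 2:
        return _random_suggest(rng, space)
    objectives = np.array([t.objective for t in completed])
    n_good = max(1, int(np.ceil(gamma * len(completed))))
    order = np.argsort(objectives)
    good = [completed[i] for i in order[:n_good]]
    bad = [completed[i] for i in order[n_good:]] or good

    suggestion = []
    for attr, (lo, hi) in (("n_layers", space.n_layers), ("width", space.width)):
        l_est = _Parzen1D(np.array([getattr(t, attr) for t in good]), lo, hi)
        g_est = _Parzen1D(np.array([getattr(t, attr) for t in bad]), lo, hi)
        candidates = [l_est.sample(rng) for _ in range(n_candidates)]
        scores = [l_est.log_pdf(c) - g_est.log_pdf(c) for c in candidates]
        suggestion.append(candidates[int(np.argmax(scores))])
    return suggestion[0], suggestion[1]


def _random_suggest(rng: np.random.Generator, space: SearchSpace) -> tuple[int, int]:
    return (
        int(rng.integers(space.n_layers[0], space.n_layers[1] + 1)),
        int(rng.integers(space.width[0], space.width[1] + 1)),
    )


def optimize(
    space: SearchSpace,
    train_xy: tuple[np.ndarray, np.ndarray],
    val_xy: tuple[np.ndarray, np.ndarray],
    seed: int = 0,
    tc: TrainingConfig = TrainingConfig(),
    n_startup_trials: int = 8,
) -> tuple[TrialResult, list[TrialResult]]:
    """Run the architecture search; returns (best trial, all trials).

    Each trial trains a fresh model (seeded from the study seed and the
    trial number) under the standard patience rule, capped at
    ``space.max_epochs_per_trial`` epochs and optionally on a row
    subsample. Raises if every trial was pruned.
    """
    rng = np.random.default_rng(seed)
    x_train, y_train = train_xy
    if space.subsample is not None and x_train.shape[0] > space.subsample:
        pick = rng.choice(x_train.shape[0], size=space.subsample, replace=False)
        x_train, y_train = x_train[pick], y_train[pick]

    trials: list[TrialResult] = []
    for number in range(space.n_trials):
        if number < n_startup_trials:
            n_layers, width = _random_suggest(rng, space)
        else:
            n_layers, width = _tpe_suggest(rng, trials, space)
        config = ModelConfig(hidden_widths=(width,) * n_layers)
        model = build_model(config, seed=seed * 100003 + number)
        trial_tc = TrainingConfig(
            learning_rate=tc.learning_rate,
            rho=tc.rho,
            epsilon=tc.epsilon,
            early_stop_patience=tc.early_stop_patience,
            batch_size=tc.batch_size,
            max_epochs=space.max_epochs_per_trial,
            seed=seed * 100003 + number,
        )
        epoch_losses: list[float] = []
        pruned = {"flag": False}

        def _pruner(epoch: int, val_loss: float) -> bool:
            epoch_losses.append(val_loss)
            if number < n_startup_trials or epoch < 1:
                return False
            prior = [
                t.epoch_losses[epoch] for t in trials if len(t.epoch_losses) > epoch
            ]
            if len(prior) < 3:
                return False
            if val_loss > float(np.median(prior)):
                pruned["flag"] = True
                return True
            return False

        train(model, (x_train, y_train), val_xy, trial_tc, epoch_callback=_pruner)
        if pruned["flag"]:
            objective = float("inf")
        else:
            mae_phi, mae_psi = validation_mae(model, val_xy[0].astype(np.float32), val_xy[1])
            objective = float(mae_phi + mae_psi)
        trials.append(
            TrialResult(
                number=number,
                n_layers=n_layers,
                width=width,
                objective=objective,
                connection_weight_count=count_connection_weights(config),
                pruned=pruned["flag"],
                epoch_losses=epoch_losses,
            )
        )

    completed = [t for t in trials if not t.pruned]
    if not completed:
        raise RuntimeError(
            "every trial was pruned; increase max_epochs_per_trial or the subsample"
        )
    best = min(completed, key=lambda t: t.objective)
    return best, trials


def loss_vs_size_table(trials: list[TrialResult]) -> pd.DataFrame:
    """Objective vs connection-weight count for completed trials,
    sorted by network size."""
    completed = [t for t in trials if not t.pruned]
    if not completed:
        raise ValueError("no completed trials")
    df = pd.DataFrame(
        {
            "connection_weight_count": [t.connection_weight_count for t in completed],
            "objective": [t.objective for t in completed],
            "n_layers": [t.n_layers for t in completed],
            "width": [t.width for t in completed],
        }
    )
    return df.sort_values("connection_weight_count", ignore_index=True)


def save_study(trials: list[TrialResult], path) -> None:
    """Persist a study as a JSON list of trial records."""
    Path(path).write_text(json.dumps([asdict(t) for t in trials], indent=1))


def load_study(path) -> list[TrialResult]:
    """Reload a study written by :func:`save_study`."""
    records = json.loads(Path(path).read_text())
    out = []
    for r in records:
        obj = r["objective"]
        r["objective"] = float("inf") if obj is None else float(obj)
        out.append(TrialResult(**r))
    return out
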