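"""Two-hidden-layer feed-forward networks and exhaustive hyperparameter search.

The model family is fixed: input (69 scaled variables) -> first hidden
layer (parametric rectified-linear, learned slope) -> second hidden
layer (rectified-linear) -> single sigmoid output.  For the selectivity
regression the target is min-max scaled to [0, 1] so the sigmoid head is
well-posed, trained under mean-absolute-error loss and inverse-
transformed at prediction time; the reliability (big-IDAC) classifier
trains the same head under binary cross-entropy and thresholds the
ensemble score at 0.5.

Tunable parameters form an exhaustive grid: weight initializer
(glorot / lecun / he, uniform variants), first hidden width (100, 200),
second hidden width (10, 20, 40) and optimizer (rmsprop, adamax,
adadelta, sgd) — 72 configurations.  For each configuration five
networks are trained, one per cross-validation fold, and their averaged
prediction on the held-out optimization set is scored by the composite
decision function; the winning configuration has the lowest (regression)
or highest (classification) decision value.

The networks are implemented directly on numpy: plain mini-batch
backpropagation with the optimizers' conventional default learning
rates.  All randomness (weight draws, batch shuffling) flows from the
integer seed in the training configuration.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import metrics

INITIALIZERS = ("glorot-uniform", "lecun-uniform", "he-uniform")
HIDDEN1_OPTIONS = (100, 200)
HIDDEN2_OPTIONS = (10, 20, 40)
OPTIMIZERS = ("rmsprop", "adamax", "adadelta", "sgd")


@dataclass(frozen=True)
class HyperParams:
    initializer: str
    n_hidden1: int
    n_hidden2: int
    optimizer: str

    def __post_init__(self) -> None:
        if self.initializer not in INITIALIZERS:
            raise ValueError(f"unknown initializer {self.initializer!r}")
        if self.n_hidden1 not in HIDDEN1_OPTIONS or self.n_hidden2 not in HIDDEN2_OPTIONS:
            raise ValueError("hidden-layer widths must come from the enumerated grid")
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


def full_grid() -> list[HyperParams]:
    """The exhaustive 3 x 2 x 3 x 4 = 72-configuration grid."""
    return [
        HyperParams(i, h1, h2, o)
        for i, h1, h2, o in itertools.product(
            INITIALIZERS, HIDDEN1_OPTIONS, HIDDEN2_OPTIONS, OPTIMIZERS
        )
    ]


def desk_grid() -> list[HyperParams]:
    """A reduced four-configuration grid spanning all tunable axes."""
    return [
        HyperParams("glorot-uniform", 100, 10, "adamax"),
        HyperParams("he-uniform", 200, 20, "rmsprop"),
        HyperParams("lecun-uniform", 100, 40, "sgd"),
        HyperParams("glorot-uniform", 200, 10, "adadelta"),
    ]


@dataclass
class TrainingConfig:
    task: str = "regression"  # or "bigidac"
    batch_size: int = 2000
    epochs: int = 500
    seed: int = 0
    prelu_init: float = 0.25

    def __post_init__(self) -> None:
        if self.task not in ("regression", "bigidac"):
            raise ValueError(f"unknown task {self.task!r}")

    @property
    def loss(self) -> str:
        return "mae" if self.task == "regression" else "bce"


def _init_weight(rng: np.random.Generator, fan_in: int, fan_out: int, kind: str) -> np.ndarray:
    if kind == "glorot-uniform":
        limit = math.sqrt(6.0 / (fan_in + fan_out))
    elif kind == "lecun-uniform":
        limit = math.sqrt(3.0 / fan_in)
    elif kind == "he-uniform":
        limit = math.sqrt(6.0 / fan_in)
    else:
        raise ValueError(f"unknown initializer {kind!r}")
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class _Optimizer:
    """Per-parameter state updaters with conventional default rates."""

    def __init__(self, kind: str):
        self.kind = kind
        self.t = 0
        self.state: dict[str, dict[str, np.ndarray]] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        eps = 1e-7
        for name, g in grads.items():
            p = params[name]
            s = self.state.setdefault(name, {})
            if self.kind == "sgd":
                p -= 0.01 * g
            elif self.kind == "rmsprop":
                acc = s.setdefault("acc", np.zeros_like(p))
                acc *= 0.9
                acc += 0.1 * g * g
                p -= 0.001 * g / (np.sqrt(acc) + eps)
            elif self.kind == "adamax":
                m = s.setdefault("m", np.zeros_like(p))
                u = s.setdefault("u", np.zeros_like(p))
                m *= 0.9
                m += 0.1 * g
                np.maximum(0.999 * u, np.abs(g), out=u)
                p -= (0.002 / (1 - 0.9 ** self.t)) * m / (u + eps)
            elif self.kind == "adadelta":
                acc = s.setdefault("acc", np.zeros_like(p))
                delta = s.setdefault("delta", np.zeros_like(p))
                acc *= 0.95
                acc += 0.05 * g * g
                update = np.sqrt(delta + eps) / np.sqrt(acc + eps) * g
                delta *= 0.95
                delta += 0.05 * update * update
                p -= update
            else:
                raise ValueError(f"unknown optimizer {self.kind!r}")


class MLP:
    """input -> PReLU hidden -> ReLU hidden -> sigmoid output."""

    def __init__(self, n_in: int, hp: HyperParams, rng: np.random.Generator, prelu_init: float = 0.25):
        self.hp = hp
        self.params: dict[str, np.ndarray] = {
            "W1": _init_weight(rng, n_in, hp.n_hidden1, hp.initializer),
            "b1": np.zeros(hp.n_hidden1),
            "alpha1": np.array(prelu_init),
            "W2": _init_weight(rng, hp.n_hidden1, hp.n_hidden2, hp.initializer),
            "b2": np.zeros(hp.n_hidden2),
            "W3": _init_weight(rng, hp.n_hidden2, 1, hp.initializer),
            "b3": np.zeros(1),
        }

    @property
    def n_in(self) -> int:
        return self.params["W1"].shape[0]

    def _forward(self, x: np.ndarray):
        p = self.params
        z1 = x @ p["W1"] + p["b1"]
        a1 = np.where(z1 > 0, z1, p["alpha1"] * z1)
        z2 = a1 @ p["W2"] + p["b2"]
        a2 = np.maximum(z2, 0.0)
        z3 = a2 @ p["W3"] + p["b3"]
        out = 1.0 / (1.0 + np.exp(-z3))
        return z1, a1, z2, a2, out

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.n_in:
            raise ValueError(f"expected {self.n_in} features, got {x.shape[1]}")
        return self._forward(x)[-1].ravel()

    def train_step(self, x: np.ndarray, t: np.ndarray, loss: str, opt: _Optimizer) -> float:
        n = x.shape[0]
        p = self.params
        z1, a1, z2, a2, out = self._forward(x)
        t = t.reshape(-1, 1)
        if loss == "mae":
            value = float(np.mean(np.abs(out - t)))
            dz3 = np.sign(out - t) / n * out * (1 - out)
        elif loss == "bce":
            clipped = np.clip(out, 1e-12, 1 - 1e-12)
            value = float(-np.mean(t * np.log(clipped) + (1 - t) * np.log(1 - clipped)))
            dz3 = (out - t) / n
        else:
            raise ValueError(f"unknown loss {loss!r}")
        grads: dict[str, np.ndarray] = {}
        grads["W3"] = a2.T @ dz3
        grads["b3"] = dz3.sum(axis=0)
        da2 = dz3 @ p["W3"].T
        dz2 = da2 * (z2 > 0)
        grads["W2"] = a1.T @ dz2
        grads["b2"] = dz2.sum(axis=0)
        da1 = dz2 @ p["W2"].T
        dz1 = da1 * np.where(z1 > 0, 1.0, p["alpha1"])
        grads["alpha1"] = np.array(np.sum(da1 * np.where(z1 > 0, 0.0, z1)))
        grads["W1"] = x.T @ dz1
        grads["b1"] = dz1.sum(axis=0)
        opt.step(p, grads)
        return value


def train_fold(
    features_scaled: np.ndarray,
    targets: np.ndarray,
    hp: HyperParams,
    cfg: TrainingConfig,
) -> MLP:
    """Train one network by mini-batch backpropagation; deterministic per seed.

    Regression targets must already be scaled into [0, 1] to match the
    sigmoid head; the ensemble wrapper handles the inverse transform.
    """
    x = np.atleast_2d(np.asarray(features_scaled, dtype=float))
    t = np.asarray(targets, dtype=float).ravel()
    if x.shape[0] == 0:
        raise ValueError("empty training data")
    if len(t) != x.shape[0]:
        raise ValueError("targets not aligned with features")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(t))):
        raise ValueError("non-finite training inputs")
    rng = np.random.default_rng(cfg.seed)
    model = MLP(x.shape[1], hp, rng, cfg.prelu_init)
    opt = _Optimizer(hp.optimizer)
    n = x.shape[0]
    for _ in range(cfg.epochs):
        perm = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            batch = perm[start : start + cfg.batch_size]
            model.train_step(x[batch], t[batch], cfg.loss, opt)
    return model


@dataclass
class FoldEnsemble:
    """Five fold networks sharing one configuration; predicts their mean."""

    models: list[MLP]
    task: str
    target_min: float = 0.0
    target_range: float = 1.0

    def predict_scores(self, features_scaled: np.ndarray) -> np.ndarray:
        """Mean raw sigmoid output across folds, in [0, 1]."""
        x = np.atleast_2d(np.asarray(features_scaled, dtype=float))
        return np.mean([m.predict(x) for m in self.models], axis=0)

    def predict(self, features_scaled: np.ndarray):
        """Regression: log10 S_inf scale.  Classification: (scores, flags)."""
        scores = self.predict_scores(features_scaled)
        if self.task == "regression":
            return scores * self.target_range + self.target_min
        return scores, scores >= 0.5


def ensemble_predict(ens: FoldEnsemble, features_scaled: np.ndarray):
    return ens.predict(features_scaled)


def train_ensemble(
    features_scaled: np.ndarray,
    targets: np.ndarray,
    folds: Sequence[tuple[np.ndarray, np.ndarray]],
    hp: HyperParams,
    cfg: TrainingConfig,
) -> FoldEnsemble:
    """One network per CV fold, fitted on the fold's fit partition.

    The regression target scaling is fitted on the whole training side
    (fit + validation) and shared by all folds, mirroring how the
    descriptor scaler is fitted.
    """
    x = np.atleast_2d(np.asarray(features_scaled, dtype=float))
    y = np.asarray(targets, dtype=float).ravel()
    if cfg.task == "regression":
        tmin, tmax = float(y.min()), float(y.max())
        trange = tmax - tmin
        if trange == 0:
            tmin, trange = tmin - 0.5, 1.0  # constant target sits at sigmoid 0.5
        t = (y - tmin) / trange
    else:
        tmin, trange = 0.0, 1.0
        t = y
    models = []
    for i, (fit_idx, _val_idx) in enumerate(folds):
        fold_cfg = TrainingConfig(
            task=cfg.task,
            batch_size=cfg.batch_size,
            epochs=cfg.epochs,
            seed=int(np.random.SeedSequence([cfg.seed, i]).generate_state(1)[0] % (2**31)),
            prelu_init=cfg.prelu_init,
        )
        models.append(train_fold(x[np.asarray(fit_idx, dtype=int)], t[np.asarray(fit_idx, dtype=int)], hp, fold_cfg))
    return FoldEnsemble(models=models, task=cfg.task, target_min=tmin, target_range=trange)


def grid_search(
    features_scaled: np.ndarray,
    targets: np.ndarray,
    folds: Sequence[tuple[np.ndarray, np.ndarray]],
    opt_features_scaled: np.ndarray,
    opt_targets: np.ndarray,
    opt_il_labels: Sequence[str],
    cfg: TrainingConfig,
    grid: Sequence[HyperParams] | None = None,
    opt_temperatures: Sequence[float] | None = None,
) -> tuple[HyperParams, FoldEnsemble, pd.DataFrame]:
    """Exhaustive search over the grid, scored on the optimization set.

    Returns the winning configuration, its trained fold ensemble, and a
    per-configuration report with every metric component and the decision
    value, so the argmin/argmax is externally auditable.  Ties are broken
    toward the smaller first then second hidden width.
    """
    grid = list(grid if grid is not None else full_grid())
    if not grid:
        raise ValueError("empty hyperparameter grid")
    if cfg.task == "regression" and opt_temperatures is None:
        raise ValueError("regression scoring needs optimization-set temperatures")
    rows = []
    ensembles = []
    for hp in grid:
        ens = train_ensemble(features_scaled, targets, folds, hp, cfg)
        row = {
            "initializer": hp.initializer,
            "n_hidden1": hp.n_hidden1,
            "n_hidden2": hp.n_hidden2,
            "optimizer": hp.optimizer,
            "seed": cfg.seed,
        }
        if cfg.task == "regression":
            pred = ens.predict(opt_features_scaled)
            m = metrics.RegressionMetrics.evaluate(
                opt_targets, pred, opt_temperatures, opt_il_labels
            )
            row.update(
                mae=m.mae, mae_per_il=m.mae_per_il, delta_cov=m.delta_cov,
                delta_range=m.delta_range, df=m.df,
            )
        else:
            _, flags = ens.predict(opt_features_scaled)
            m = metrics.ClassificationMetrics.evaluate(opt_targets, flags, opt_il_labels)
            row.update(
                sensitivity=m.sensitivity, specificity=m.specificity, ba=m.ba,
                acc=m.acc, acc_per_il=m.acc_per_il, df=m.df,
            )
        rows.append(row)
        ensembles.append(ens)
    report = pd.DataFrame(rows)
    sign = 1.0 if cfg.task == "regression" else -1.0
    order = sorted(
        range(len(grid)),
        key=lambda i: (sign * report["df"][i], grid[i].n_hidden1, grid[i].n_hidden2, i),
    )
    best = order[0]
    return grid[best], ensembles[best], report


def save_ensemble(ens: FoldEnsemble, directory) -> None:
    """Persist fold weights (npz per fold) plus a small JSON manifest."""
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "task": ens.task,
        "target_min": ens.target_min,
        "target_range": ens.target_range,
        "n_folds": len(ens.models),
        "hyperparams": [
            {
                "initializer": m.hp.initializer,
                "n_hidden1": m.hp.n_hidden1,
                "n_hidden2": m.hp.n_hidden2,
                "optimizer": m.hp.optimizer,
            }
            for m in ens.models
        ],
    }
    with open(directory / "ensemble.json", "w") as fh:
        json.dump(manifest, fh)
    for i, m in enumerate(ens.models):
        np.savez(directory / f"fold{i}.npz", **m.params)


def load_ensemble(directory) -> FoldEnsemble:
    import json
    from pathlib import Path

    directory = Path(directory)
    with open(directory / "ensemble.json") as fh:
        manifest = json.load(fh)
    models = []
    for i in range(manifest["n_folds"]):
        hp = HyperParams(**manifest["hyperparams"][i])
        data = np.load(directory / f"fold{i}.npz")
        model = MLP(data["W1"].shape[0], hp, np.random.default_rng(0))
        model.params = {k: data[k] for k in data.files}
        models.append(model)
    return FoldEnsemble(
        models=models,
        task=manifest["task"],
        target_min=manifest["target_min"],
        target_range=manifest["target_range"],
    )


def ci_of_mae(mae_values: Sequence[float], z: float = 1.96) -> tuple[float, float]:
    """Normal-theory confidence interval for a mean MAE across repeat models.

    mean +/- z * sd / sqrt(n) with the sample standard deviation;
    endpoints reported rounded to three decimals.
    """
    vals = np.asarray(mae_values, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least two MAE values")
    mean = vals.mean()
    half = z * vals.std(ddof=1) / math.sqrt(vals.size)
    return (round(float(mean - half), 3), round(float(mean + half), 3))
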