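"""Regression and classification metric suite with composite decision functions.

Selecting one model for a four-component mixture property needs more
than a single error number: a model can score a low pooled MAE by
nailing the most common ILs and temperatures while averaging away the
extremes.  The suite therefore combines

* MAE — pooled absolute error over all points,
* MAE per IL — per-extractant MAE averaged with equal weight per IL,
* delta Cov — |Cov(observed, T) - Cov(predicted, T)| (population, 1/n
  form), penalizing models that lose the temperature dependence,
* delta range — |range(observed) - range(predicted)|, penalizing models
  that shrink predictions toward the mean,

into the regression decision function Df = (MAE * MAE_IL * dCov *
dRange)^(1/4), a geometric mean so each metric contributes equally;
lower is better.  The reliability classifier is scored by balanced
accuracy BA = (sensitivity + specificity)/2 and per-IL accuracy,
combined as Df = sqrt(BA * Acc_IL); higher is better.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np


def _arrays(*vecs):
    out = [np.asarray(v, dtype=float) for v in vecs]
    n = {len(v) for v in out}
    if len(n) != 1:
        raise ValueError("input lengths differ")
    if out[0].size == 0:
        raise ValueError("empty input")
    return out


def mae(observed, predicted) -> float:
    """Mean absolute error over all data points."""
    x, y = _arrays(observed, predicted)
    return float(np.mean(np.abs(y - x)))


def mae_per_il(observed, predicted, il_labels) -> float:
    """Per-IL MAE averaged with equal weight per IL, not per point."""
    x, y = _arrays(observed, predicted)
    labels = np.asarray(il_labels)
    if len(labels) != len(x):
        raise ValueError("labels not aligned with values")
    groups = np.unique(labels)
    return float(np.mean([np.mean(np.abs(y[labels == g] - x[labels == g])) for g in groups]))


def delta_cov(observed, predicted, temperatures) -> float:
    """|Cov(observed, T) - Cov(predicted, T)|, population (1/n) covariance."""
    x, y, t = _arrays(observed, predicted, temperatures)
    cov_x = np.mean((x - x.mean()) * (t - t.mean()))
    cov_y = np.mean((y - y.mean()) * (t - t.mean()))
    return float(abs(cov_x - cov_y))


def delta_range(observed, predicted) -> float:
    """|range(observed) - range(predicted)|."""
    x, y = _arrays(observed, predicted)
    return float(abs((x.max() - x.min()) - (y.max() - y.min())))


def df_regression(mae_value: float, mae_il: float, dcov: float, drange: float) -> float:
    """Geometric mean (fourth root of the product) of the four error metrics."""
    parts = (mae_value, mae_il, dcov, drange)
    if any(p < 0 for p in parts):
        raise ValueError("metric components must be non-negative")
    return float(np.prod(parts) ** 0.25)


@dataclass
class RegressionMetrics:
    mae: float
    mae_per_il: float
    delta_cov: float
    delta_range: float
    df: float

    @classmethod
    def evaluate(cls, observed, predicted, temperatures, il_labels) -> "RegressionMetrics":
        m = mae(observed, predicted)
        m_il = mae_per_il(observed, predicted, il_labels)
        dc = delta_cov(observed, predicted, temperatures)
        dr = delta_range(observed, predicted)
        return cls(m, m_il, dc, dr, df_regression(m, m_il, dc, dr))


class ConfusionCounts(NamedTuple):
    tp: int
    tn: int
    fp: int
    fn: int


def confusion(observed_flags, predicted_flags) -> ConfusionCounts:
    """Confusion counts with flag=True as the positive class."""
    obs = np.asarray(observed_flags, dtype=bool)
    pred = np.asarray(predicted_flags, dtype=bool)
    if obs.shape != pred.shape:
        raise ValueError("input lengths differ")
    return ConfusionCounts(
        tp=int(np.sum(obs & pred)),
        tn=int(np.sum(~obs & ~pred)),
        fp=int(np.sum(~obs & pred)),
        fn=int(np.sum(obs & ~pred)),
    )


def sensitivity(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0:
        raise ValueError("no positive observations")
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    if c.tn + c.fp == 0:
        raise ValueError("no negative observations")
    return c.tn / (c.tn + c.fp)


def balanced_accuracy(c: ConfusionCounts) -> float:
    """Mean of sensitivity and specificity."""
    return (sensitivity(c) + specificity(c)) / 2


def accuracy(c: ConfusionCounts) -> float:
    total = c.tp + c.tn + c.fp + c.fn
    if total == 0:
        raise ValueError("empty confusion counts")
    return (c.tp + c.tn) / total


def acc_per_il(observed_flags, predicted_flags, il_labels) -> float:
    """Per-IL accuracy averaged with equal weight per IL."""
    obs = np.asarray(observed_flags, dtype=bool)
    pred = np.asarray(predicted_flags, dtype=bool)
    labels = np.asarray(il_labels)
    if not (len(obs) == len(pred) == len(labels)) or len(obs) == 0:
        raise ValueError("inputs empty or misaligned")
    groups = np.unique(labels)
    return float(np.mean([np.mean(obs[labels == g] == pred[labels == g]) for g in groups]))


def df_classification(ba: float, acc_il: float) -> float:
    """sqrt(BA * Acc_IL) — geometric mean; higher is better."""
    if not (0 <= ba <= 1 and 0 <= acc_il <= 1):
        raise ValueError("components must lie in [0, 1]")
    return float(np.sqrt(ba * acc_il))


@dataclass
class ClassificationMetrics:
    sensitivity: float
    specificity: float
    ba: float
    acc: float
    acc_per_il: float
    df: float

    @classmethod
    def evaluate(cls, observed_flags, predicted_flags, il_labels) -> "ClassificationMetrics":
        c = confusion(observed_flags, predicted_flags)
        # one-class data leaves the matching rate undefined rather than erroring
        sens = c.tp / (c.tp + c.fn) if c.tp + c.fn else float("nan")
        spec = c.tn / (c.tn + c.fp) if c.tn + c.fp else float("nan")
        ba = (sens + spec) / 2
        a_il = acc_per_il(observed_flags, predicted_flags, il_labels)
        df = df_classification(ba, a_il) if np.isfinite(ba) else float("nan")
        return cls(sens, spec, ba, accuracy(c), a_il, df)


@dataclass
class CategoricalMetrics:
    """Binarized reading of the regression output: is it a good extractant?"""

    acc: float
    sensitivity: float
    specificity: float
    ba: float
    ppv: float
    npv: float


#: default "good extractant" cutoff on log10 S_inf (selectivity >> 1)
GOOD_EXTRACTANT_THRESHOLD = 1.0


def categorize_regression(
    observed, predicted, threshold: float = GOOD_EXTRACTANT_THRESHOLD
) -> CategoricalMetrics:
    """Binarize both vectors at the threshold, then score the agreement."""
    x, y = _arrays(observed, predicted)
    c = confusion(x > threshold, y > threshold)
    # rates with an empty denominator (one-class data) are undefined, not errors
    ppv = c.tp / (c.tp + c.fp) if c.tp + c.fp else float("nan")
    npv = c.tn / (c.tn + c.fn) if c.tn + c.fn else float("nan")
    sens = c.tp / (c.tp + c.fn) if c.tp + c.fn else float("nan")
    spec = c.tn / (c.tn + c.fp) if c.tn + c.fp else float("nan")
    return CategoricalMetrics(
        acc=accuracy(c),
        sensitivity=sens,
        specificity=spec,
        ba=(sens + spec) / 2,
        ppv=ppv,
        npv=npv,
    )
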