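"""Optimization-set selection and cross-validation fold construction.

Hyperparameters are selected on an optimization set held out on an
IL-out basis: every data point of a selected ionic liquid leaves the
training data together (the individual cation or anion may still appear
on both sides, paired differently).  ILs are picked by their position in
descriptor space: compute all pairwise Euclidean distances between IL
descriptor vectors (cation block + anion block, unscaled), take each
IL's median distance to the others, and use the median of those medians
as a threshold.  The first 10% of ILs whose median lies above the
threshold (structurally unfamiliar) and the first 10% below it
(familiar) form the optimization set.

The remaining training data is split by five-fold random
cross-validation at the data-point level, with the validation fraction
set to 20, 50 or 80% and every point guaranteed to appear in at least
one validation partition.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

CV_FRACTIONS = (0.2, 0.5, 0.8)


@dataclass
class DistanceMatrix:
    il_codes: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.il_codes)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match code list")


@dataclass
class SplitPlan:
    optimization_ils: list[str]
    training_ils: list[str]
    threshold: float
    cv_fraction: float
    folds: list[tuple[np.ndarray, np.ndarray]]  # (fit, validation) point indices
    seed: int

    def to_json(self, path) -> None:
        payload = {
            "optimization_ils": list(self.optimization_ils),
            "training_ils": list(self.training_ils),
            "threshold": self.threshold,
            "cv_fraction": self.cv_fraction,
            "folds": [
                {"fit": np.asarray(f).tolist(), "validation": np.asarray(v).tolist()}
                for f, v in self.folds
            ],
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SplitPlan":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            optimization_ils=payload["optimization_ils"],
            training_ils=payload["training_ils"],
            threshold=payload["threshold"],
            cv_fraction=payload["cv_fraction"],
            folds=[
                (np.asarray(f["fit"], dtype=int), np.asarray(f["validation"], dtype=int))
                for f in payload["folds"]
            ],
            seed=payload["seed"],
        )


def il_distance_matrix(il_vectors: dict[str, np.ndarray]) -> DistanceMatrix:
    """Pairwise Euclidean distances between IL descriptor vectors."""
    codes = list(il_vectors)
    if len(codes) < 2:
        raise ValueError("need at least two ILs")
    lengths = {len(v) for v in il_vectors.values()}
    if len(lengths) != 1:
        raise ValueError("IL descriptor vectors have mismatched lengths")
    x = np.vstack([np.asarray(il_vectors[c], dtype=float) for c in codes])
    return DistanceMatrix(il_codes=codes, d=squareform(pdist(x)))


def per_il_medians(dm: DistanceMatrix) -> np.ndarray:
    """Median distance of each IL to all *other* ILs (self excluded)."""
    n = len(dm.il_codes)
    off = ~np.eye(n, dtype=bool)
    return np.array([np.median(dm.d[i][off[i]]) for i in range(n)])


def median_threshold(dm: DistanceMatrix) -> float:
    """Median of the per-IL median distances — the selection threshold."""
    if len(dm.il_codes) < 3:
        raise ValueError("need at least three ILs for a meaningful threshold")
    return float(np.median(per_il_medians(dm)))


def select_optimization_ils(
    dm: DistanceMatrix,
    thr: float,
    fraction: float = 0.10,
    order: str = "extreme",
) -> tuple[list[str], list[str]]:
    """Pick the optimization-set ILs on both sides of the threshold.

    Takes floor(fraction * N) ILs with median above the threshold and
    the same number below.  ``order="extreme"`` ranks eligible ILs by
    descending distance |median - thr| (most extreme first);
    ``order="input"`` keeps the distance-matrix order.
    """
    medians = per_il_medians(dm)
    k = int(np.floor(fraction * len(dm.il_codes)))
    above = [i for i, m in enumerate(medians) if m > thr]
    below = [i for i, m in enumerate(medians) if m < thr]
    if order == "extreme":
        keyfun = lambda i: (-abs(medians[i] - thr), dm.il_codes[i])
        above = sorted(above, key=keyfun)
        below = sorted(below, key=keyfun)
    elif order != "input":
        raise ValueError(f"unknown order {order!r}")
    if len(above) < k or len(below) < k:
        warnings.warn(
            f"fewer eligible ILs than requested ({len(above)} above, {len(below)} below, "
            f"wanted {k} each); taking all available",
            stacklevel=2,
        )
    chosen = set(above[:k]) | set(below[:k])
    optimization = [dm.il_codes[i] for i in sorted(chosen)]
    training = [c for i, c in enumerate(dm.il_codes) if i not in chosen]
    return optimization, training


def make_cv_folds(
    n_points: int, cv_fraction: float, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Five random (fit, validation) splits of the training points.

    At fraction 0.2 the validation partitions are a disjoint 5-fold
    partition.  At 0.5 / 0.8 each validation partition is an independent
    random draw of round(fraction * n) points; any point never drawn is
    swapped into the last fold for a point already covered elsewhere, so
    every point is validated at least once.  Deterministic given seed.
    """
    if cv_fraction not in CV_FRACTIONS:
        raise ValueError(f"cv_fraction must be one of {CV_FRACTIONS}")
    rng = np.random.default_rng(seed)
    all_idx = np.arange(n_points)
    if cv_fraction == 0.2:
        if n_points < 5:
            raise ValueError("too few points for five disjoint validation partitions")
        perm = rng.permutation(n_points)
        return [
            (np.sort(np.setdiff1d(all_idx, val)), np.sort(val))
            for val in np.array_split(perm, 5)
        ]
    m = int(round(cv_fraction * n_points))
    if m < 1 or n_points - m < 1:
        raise ValueError("dataset too small for the requested validation fraction")
    vals = [rng.choice(n_points, size=m, replace=False) for _ in range(5)]
    coverage = np.zeros(n_points, dtype=int)
    for val in vals:
        coverage[val] += 1
    last = set(vals[-1].tolist())
    for p in np.flatnonzero(coverage == 0):
        candidates = sorted(i for i in last if coverage[i] >= 2)
        if not candidates:
            raise ValueError("cannot repair validation coverage; dataset too small")
        out = candidates[rng.integers(len(candidates))]
        last.remove(out)
        last.add(int(p))
        coverage[out] -= 1
        coverage[p] += 1
    vals[-1] = np.array(sorted(last))
    return [(np.sort(np.setdiff1d(all_idx, val)), np.sort(val)) for val in vals]


def build_split_plan(
    il_vectors: dict[str, np.ndarray],
    point_il_codes: list[str],
    cv_fraction: float,
    seed: int,
    opt_fraction: float = 0.10,
    order: str = "extreme",
) -> SplitPlan:
    """Full plan: optimization ILs, training ILs, CV folds on training points.

    ``point_il_codes`` gives the IL code of each data point, aligned with
    the feature/dataset row order; fold indices refer to the positions of
    the training-side points within that row order.
    """
    dm = il_distance_matrix(il_vectors)
    thr = median_threshold(dm)
    optimization_ils, training_ils = select_optimization_ils(dm, thr, opt_fraction, order)
    training_set = set(training_ils)
    training_rows = np.array([i for i, c in enumerate(point_il_codes) if c in training_set])
    folds_local = make_cv_folds(len(training_rows), cv_fraction, seed)
    folds = [(training_rows[f], training_rows[v]) for f, v in folds_local]
    return SplitPlan(
        optimization_ils=optimization_ils,
        training_ils=training_ils,
        threshold=thr,
        cv_fraction=cv_fraction,
        folds=folds,
        seed=seed,
    )
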