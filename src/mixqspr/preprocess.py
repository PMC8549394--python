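"""Range scaling and the bounding-box applicability domain.

Descriptors (temperature included — it is one of the 69 variables) are
scaled linearly by their training-set range so every training value lies
in [0, 1], then rounded to one decimal, collapsing each variable onto
the 11-point grid {0.0, 0.1, ..., 1.0}.  The scaling coefficients fitted
on the training side are applied unchanged to optimization and test
rows, which may therefore fall outside [0, 1]; such rows are not
clipped — reliability is reported separately by the applicability
domain.

The applicability domain (AD) is a bounding box: the per-variable
[min, max] of the *unscaled* training descriptors.  A row is inside the
domain iff every variable lies within its training range, bounds
inclusive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass
class RangeScaler:
    """Per-variable min and range (max - min) fitted on training features."""

    mins: np.ndarray
    ranges: np.ndarray
    names: list[str]
    decimals: int = 1

    @property
    def constant_mask(self) -> np.ndarray:
        return self.ranges == 0

    @classmethod
    def fit(cls, features: np.ndarray, names: Sequence[str] | None = None, decimals: int = 1) -> "RangeScaler":
        x = np.atleast_2d(np.asarray(features, dtype=float))
        if x.shape[0] < 1:
            raise ValueError("need at least one training row")
        mins = x.min(axis=0)
        ranges = x.max(axis=0) - mins
        names = list(names) if names is not None else [f"x{i}" for i in range(x.shape[1])]
        if len(names) != x.shape[1]:
            raise ValueError("name count does not match variable count")
        return cls(mins=mins, ranges=ranges, names=names, decimals=decimals)

    def transform(self, features: np.ndarray) -> np.ndarray:
        """x' = round((x - min) / range, 1 decimal); constant columns -> 0."""
        x = np.atleast_2d(np.asarray(features, dtype=float))
        if x.shape[1] != len(self.mins):
            raise ValueError(
                f"expected {len(self.mins)} variables, got {x.shape[1]}"
            )
        safe = np.where(self.constant_mask, 1.0, self.ranges)
        z = (x - self.mins) / safe
        z[:, self.constant_mask] = 0.0
        # round-half-to-even, matching numpy; reproducible across platforms
        return np.round(z, self.decimals)

    def to_json(self, path) -> None:
        payload = {
            name: {"min": float(lo), "range": float(r)}
            for name, lo, r in zip(self.names, self.mins, self.ranges)
        }
        with open(path, "w") as fh:
            json.dump({"decimals": self.decimals, "variables": payload}, fh)

    @classmethod
    def from_json(cls, path) -> "RangeScaler":
        with open(path) as fh:
            payload = json.load(fh)
        names = list(payload["variables"])
        return cls(
            mins=np.array([payload["variables"][n]["min"] for n in names]),
            ranges=np.array([payload["variables"][n]["range"] for n in names]),
            names=names,
            decimals=payload.get("decimals", 1),
        )


@dataclass
class BoundingBoxAD:
    """Per-variable [min, max] of the unscaled training descriptors."""

    mins: np.ndarray
    maxs: np.ndarray
    names: list[str]

    @classmethod
    def fit(cls, features: np.ndarray, names: Sequence[str] | None = None) -> "BoundingBoxAD":
        x = np.atleast_2d(np.asarray(features, dtype=float))
        if x.shape[0] < 1:
            raise ValueError("need at least one training row")
        names = list(names) if names is not None else [f"x{i}" for i in range(x.shape[1])]
        if len(names) != x.shape[1]:
            raise ValueError("name count does not match variable count")
        return cls(mins=x.min(axis=0), maxs=x.max(axis=0), names=names)

    def contains(self, features: np.ndarray) -> np.ndarray:
        """Boolean per row: all variables within [min, max], inclusive.

        Variables constant in training (degenerate box edge) are skipped,
        mirroring their exclusion from the scaled representation.
        """
        x = np.atleast_2d(np.asarray(features, dtype=float))
        if x.shape[1] != len(self.mins):
            raise ValueError(f"expected {len(self.mins)} variables, got {x.shape[1]}")
        active = self.maxs > self.mins
        inside = (x >= self.mins) & (x <= self.maxs)
        return np.all(inside[:, active], axis=1) if active.any() else np.ones(x.shape[0], bool)

    def check(self, row: np.ndarray) -> bool:
        return bool(self.contains(np.atleast_2d(row))[0])

    def to_json(self, path) -> None:
        payload = {
            name: {"min": float(lo), "max": float(hi)}
            for name, lo, hi in zip(self.names, self.mins, self.maxs)
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "BoundingBoxAD":
        with open(path) as fh:
            payload = json.load(fh)
        names = list(payload)
        return cls(
            mins=np.array([payload[n]["min"] for n in names]),
            maxs=np.array([payload[n]["max"] for n in names]),
            names=names,
        )
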