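"""Combinatorial cation x anion library enumeration and virtual screening.

A screening run enumerates every cation-anion combination, drops the
combinations already explored experimentally (marked 'X' in the
plain-text combination matrix; 'O' means unexplored), predicts
log10 S_inf for the query mixture at the query temperature with the
trained regression ensemble, attaches the reliability (big-IDAC) flag
from the classifier and the applicability-domain verdict, and ranks the
candidates by predicted selectivity, best first.  Out-of-domain or
flagged candidates are reported, not silently removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ann_model import FoldEnsemble
from .chem_io import Component, DataPoint, IonicLiquid, component_index
from .descriptors import DescriptorCalculator, assemble_features
from .preprocess import BoundingBoxAD, RangeScaler


@dataclass
class CombinationMatrix:
    cations: list[str]
    anions: list[str]
    explored: np.ndarray  # bool, shape (len(cations), len(anions))

    def __post_init__(self) -> None:
        self.explored = np.asarray(self.explored, dtype=bool)
        if self.explored.shape != (len(self.cations), len(self.anions)):
            raise ValueError("explored grid shape does not match code lists")

    @property
    def n_combinations(self) -> int:
        return len(self.cations) * len(self.anions)

    @property
    def n_explored(self) -> int:
        return int(self.explored.sum())

    @property
    def explored_rate(self) -> float:
        return self.n_explored / self.n_combinations

    def candidates(self) -> list[IonicLiquid]:
        """Unexplored combinations, row-major order."""
        return [
            IonicLiquid(c, a)
            for i, c in enumerate(self.cations)
            for j, a in enumerate(self.anions)
            if not self.explored[i, j]
        ]


@dataclass
class ScreeningRecord:
    il_code: str
    predicted_log_selectivity: float
    big_idac_flag: bool
    big_idac_score: float
    in_ad: bool
    explored: bool = False


def enumerate_library(cations: Sequence[str], anions: Sequence[str]) -> list[IonicLiquid]:
    """All cation x anion combinations in deterministic row-major order."""
    if not cations or not anions:
        raise ValueError("cation and anion lists must be non-empty")
    return [IonicLiquid(c, a) for c in cations for a in anions]


def read_matrix(path) -> CombinationMatrix:
    """Read the tab-separated X/O grid (rows cations, columns anions)."""
    with open(path) as fh:
        lines = [line.rstrip("\n") for line in fh if line.strip()]
    if len(lines) < 2:
        raise ValueError("combination matrix needs a header and at least one row")
    header = lines[0].split("\t")
    anions = header[1:]
    cations, cells = [], []
    for line in lines[1:]:
        parts = line.split("\t")
        if len(parts) != len(anions) + 1:
            raise ValueError(f"ragged row in combination matrix: {line!r}")
        cations.append(parts[0])
        row = []
        for cell in parts[1:]:
            if cell not in ("X", "O"):
                raise ValueError(f"matrix cell must be X or O, got {cell!r}")
            row.append(cell == "X")
        cells.append(row)
    return CombinationMatrix(cations=cations, anions=anions, explored=np.array(cells, dtype=bool))


def write_matrix(matrix: CombinationMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join([""] + list(matrix.anions)) + "\n")
        for cat, row in zip(matrix.cations, matrix.explored):
            fh.write("\t".join([cat] + ["X" if v else "O" for v in row]) + "\n")


def screen(
    candidates: Iterable[IonicLiquid],
    solute_code: str,
    raffinate_code: str,
    temperature: float,
    reg_model: FoldEnsemble,
    clf_model: FoldEnsemble | None,
    scaler: RangeScaler,
    ad: BoundingBoxAD,
    components: Iterable[Component] | Mapping[tuple[str, str], Component],
) -> list[ScreeningRecord]:
    """Predict and rank candidate entrainers for one mixture and temperature.

    Returns one record per candidate, sorted by predicted log10 S_inf
    descending with ties broken lexicographically by IL code.
    """
    idx = components if isinstance(components, Mapping) else component_index(components)
    calc = DescriptorCalculator()
    candidates = list(candidates)
    if not candidates:
        return []
    rows = []
    for il in candidates:
        dp = DataPoint(
            il=il,
            solute_code=solute_code,
            raffinate_code=raffinate_code,
            temperature=temperature,
            log_selectivity=0.0,
        )
        rows.append(assemble_features(dp, idx, calc))
    raw = np.vstack(rows)
    scaled = scaler.transform(raw)
    preds = reg_model.predict(scaled)
    in_ad = ad.contains(raw)
    if clf_model is not None:
        scores, flags = clf_model.predict(scaled)
    else:
        scores = np.zeros(len(candidates))
        flags = np.zeros(len(candidates), dtype=bool)
    records = [
        ScreeningRecord(
            il_code=il.il_code,
            predicted_log_selectivity=float(p),
            big_idac_flag=bool(f),
            big_idac_score=float(s),
            in_ad=bool(a),
        )
        for il, p, f, s, a in zip(candidates, preds, flags, scores, in_ad)
    ]
    records.sort(key=lambda r: (-r.predicted_log_selectivity, r.il_code))
    return records


def records_to_frame(records: Sequence[ScreeningRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "il_code": r.il_code,
                "predicted_log10_S": r.predicted_log_selectivity,
                "big_idac_flag": r.big_idac_flag,
                "big_idac_score": r.big_idac_score,
                "in_ad": r.in_ad,
            }
            for r in records
        ]
    )
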