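"""Component and selectivity-table I/O.

An extraction data point is defined by five things: the ionic liquid
(cation + anion), the solute, the raffinate, and the temperature.  The
modeled property is the decimal-log selectivity at infinite dilution,

    log10 S_inf = log10(gamma_inf_raffinate / gamma_inf_solute),

where the gammas are infinite-dilution activity coefficients (IDACs) of
the two mixture components in the same solvent at the same temperature.
A "big IDAC" flag marks records whose high selectivity comes from
dividing one huge IDAC by another large one — the solvent dissolves
neither component well and the record is unreliable as an extraction
lead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

ROLES = ("cation", "anion", "solute", "raffinate")

#: default threshold on both IDACs above which a record is flagged unreliable
BIG_IDAC_THRESHOLD = 20.0


class ChemIOError(ValueError):
    """Raised for malformed components, tables or SMILES."""


@dataclass(frozen=True)
class Component:
    """A cation, anion, solute or raffinate with a standardized structure."""

    code: str
    role: str
    smiles: str
    formal_charge: int

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ChemIOError(f"invalid role {self.role!r} for component {self.code!r}")


@dataclass(frozen=True)
class IonicLiquid:
    cation_code: str
    anion_code: str

    @property
    def il_code(self) -> str:
        return f"{self.cation_code}_{self.anion_code}"


@dataclass
class DataPoint:
    """One (IL, solute, raffinate, T) record with its property values."""

    il: IonicLiquid
    solute_code: str
    raffinate_code: str
    temperature: float  # kelvin
    log_selectivity: float
    big_idac: bool = False

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ChemIOError(f"temperature must be positive (got {self.temperature})")
        if self.solute_code == self.raffinate_code:
            raise ChemIOError(f"solute and raffinate are both {self.solute_code!r}")
        if not math.isfinite(self.log_selectivity):
            raise ChemIOError("log selectivity must be finite")


def standardize_smiles(raw: str, role: str) -> str:
    """Canonicalize a SMILES for its role.

    Ions keep their explicit charges (they are the modeling subject);
    neutral roles are reduced to their largest neutral covalent fragment,
    dropping counter-ions or solvent fragments.  The output is RDKit
    canonical SMILES, so the operation is idempotent.
    """
    if role not in ROLES:
        raise ChemIOError(f"invalid role {role!r}")
    mol = Chem.MolFromSmiles(raw)
    if mol is None:
        raise ChemIOError(f"unparseable SMILES for role {role}: {raw!r}")
    if role in ("solute", "raffinate"):
        frags = Chem.GetMolFrags(mol, asMols=True)
        neutral = [f for f in frags if Chem.GetFormalCharge(f) == 0]
        if not neutral:
            raise ChemIOError(f"no neutral fragment in {role} SMILES {raw!r}")
        mol = max(neutral, key=lambda f: (f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)))
    charge = Chem.GetFormalCharge(mol)
    if role == "cation" and charge < 1:
        raise ChemIOError(f"cation {raw!r} has non-positive net charge {charge}")
    if role == "anion" and charge > -1:
        raise ChemIOError(f"anion {raw!r} has non-negative net charge {charge}")
    return Chem.MolToSmiles(mol)


def make_component(code: str, role: str, raw_smiles: str) -> Component:
    smi = standardize_smiles(raw_smiles, role)
    charge = Chem.GetFormalCharge(Chem.MolFromSmiles(smi))
    return Component(code=code, role=role, smiles=smi, formal_charge=charge)


def read_component_table(path) -> list[Component]:
    """Read a components CSV with columns code, role, smiles."""
    df = pd.read_csv(path, dtype=str)
    missing = {"code", "role", "smiles"} - set(df.columns)
    if missing:
        raise ChemIOError(f"components table missing columns: {sorted(missing)}")
    components: list[Component] = []
    seen: set[tuple[str, str]] = set()
    for row in df.itertuples(index=False):
        key = (row.role, row.code)
        if key in seen:
            raise ChemIOError(f"duplicate component code {row.code!r} for role {row.role!r}")
        seen.add(key)
        components.append(make_component(row.code, row.role, row.smiles))
    return components


def write_component_table(components: Iterable[Component], path) -> None:
    pd.DataFrame(
        [{"code": c.code, "role": c.role, "smiles": c.smiles} for c in components]
    ).to_csv(path, index=False)


def component_index(components: Iterable[Component]) -> dict[tuple[str, str], Component]:
    """Index components by (role, code)."""
    return {(c.role, c.code): c for c in components}


_TRUE = {"1", "true", "t", "yes", "y", "x"}
_FALSE = {"0", "false", "f", "no", "n", "o", ""}


def _parse_flag(value) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ChemIOError(f"cannot interpret big-IDAC flag value {value!r}")


def read_selectivity_table(path, components: Iterable[Component], *, celsius: bool = False) -> list[DataPoint]:
    """Read a selectivity CSV and resolve codes against the component table.

    Rows identical in (cation, anion, solute, raffinate, T) are merged:
    log10 S_inf by arithmetic mean, big-IDAC flags by OR (a conflicting
    flag is kept as a conservative warning).  ``celsius=True`` converts
    the temperature column to kelvin at read time.
    """
    idx = component_index(components)
    df = pd.read_csv(path)
    required = {"cation", "anion", "solute", "raffinate", "temperature_K", "log10_S"}
    missing = required - set(df.columns)
    if missing:
        raise ChemIOError(f"selectivity table missing columns: {sorted(missing)}")
    merged: dict[tuple, list] = {}
    order: list[tuple] = []
    for row in df.itertuples(index=False):
        for role, code in (
            ("cation", row.cation),
            ("anion", row.anion),
            ("solute", row.solute),
            ("raffinate", row.raffinate),
        ):
            if (role, str(code)) not in idx:
                raise ChemIOError(f"unknown {role} code {code!r}")
        temp = float(row.temperature_K) + (273.15 if celsius else 0.0)
        value = float(row.log10_S)
        if not math.isfinite(value):
            raise ChemIOError(f"non-finite log10 S for {row}")
        flag = _parse_flag(getattr(row, "big_idac", False))
        key = (str(row.cation), str(row.anion), str(row.solute), str(row.raffinate), temp)
        if key not in merged:
            merged[key] = [value, flag, 1]
            order.append(key)
        else:
            rec = merged[key]
            rec[0] += value
            rec[1] = rec[1] or flag
            rec[2] += 1
    points = []
    for key in order:
        cat, an, sol, raf, temp = key
        total, flag, count = merged[key]
        points.append(
            DataPoint(
                il=IonicLiquid(cat, an),
                solute_code=sol,
                raffinate_code=raf,
                temperature=temp,
                log_selectivity=total / count,
                big_idac=flag,
            )
        )
    return points


def write_selectivity_table(points: Iterable[DataPoint], path) -> None:
    pd.DataFrame(
        [
            {
                "cation": p.il.cation_code,
                "anion": p.il.anion_code,
                "solute": p.solute_code,
                "raffinate": p.raffinate_code,
                "temperature_K": p.temperature,
                "log10_S": p.log_selectivity,
                "big_idac": p.big_idac,
            }
            for p in points
        ]
    ).to_csv(path, index=False)


def compute_log_selectivity(idac_solute: float, idac_raffinate: float) -> float:
    """log10 S_inf from the two infinite-dilution activity coefficients."""
    if idac_solute <= 0 or idac_raffinate <= 0:
        raise ChemIOError("IDACs must be positive")
    return math.log10(idac_raffinate / idac_solute)


def assign_big_idac(idac_solute: float, idac_raffinate: float, threshold: float = BIG_IDAC_THRESHOLD) -> bool:
    """Flag a record whose selectivity is a ratio of two large IDACs."""
    if idac_solute <= 0 or idac_raffinate <= 0:
        raise ChemIOError("IDACs must be positive")
    if threshold <= 0:
        raise ChemIOError("threshold must be positive")
    return idac_solute > threshold and idac_raffinate > threshold


def read_idac_table(path, components: Iterable[Component], *, threshold: float = BIG_IDAC_THRESHOLD) -> list[DataPoint]:
    """Read raw IDAC pairs and derive log10 S_inf and the big-IDAC flag."""
    idx = component_index(components)
    df = pd.read_csv(path)
    required = {"cation", "anion", "solute", "raffinate", "temperature_K", "idac_solute", "idac_raffinate"}
    missing = required - set(df.columns)
    if missing:
        raise ChemIOError(f"idac table missing columns: {sorted(missing)}")
    points = []
    for row in df.itertuples(index=False):
        for role, code in (
            ("cation", row.cation),
            ("anion", row.anion),
            ("solute", row.solute),
            ("raffinate", row.raffinate),
        ):
            if (role, str(code)) not in idx:
                raise ChemIOError(f"unknown {role} code {code!r}")
        points.append(
            DataPoint(
                il=IonicLiquid(str(row.cation), str(row.anion)),
                solute_code=str(row.solute),
                raffinate_code=str(row.raffinate),
                temperature=float(row.temperature_K),
                log_selectivity=compute_log_selectivity(float(row.idac_solute), float(row.idac_raffinate)),
                big_idac=assign_big_idac(float(row.idac_solute), float(row.idac_raffinate), threshold),
            )
        )
    return points
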