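"""Per-component molecular descriptors and 69-variable feature rows.

Each of the four mixture components (cation, anion, solute, raffinate)
contributes a fixed 17-descriptor vector mixing physico-chemical
character (logP, polar surface area, molar refractivity ...) and
structural features (rotatable bonds, aromatic atoms, rings ...); the
temperature in kelvin is the single non-molecular variable, giving
4 x 17 + 1 = 69 independent variables per data point.

The roster is configurable by name; descriptors are computed once per
unique standardized SMILES and cached, since a large selectivity table
reuses a few hundred components.
"""

from __future__ import annotations

from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, GraphDescriptors, Lipinski

from .chem_io import ROLES, Component, DataPoint, component_index


class DescriptorError(ValueError):
    """Raised when a descriptor cannot be computed for a structure."""


def _aromatic_atoms(mol) -> float:
    return float(sum(1 for a in mol.GetAtoms() if a.GetIsAromatic()))


def _atom_count(symbol: str) -> Callable:
    def count(mol) -> float:
        return float(sum(1 for a in mol.GetAtoms() if a.GetSymbol() == symbol))

    return count


def _topological_diameter(mol) -> float:
    # longest shortest path (in bonds) between any two heavy atoms
    if mol.GetNumAtoms() < 2:
        return 0.0
    return float(Chem.GetDistanceMatrix(mol).max())


def _balaban_j(mol) -> float:
    if mol.GetNumBonds() == 0:
        return 0.0
    return float(GraphDescriptors.BalabanJ(mol))


#: descriptor roster: name -> callable(mol) -> float, in fixed order
DESCRIPTOR_FUNCS: dict[str, Callable] = {
    "log_p": Crippen.MolLogP,
    "tpsa": Descriptors.TPSA,
    "molar_refractivity": Crippen.MolMR,
    "hbd_count": Lipinski.NumHDonors,
    "hba_count": Lipinski.NumHAcceptors,
    "rotatable_bonds": Lipinski.NumRotatableBonds,
    "aromatic_atoms": _aromatic_atoms,
    "ring_count": Descriptors.RingCount,
    "heavy_atoms": lambda m: float(m.GetNumHeavyAtoms()),
    "mol_weight": Descriptors.MolWt,
    "formal_charge": Chem.GetFormalCharge,
    "fraction_csp3": Descriptors.FractionCSP3,
    "heteroatom_count": Lipinski.NumHeteroatoms,
    "n_count": _atom_count("N"),
    "o_count": _atom_count("O"),
    "topological_diameter": _topological_diameter,
    "balaban_index": _balaban_j,
}

DESCRIPTOR_NAMES: tuple[str, ...] = tuple(DESCRIPTOR_FUNCS)

N_DESCRIPTORS = len(DESCRIPTOR_NAMES)
N_FEATURES = 4 * N_DESCRIPTORS + 1

TEMPERATURE_COLUMN = "temperature_K"


def feature_names(roster: Sequence[str] = DESCRIPTOR_NAMES) -> list[str]:
    """Column names of the assembled feature row, temperature last."""
    names = [f"{role}_{d}" for role in ROLES for d in roster]
    names.append(TEMPERATURE_COLUMN)
    return names


class DescriptorCalculator:
    """Computes and caches per-component descriptor vectors."""

    def __init__(self, roster: Sequence[str] = DESCRIPTOR_NAMES):
        unknown = set(roster) - set(DESCRIPTOR_FUNCS)
        if unknown:
            raise DescriptorError(f"unknown descriptors: {sorted(unknown)}")
        self.roster = tuple(roster)
        self._cache: dict[str, np.ndarray] = {}

    def compute(self, component: Component) -> np.ndarray:
        """Descriptor vector for one standardized component (cached)."""
        vec = self._cache.get(component.smiles)
        if vec is not None:
            return vec
        mol = Chem.MolFromSmiles(component.smiles)
        if mol is None:
            raise DescriptorError(f"unparseable SMILES for {component.code!r}")
        values = np.empty(len(self.roster))
        for i, name in enumerate(self.roster):
            try:
                values[i] = float(DESCRIPTOR_FUNCS[name](mol))
            except Exception as exc:  # structure-descriptor calculation failure
                raise DescriptorError(
                    f"descriptor {name!r} failed for component {component.code!r}: {exc}"
                ) from exc
        if not np.all(np.isfinite(values)):
            bad = [n for n, v in zip(self.roster, values) if not np.isfinite(v)]
            raise DescriptorError(f"non-finite descriptors {bad} for {component.code!r}")
        self._cache[component.smiles] = values
        return values


def compute_descriptors(component: Component, roster: Sequence[str] = DESCRIPTOR_NAMES) -> np.ndarray:
    return DescriptorCalculator(roster).compute(component)


def assemble_features(
    dp: DataPoint,
    components: Iterable[Component] | Mapping[tuple[str, str], Component],
    calculator: DescriptorCalculator | None = None,
) -> np.ndarray:
    """The 69-entry feature row: cation | anion | solute | raffinate | T."""
    calc = calculator or DescriptorCalculator()
    idx = components if isinstance(components, Mapping) else component_index(components)
    codes = {
        "cation": dp.il.cation_code,
        "anion": dp.il.anion_code,
        "solute": dp.solute_code,
        "raffinate": dp.raffinate_code,
    }
    blocks = []
    for role in ROLES:
        comp = idx.get((role, codes[role]))
        if comp is None:
            raise DescriptorError(f"no {role} component with code {codes[role]!r}")
        blocks.append(calc.compute(comp))
    return np.concatenate(blocks + [[dp.temperature]])


def featurize_dataset(
    points: Sequence[DataPoint],
    components: Iterable[Component],
    roster: Sequence[str] = DESCRIPTOR_NAMES,
) -> tuple[pd.DataFrame, list[DataPoint], int]:
    """Feature matrix for a dataset.

    Components whose descriptor computation fails have their dependent
    data points dropped; the drop count is returned so curation loss is
    visible rather than silent.
    """
    calc = DescriptorCalculator(roster)
    idx = component_index(components)
    rows, kept = [], []
    dropped = 0
    for dp in points:
        try:
            rows.append(assemble_features(dp, idx, calc))
        except DescriptorError:
            dropped += 1
            continue
        kept.append(dp)
    cols = feature_names(roster)
    if rows:
        df = pd.DataFrame(np.vstack(rows), columns=cols)
    else:
        df = pd.DataFrame(columns=cols)
    return df, kept, dropped


def il_descriptor_vectors(
    points: Sequence[DataPoint],
    components: Iterable[Component],
    roster: Sequence[str] = DESCRIPTOR_NAMES,
) -> dict[str, np.ndarray]:
    """Unscaled cation|anion descriptor vector per IL code, for splitting."""
    calc = DescriptorCalculator(roster)
    idx = component_index(components)
    vectors: dict[str, np.ndarray] = {}
    for dp in points:
        code = dp.il.il_code
        if code in vectors:
            continue
        cat = idx.get(("cation", dp.il.cation_code))
        an = idx.get(("anion", dp.il.anion_code))
        if cat is None or an is None:
            raise DescriptorError(f"unresolvable IL {code!r}")
        vectors[code] = np.concatenate([calc.compute(cat), calc.compute(an)])
    return vectors
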