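"""Self-contained synthetic fixtures for the whole pipeline.

Real selectivity compilations are external and enormous; this module
generates chemically valid stand-ins with planted, recoverable
structure so every pipeline stage can be exercised and verified offline:

* component rosters — singly charged cations built from quaternary
  ammonium / morpholinium / pyridinium cores with varied alkyl,
  hydroxyalkyl and methoxyalkyl chains; anions from a fixed list of
  common IL anions; neutral solutes and raffinates;
* a selectivity table over every (IL, mixture, temperature) combination
  whose noiseless truth is a smooth planted map of the 69 features —
  a linear form over the standardized descriptors plus one pairwise
  product term (mild nonlinearity a small network can capture), with
  additive Gaussian noise on top;
* per-record synthetic IDAC magnitudes, partly descriptor-driven, from
  which the big-IDAC reliability flag is derived by thresholding, with
  prevalence steered by ``big_idac_rate``;
* an explored/unexplored combination matrix.

Everything is deterministic given the spec's integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .chem_io import (
    BIG_IDAC_THRESHOLD,
    Component,
    DataPoint,
    IonicLiquid,
    assign_big_idac,
    make_component,
    write_component_table,
    write_selectivity_table,
)
from .descriptors import featurize_dataset
from .screening import CombinationMatrix, write_matrix

_CATION_CORES = (
    ("AM", "C[N+](C)(C){chain}"),  # trimethyl-alkyl ammonium
    ("MO", "C[N+]1({chain})CCOCC1"),  # N-methyl-N-alkyl morpholinium
    ("PY", "c1cc[n+]({chain})cc1"),  # N-alkyl pyridinium
)
_CATION_CHAINS = ("C", "CC", "CCC", "CCCC", "CCCCC", "CCO", "CCCO", "CCOC")

_ANIONS = (
    ("CL", "[Cl-]"),
    ("BR", "[Br-]"),
    ("AC", "CC(=O)[O-]"),
    ("SCN", "[S-]C#N"),
    ("BF4", "[B-](F)(F)(F)F"),
    ("DCA", "N#C[N-]C#N"),
    ("NO3", "[O-][N+](=O)[O-]"),
    ("MS", "CS(=O)(=O)[O-]"),
    ("TFO", "[O-]S(=O)(=O)C(F)(F)F"),
    ("TS", "Cc1ccc(cc1)S(=O)(=O)[O-]"),
)

_NEUTRALS = (
    "c1ccccc1",  # benzene
    "CCCCCC",  # n-hexane
    "CCO",  # ethanol
    "Cc1ccccc1",  # toluene
    "C1CCCCC1",  # cyclohexane
    "CC(C)=O",  # acetone
    "Nc1ccccc1",  # aniline
    "CCCCCCCCCCCC",  # n-dodecane
    "c1ccncc1",  # pyridine
    "c1ccsc1",  # thiophene
    "CO",  # methanol
    "CC#N",  # acetonitrile
    "CCCCCCC",  # n-heptane
    "ClC(Cl)Cl",  # chloroform
)

#: default kelvin series, 288.15-368.15 K in 10 K steps
DEFAULT_TEMPERATURES = tuple(288.15 + 10.0 * k for k in range(9))


@dataclass
class SyntheticSpec:
    n_cations: int = 10
    n_anions: int = 6
    n_solutes: int = 3
    n_raffinates: int = 3
    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES
    noise_sd: float = 0.1
    big_idac_rate: float = 0.1
    truth_span: tuple[float, float] = (-0.5, 3.5)  # planted log10 S_inf range
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cations, self.n_anions, self.n_solutes, self.n_raffinates) < 2:
            raise ValueError("component counts must be at least 2")
        if self.n_cations > len(_CATION_CORES) * len(_CATION_CHAINS):
            raise ValueError("cation vocabulary exhausted")
        if self.n_anions > len(_ANIONS):
            raise ValueError("anion vocabulary exhausted")
        if self.n_solutes + self.n_raffinates > len(_NEUTRALS):
            raise ValueError("neutral vocabulary exhausted")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.big_idac_rate <= 1:
            raise ValueError("big_idac_rate must lie in [0, 1]")


def generate_components(spec: SyntheticSpec) -> list[Component]:
    """Deterministic component roster; every entry passes standardization."""
    components: list[Component] = []
    k = 0
    for chain in _CATION_CHAINS:
        for prefix, template in _CATION_CORES:
            if k >= spec.n_cations:
                break
            k += 1
            components.append(
                make_component(f"{prefix}-{chain}", "cation", template.format(chain=chain))
            )
    for code, smi in _ANIONS[: spec.n_anions]:
        components.append(make_component(code, "anion", smi))
    for i, smi in enumerate(_NEUTRALS[: spec.n_solutes]):
        components.append(make_component(f"SOL{i + 1}", "solute", smi))
    for i, smi in enumerate(_NEUTRALS[spec.n_solutes : spec.n_solutes + spec.n_raffinates]):
        components.append(make_component(f"RAF{i + 1}", "raffinate", smi))
    return components


def _enumerate_points(spec: SyntheticSpec, components: list[Component]) -> list[DataPoint]:
    cations = [c.code for c in components if c.role == "cation"]
    anions = [c.code for c in components if c.role == "anion"]
    solutes = [c.code for c in components if c.role == "solute"]
    raffinates = [c.code for c in components if c.role == "raffinate"]
    return [
        DataPoint(
            il=IonicLiquid(cat, an),
            solute_code=sol,
            raffinate_code=raf,
            temperature=t,
            log_selectivity=0.0,
        )
        for cat in cations
        for an in anions
        for sol in solutes
        for raf in raffinates
        for t in spec.temperatures
    ]


def generate_dataset(
    spec: SyntheticSpec, components: list[Component]
) -> tuple[list[DataPoint], pd.DataFrame]:
    """Selectivity table plus the hidden truth table.

    The noiseless planted value is an affine rescaling of
    ``Z w + c * Z_p Z_q`` (Z = column-standardized features) onto
    ``truth_span``; observed log10 S_inf adds N(0, noise_sd) noise.
    Synthetic IDAC magnitudes place log10(IDAC_solute) around a base
    level calibrated so that roughly ``big_idac_rate`` of records have
    both IDACs above the reliability threshold; IDAC_raffinate follows
    from the observed selectivity.
    """
    points = _enumerate_points(spec, components)
    features, kept, dropped = featurize_dataset(points, components)
    if dropped:
        raise RuntimeError(f"{dropped} synthetic points failed featurization")
    x = features.to_numpy(dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd

    rng = np.random.default_rng(spec.seed)
    w = rng.normal(size=z.shape[1])
    p, q = rng.choice(z.shape[1], size=2, replace=False)
    c_int = rng.normal()
    g = z @ w + c_int * z[:, p] * z[:, q]
    lo, hi = spec.truth_span
    span = g.max() - g.min()
    truth = (g - g.min()) / span * (hi - lo) + lo if span > 0 else np.full_like(g, (lo + hi) / 2)
    noise = rng.normal(scale=spec.noise_sd, size=len(truth)) if spec.noise_sd > 0 else 0.0
    observed = truth + noise

    # descriptor-driven component of the planted IDAC magnitude
    w2 = rng.normal(size=z.shape[1])
    h = z @ w2
    h_sd = h.std()
    h = 0.4 * (h - h.mean()) / (h_sd if h_sd > 0 else 1.0)
    idac_noise = rng.normal(scale=0.3, size=len(truth))
    total_sd = np.hypot(0.4, 0.3)
    base = np.log10(BIG_IDAC_THRESHOLD) + total_sd * norm.ppf(spec.big_idac_rate)
    log_idac_solute = base + h + idac_noise
    idac_solute = 10.0**log_idac_solute
    idac_raffinate = 10.0 ** (log_idac_solute + observed)

    rows = []
    for dp, t_val, o_val, s_idac, r_idac in zip(kept, truth, observed, idac_solute, idac_raffinate):
        dp.log_selectivity = float(o_val)
        dp.big_idac = assign_big_idac(float(s_idac), float(r_idac))
        rows.append(
            {
                "cation": dp.il.cation_code,
                "anion": dp.il.anion_code,
                "solute": dp.solute_code,
                "raffinate": dp.raffinate_code,
                "temperature_K": dp.temperature,
                "log10_S_true": float(t_val),
                "log10_S": float(o_val),
                "idac_solute": float(s_idac),
                "idac_raffinate": float(r_idac),
                "big_idac": dp.big_idac,
            }
        )
    return kept, pd.DataFrame(rows)


def generate_matrix(spec: SyntheticSpec, explored_fraction: float) -> CombinationMatrix:
    """Explored/unexplored grid with round(fraction * cells) cells marked X."""
    if not 0 <= explored_fraction <= 1:
        raise ValueError("explored_fraction must lie in [0, 1]")
    cations = [f"{p}-{ch}" for ch in _CATION_CHAINS for p, _ in _CATION_CORES][: spec.n_cations]
    anions = [code for code, _ in _ANIONS[: spec.n_anions]]
    cells = len(cations) * len(anions)
    k = int(round(explored_fraction * cells))
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    chosen = rng.choice(cells, size=k, replace=False) if k else np.array([], dtype=int)
    explored = np.zeros(cells, dtype=bool)
    explored[chosen] = True
    return CombinationMatrix(
        cations=cations, anions=anions, explored=explored.reshape(len(cations), len(anions))
    )


def write_fixture_dir(spec: SyntheticSpec, outdir, explored_fraction: float = 0.048) -> dict[str, Path]:
    """Emit components.csv, selectivity.csv, idac.csv, truth.csv, combos.txt."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    components = generate_components(spec)
    points, truth = generate_dataset(spec, components)
    paths = {
        "components": outdir / "components.csv",
        "selectivity": outdir / "selectivity.csv",
        "idac": outdir / "idac.csv",
        "truth": outdir / "truth.csv",
        "combos": outdir / "combos.txt",
    }
    write_component_table(components, paths["components"])
    write_selectivity_table(points, paths["selectivity"])
    truth[
        ["cation", "anion", "solute", "raffinate", "temperature_K", "idac_solute", "idac_raffinate"]
    ].to_csv(paths["idac"], index=False)
    truth.to_csv(paths["truth"], index=False)
    write_matrix(generate_matrix(spec, explored_fraction), paths["combos"])
    return paths
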