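"""Closed-form thermodynamic and field arithmetic.

The Boltzmann inversion at the end of the pipeline: with cluster
populations P₁ and P₂ (total tuple weights) in equilibrium at temperature
T, the standard free-energy difference is

    ΔG⁰ = −R·T·ln(P₁ / P₂)      [J/mol]

so the more populated cluster lies lower in free energy. The module also
carries the field bookkeeping of the original simulation campaign: the
transmembrane potential ΔV = E_z · L_z across a box of height L_z, the
per-atom force F = q·E_z, and the thermal scale R·T.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

GAS_CONSTANT_J_PER_MOL_K = 8.314
#: 1 e·V/nm expressed in kJ/(mol·nm) — the Faraday constant in kJ/mol/V
EV_PER_NM_TO_KJ_PER_MOL_NM = 96.485


@dataclass
class ThermoConfig:
    temperature: float = 310.0  # K
    gas_constant: float = GAS_CONSTANT_J_PER_MOL_K  # J/(mol·K)

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise InvalidArgumentError("temperature must be > 0")
        if self.gas_constant <= 0:
            raise InvalidArgumentError("gas_constant must be > 0")


@dataclass
class FieldSpec:
    Ez: float  # V/nm
    Lz: float  # nm
    charge: float = 0.0  # elementary charges

    def __post_init__(self) -> None:
        if self.Lz <= 0:
            raise InvalidArgumentError("Lz must be > 0")


def delta_g(p1: float, p2: float, cfg: ThermoConfig | None = None) -> float:
    """Free-energy difference −RT·ln(p1/p2) in J/mol.

    Larger p1 gives a negative ΔG (cluster 1 more stable). Only the ratio
    of the populations matters.
    """
    cfg = cfg or ThermoConfig()
    if p1 <= 0 or p2 <= 0:
        raise InvalidArgumentError("populations must be positive")
    return float(-cfg.gas_constant * cfg.temperature * np.log(p1 / p2))


def free_energy_table(
    populations: Sequence[float] | Mapping[int, float],
    cfg: ThermoConfig | None = None,
) -> pd.DataFrame:
    """ΔG⁰ for every unordered cluster pair, in canonical cluster order.

    Clusters are numbered from 1 in the given order. Antisymmetry and
    additivity (ΔG₁₃ = ΔG₁₂ + ΔG₂₃) hold by construction of the log.
    """
    cfg = cfg or ThermoConfig()
    if isinstance(populations, Mapping):
        items = sorted(populations.items())
        names = [k for k, _ in items]
        pops = [v for _, v in items]
    else:
        pops = list(populations)
        names = list(range(1, len(pops) + 1))
    if len(pops) < 2:
        raise InvalidArgumentError("need at least 2 clusters")
    rows = [
        {
            "pair": f"{names[i]}-{names[j]}",
            "p1": pops[i],
            "p2": pops[j],
            "delta_g_J_per_mol": delta_g(pops[i], pops[j], cfg),
        }
        for i, j in combinations(range(len(pops)), 2)
    ]
    df = pd.DataFrame(rows)
    df.attrs["temperature_K"] = cfg.temperature
    df.attrs["gas_constant"] = cfg.gas_constant
    return df


def membrane_potential(Ez: float, Lz: float) -> float:
    """Transmembrane potential ΔV = Ez · Lz (V, with Ez in V/nm, Lz in nm)."""
    if Lz <= 0:
        raise InvalidArgumentError("Lz must be > 0")
    return Ez * Lz


def field_force(q: float, Ez: float, unit: str = "kJ/mol/nm") -> float:
    """Force q·Ez on a charge of ``q`` elementary charges in a field Ez (V/nm).

    ``unit="eV/nm"`` returns the bare product; ``unit="kJ/mol/nm"``
    (default) converts with the Faraday constant, 1 e·V/nm =
    96.485 kJ/(mol·nm).
    """
    bare = q * Ez
    if unit == "eV/nm":
        return bare
    if unit == "kJ/mol/nm":
        return bare * EV_PER_NM_TO_KJ_PER_MOL_NM
    raise InvalidArgumentError(f"unknown unit {unit!r}")


def thermal_noise(cfg: ThermoConfig | None = None) -> float:
    """The thermal energy scale R·T in kJ/mol."""
    cfg = cfg or ThermoConfig()
    return cfg.gas_constant * cfg.temperature / 1000.0


def write_free_energy_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """`free_energy.tsv` with a metadata header comment."""
    with open(path, "w") as fh:
        fh.write(
            f"# temperature_K={table.attrs.get('temperature_K')} "
            f"gas_constant={table.attrs.get('gas_constant')}\n"
        )
        table.to_csv(fh, sep="\t", index=False, float_format="%.10g")
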