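"""Stoichiometry of lipid-coated droplets and vesicle suspensions.

Two bookkeeping calculations connect the experimental geometry to molecular
ratios:

* For a lone aqueous droplet in lipid-in-oil solution, the droplet surface
  carries a lipid monolayer (4*pi*r^2 / A_L molecules) while an amphiphilic
  solute at concentration c is dissolved throughout the droplet volume
  (c * N_A * 4/3*pi*r^3 molecules).  Their ratio reduces to
  3 / (A_L * c * N_A * r): small droplets and dilute solute are lipid-rich.

* For a multilamellar-vesicle suspension mixed at a fixed lipid:solute mole
  ratio, the solute molarity follows from the lipid mass concentration and
  molar mass.
"""

from __future__ import annotations

from dataclasses import dataclass

from .constants import (A2_TO_M2, DOPC_AREA_PER_LIPID_A2, DOPC_MOLAR_MASS,
                        N_AVOGADRO, UM_TO_M)
from .exceptions import DomainError

__all__ = ["DropletSpec", "SuspensionSpec", "lipid_pfas_ratio",
           "suspension_pfas_molarity"]


@dataclass
class DropletSpec:
    """A monolayer-coated droplet holding dissolved amphiphile."""

    diameter_um: float = 100.0
    area_per_lipid_A2: float = DOPC_AREA_PER_LIPID_A2
    pfas_conc_mM: float = 0.1

    def __post_init__(self):
        if self.diameter_um <= 0 or self.area_per_lipid_A2 <= 0:
            raise DomainError("diameter and area per lipid must be positive")
        if self.pfas_conc_mM < 0:
            raise DomainError("concentration must be non-negative")


@dataclass
class SuspensionSpec:
    """A vesicle suspension mixed at a fixed lipid:solute mole ratio."""

    lipid_mass_conc_mg_ml: float = 16.0
    lipid_molar_mass_g_mol: float = DOPC_MOLAR_MASS
    mole_ratio_lipid_to_pfas: float = 10.0

    def __post_init__(self):
        if min(self.lipid_mass_conc_mg_ml, self.lipid_molar_mass_g_mol,
               self.mole_ratio_lipid_to_pfas) <= 0:
            raise DomainError("all suspension parameters must be positive")


def lipid_pfas_ratio(spec: DropletSpec) -> float:
    """Monolayer lipid count over dissolved solute count for one droplet.

    Equals [4 pi r^2 / A_L] / [c N_A (4/3) pi r^3] = 3 / (A_L c N_A r) in
    coherent SI units (c in mol/m^3 = mM).
    """
    if spec.pfas_conc_mM == 0:
        raise DomainError("ratio is undefined at zero solute concentration")
    r_m = 0.5 * spec.diameter_um * UM_TO_M
    a_l = spec.area_per_lipid_A2 * A2_TO_M2
    c = spec.pfas_conc_mM  # mM == mol/m^3
    n_lipid = 4.0 * 3.141592653589793 * r_m ** 2 / a_l
    n_solute = c * N_AVOGADRO * (4.0 / 3.0) * 3.141592653589793 * r_m ** 3
    return n_lipid / n_solute


def suspension_pfas_molarity(spec: SuspensionSpec) -> float:
    """Solute molarity (mM) in a suspension mixed at the given lipid:solute
    mole ratio: (mass_conc / molar_mass) / ratio."""
    lipid_mM = spec.lipid_mass_conc_mg_ml / spec.lipid_molar_mass_g_mol * 1e3
    return lipid_mM / spec.mole_ratio_lipid_to_pfas
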