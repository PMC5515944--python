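"""One-dimensional serial-resistance model of mesophyll conductance.

CO2 entering the leaf crosses a gas phase (intercellular airspace) and a
liquid phase (cell wall -> plasmalemma -> cytosol -> chloroplast envelope ->
stroma).  The two phases combine as

    gm = 1 / ( 1/gias + R*Tk / (H * gliq) )

where the Henry-law factor R*Tk/H converts the liquid-phase conductance
(defined on a dissolved-CO2 basis) to the gas-phase mole-fraction basis.
The gas phase is

    gias = Da * fias / (dL_ias * zeta),     dL_ias = Tmes / 2

and each liquid component, per unit chloroplast-exposed area, is

    gi = Dw * p_i * gamma_i / dL_i

with p_i an effective porosity (< 1 only for the cell wall) and gamma_i a
diffusivity-reduction factor for cytosol and stroma.  Membranes (plasmalemma
and envelope) use a fixed conductance instead.  The liquid chain is summed
in series and scaled to leaf area by Sc:

    gliq = Sc / sum_i(1/gi).

Conductances in m s-1 convert to molar units via P/(R*Tk).

The partition of the total mesophyll resistance assigns the gas phase
l_ias = gm/gias and each liquid component l_i = gm*(R*Tk/H)/(gi*Sc); under
the series law these fractions sum to 1 exactly, which is the closure
identity tested throughout.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anatomy import LeafAnatomy
from .errors import DataValidationError, DomainError

__all__ = [
    "PhysicalConstants",
    "ConductancePartition",
    "gas_phase_conductance",
    "component_conductance",
    "gm_from_anatomy",
    "sensitivity_grid",
    "standard_sensitivity",
]

GAS_CONSTANT = 8.314  # J mol-1 K-1


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants of the diffusion model (SI units, defaults at 25 degC).

    da : gas-phase CO2 diffusivity (m^2 s-1)
    dw : liquid-phase CO2 diffusivity (m^2 s-1)
    zeta : gas-path tortuosity (>= 1, dimensionless)
    henry : Henry constant (Pa m^3 mol-1); R*Tk/henry ~ 0.84 at 25 degC
    g_pl / g_en : plasmalemma and chloroplast-envelope conductances (m s-1)
    gamma_cyt / gamma_str : diffusivity reduction in cytosol / stroma
    porosity_* : piecewise-linear effective cell-wall porosity vs Tcw (um)
    stroma_divisor : dL_str = Tstr / stroma_divisor (2 = mid-stroma carboxylation)
    """

    da: float = 1.51e-5
    dw: float = 1.79e-9
    zeta: float = 1.57
    henry: float = 2941.0
    tk: float = 298.15
    pressure: float = 101325.0
    g_pl: float = 0.0035
    g_en: float = 0.0035
    gamma_cw: float = 1.0
    gamma_cyt: float = 0.3
    gamma_str: float = 0.3
    porosity_tcw_lo: float = 0.1
    porosity_tcw_hi: float = 0.5
    porosity_lo: float = 1.0
    porosity_hi: float = 0.1
    wall_divisor: float = 1.0
    cytosol_divisor: float = 1.0
    stroma_divisor: float = 2.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise DataValidationError(f"physical constant {f.name} must be positive")
        if self.zeta < 1.0:
            raise DataValidationError("tortuosity zeta must be >= 1")
        if not 0.0 < self.porosity_hi <= self.porosity_lo <= 1.0:
            raise DataValidationError("porosity bounds must satisfy 0 < hi <= lo <= 1")

    def porosity(self, tcw_um: float) -> float:
        """Effective cell-wall porosity, declining linearly with wall thickness."""
        return float(
            np.interp(tcw_um, [self.porosity_tcw_lo, self.porosity_tcw_hi], [self.porosity_lo, self.porosity_hi])
        )

    def molar(self, g_ms):
        """Convert a conductance from m s-1 to mol m-2 s-1 at (P, Tk)."""
        return g_ms * self.pressure / (GAS_CONSTANT * self.tk)

    @property
    def henry_factor(self) -> float:
        """Dimensionless gas/liquid conversion R*Tk/H of the series law."""
        return GAS_CONSTANT * self.tk / self.henry


@dataclass
class ConductancePartition:
    """Component conductances and their fractional share of mesophyll resistance.

    Component conductances (gcw ... gstr) are m s-1 per unit
    chloroplast-exposed area; gias and gliq are m s-1 on a leaf-area basis;
    gm is reported both ways.  The fractions l_* sum to 1 to 1e-9.
    """

    gias_ms: float
    gias_mol: float
    gcw: float
    gpl: float
    gcyt: float
    gen: float
    gstr: float
    gliq_ms: float
    gm_ms: float
    gm_mol: float
    lias: float
    lcw: float
    lpl: float
    len_: float
    lcyt: float
    lstr: float

    @property
    def lp(self) -> float:
        """Combined membrane share (plasmalemma + envelope)."""
        return self.lpl + self.len_

    @property
    def fractions(self) -> dict[str, float]:
        return {"lias": self.lias, "lcw": self.lcw, "lp": self.lp, "lcyt": self.lcyt, "lstr": self.lstr}

    @property
    def liquid_fractions(self) -> dict[str, float]:
        """Liquid-phase shares renormalised to the liquid phase only."""
        tot = self.lcw + self.lpl + self.len_ + self.lcyt + self.lstr
        return {"lcw": self.lcw / tot, "lp": self.lp / tot, "lcyt": self.lcyt / tot, "lstr": self.lstr / tot}


def gas_phase_conductance(fias: float, tmes_um: float, pc: PhysicalConstants) -> float:
    """Gas-phase conductance gias = Da*fias/(dL_ias*zeta), m s-1.

    The gas diffusion path dL_ias is half the mesophyll thickness.
    """
    if not 0.0 < fias < 1.0:
        raise DomainError("fias must lie strictly between 0 and 1")
    if tmes_um <= 0:
        raise DomainError("mesophyll thickness must be positive")
    dl = tmes_um * 1e-6 / 2.0
    return pc.da * fias / (dl * pc.zeta)


def component_conductance(dw: float, p: float, gamma: float, dl_m: float) -> float:
    """Liquid-component conductance gi = Dw*p*gamma/dL, m s-1."""
    if dl_m <= 0:
        raise DomainError("diffusion path length must be positive")
    if dw <= 0 or p <= 0 or gamma <= 0:
        raise DomainError("Dw, porosity and gamma must be positive")
    return dw * p * gamma / dl_m


def gm_from_anatomy(an: LeafAnatomy, pc: PhysicalConstants | None = None) -> ConductancePartition:
    """Evaluate the full serial-resistance model for one leaf."""
    pc = pc or PhysicalConstants()
    for trait in ("fias", "tmes", "tcw", "tcyt", "tstr", "sc"):
        val = getattr(an, trait)
        if val is None or not np.isfinite(val) or val <= 0:
            raise DomainError(f"anatomical gm model needs a positive {trait}")

    gias = gas_phase_conductance(an.fias, an.tmes, pc)
    gcw = component_conductance(pc.dw, pc.porosity(an.tcw), pc.gamma_cw, an.tcw * 1e-6 / pc.wall_divisor)
    gcyt = component_conductance(pc.dw, 1.0, pc.gamma_cyt, an.tcyt * 1e-6 / pc.cytosol_divisor)
    gstr = component_conductance(pc.dw, 1.0, pc.gamma_str, an.tstr * 1e-6 / pc.stroma_divisor)
    comps = {"cw": gcw, "pl": pc.g_pl, "cyt": gcyt, "en": pc.g_en, "str": gstr}

    r_liq = sum(1.0 / g for g in comps.values())  # s m-1, chloroplast-area basis
    gliq = an.sc / r_liq  # m s-1, leaf-area basis
    hf = pc.henry_factor
    gm_ms = 1.0 / (1.0 / gias + hf / gliq)
    frac = {name: gm_ms * hf / (g * an.sc) for name, g in comps.items()}
    return ConductancePartition(
        gias_ms=gias,
        gias_mol=pc.molar(gias),
        gcw=gcw,
        gpl=pc.g_pl,
        gcyt=gcyt,
        gen=pc.g_en,
        gstr=gstr,
        gliq_ms=gliq,
        gm_ms=gm_ms,
        gm_mol=pc.molar(gm_ms),
        lias=gm_ms / gias,
        lcw=frac["cw"],
        lpl=frac["pl"],
        len_=frac["en"],
        lcyt=frac["cyt"],
        lstr=frac["str"],
    )


_SWEEPABLE = ("tcw", "tstr", "tcyt", "sc", "fias", "tmes")


def sensitivity_grid(base: LeafAnatomy, pc: PhysicalConstants | None = None, sweep: dict | None = None) -> pd.DataFrame:
    """Evaluate modelled gm over a grid of one or two varied anatomical traits.

    ``sweep`` maps trait names (any of tcw, tstr, tcyt, sc, fias, tmes) to
    value arrays; all combinations are evaluated with the remaining traits
    held at ``base``.  Returns a long table with one gm_mol column.
    """
    pc = pc or PhysicalConstants()
    if not sweep or len(sweep) > 2:
        raise DomainError("sweep must vary one or two traits")
    for name in sweep:
        if name not in _SWEEPABLE:
            raise DomainError(f"cannot sweep unknown trait {name!r}")
    names = list(sweep)
    rows = []
    for combo in itertools.product(*(np.asarray(sweep[n], dtype=float) for n in names)):
        an = dataclasses.replace(base, **dict(zip(names, (float(v) for v in combo))))
        part = gm_from_anatomy(an, pc)
        row = dict(zip(names, (float(v) for v in combo)))
        row["gm_mol"] = part.gm_mol
        rows.append(row)
    return pd.DataFrame(rows, columns=names + ["gm_mol"])


def standard_sensitivity(base: LeafAnatomy, pc: PhysicalConstants | None = None, n: int = 25) -> dict[str, pd.DataFrame]:
    """One-trait sweeps over physiologically sensible ranges for each trait."""
    ranges = {
        "tcw": np.linspace(0.05, 0.6, n),
        "tstr": np.linspace(0.5, 4.0, n),
        "tcyt": np.linspace(0.03, 0.5, n),
        "sc": np.linspace(2.0, 12.0, n),
        "fias": np.linspace(0.05, 0.5, n),
    }
    return {name: sensitivity_grid(base, pc, {name: vals}) for name, vals in ranges.items()}
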