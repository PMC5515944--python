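"""Synthetic leaves: ground-truth generators for every pipeline stage.

A :class:`TrueLeaf` bundles the FvCB parameters, the true mesophyll and
stomatal conductances, the fluorescence calibration product, and the
anatomical ground truth of one leaf.  Generators emit gas-exchange /
fluorescence curve sets and per-section anatomy tables in the canonical
dialects, so every estimator in the package has a recovery test without any
external data.

CO2 response curves solve the coupled supply-demand system

    A = FvCB(Cc),   Cc = Ci - A/gm,   Ci = Ca - A/gs

by bracketed root finding at each CO2 setpoint.  Fluorescence is emitted
consistently with the operating electron transport rate, so the noiseless
variable-J round trip is exact.  Low-O2 calibration sets are generated with
a vanishing photorespiratory compensation point, which makes the
Phi_CO2 = alpha*beta * Phi_PSII/4 calibration line exact.  Laisk sets are
emitted as the tangent-line (exactly linear) low-Ci responses through the
true intersection (Ci*, -Rd), with per-irradiance slopes taken from the
RuBP-limited model slope at the compensation point.

Anatomy sections embody a minimal chloroplast-coverage mechanism:
chloroplasts are non-overlapping arcs on the airspace-facing cell perimeter
with appressed length proportional to the square root of their
cross-section area, so a few large chloroplasts cover less perimeter (lower
Sc) and leave a thicker cytosol sleeve (larger Tcyt) than many small ones
of the same total volume.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .anatomy import SectionMeasurement, aggregate_anatomy, mixed_curvature_factor
from .errors import DataValidationError, InsufficientDataError, SimulationError
from .fvcb import KineticConstants
from .gasx_io import CurveSet, GasExchangeRecord

__all__ = [
    "TrueLeaf",
    "NoiseModel",
    "NOISELESS",
    "REFERENCE_TRAITS",
    "make_preset",
    "simulate_aci",
    "simulate_light",
    "simulate_low_o2_calibration",
    "simulate_laisk_set",
    "simulate_anatomy",
    "chloroplast_contrast",
    "DEFAULT_CA_SERIES",
]

#: Reference-chamber CO2 setpoint protocol for CO2 response curves (umol mol-1).
DEFAULT_CA_SERIES = (400.0, 200.0, 150.0, 100.0, 50.0, 400.0, 600.0, 800.0, 1000.0)

#: PPFD protocol for light-response curves (umol m-2 s-1).
DEFAULT_LIGHT_SERIES = (700.0, 500.0, 300.0, 200.0, 150.0, 100.0, 50.0, 0.0)

#: Irradiances for the low-Ci (Laisk) curve family.
DEFAULT_LAISK_PPFDS = (50.0, 100.0, 200.0)

#: Published mean leaf traits of the four Arabidopsis lines (two wild-types
#: and their few-large-chloroplast arc mutants) used to seed the presets.
#: Units follow the package conventions (fluxes umol m-2 s-1, conductances
#: mol m-2 s-1, CO2 umol mol-1, lengths um, areas um^2, surfaces m2 m-2,
#: N g m-2; fias is a fraction).
REFERENCE_TRAITS: dict[str, dict[str, float]] = {
    "colwt": dict(a=7.69, gt=0.054, gs=0.085, gm_harley=0.152, gm_ethier=0.132, gm_anatomy=0.111,
                  ci=292.0, cc=239.0, e=1.56, rd=1.61, gamma_star=41.3, j=56.0, vcmax=30.5,
                  jcmax=57.8, pnue=9.18, narea=0.847, lma=11.38, tleaf=80.1, tmes=68.4,
                  tcw=0.174, sm=9.02, sc=8.17, tcyt=0.100, tstr=1.98, chl_size=14.6,
                  pchl=44.3, fias=0.234, chl_number=100.0),
    "arc12": dict(a=3.86, gt=0.015, gs=0.049, gm_harley=0.022, gm_ethier=0.021, gm_anatomy=0.069,
                  ci=309.0, cc=132.0, e=0.92, rd=1.54, gamma_star=40.6, j=47.0, vcmax=29.8,
                  jcmax=52.7, pnue=5.06, narea=0.762, lma=11.85, tleaf=79.6, tmes=67.8,
                  tcw=0.181, sm=8.52, sc=5.26, tcyt=0.121, tstr=2.13, chl_size=198.2,
                  pchl=41.9, fias=0.199, chl_number=1.5),
    "wswt": dict(a=4.72, gt=0.049, gs=0.100, gm_harley=0.098, gm_ethier=0.097, gm_anatomy=0.087,
                 ci=341.0, cc=293.0, e=1.84, rd=1.37, gamma_star=39.5, j=33.7, vcmax=18.1,
                 jcmax=35.3, pnue=7.82, narea=0.604, lma=14.47, tleaf=81.1, tmes=71.3,
                 tcw=0.193, sm=7.77, sc=6.31, tcyt=0.097, tstr=1.81, chl_size=15.1,
                 pchl=31.8, fias=0.227, chl_number=83.0),
    "arc8": dict(a=3.32, gt=0.015, gs=0.039, gm_harley=0.028, gm_ethier=0.029, gm_anatomy=0.065,
                 ci=299.0, cc=172.0, e=0.96, rd=1.26, gamma_star=40.1, j=33.1, vcmax=18.0,
                 jcmax=38.9, pnue=5.42, narea=0.613, lma=12.93, tleaf=75.9, tmes=67.6,
                 tcw=0.199, sm=7.38, sc=5.48, tcyt=0.123, tstr=2.22, chl_size=34.4,
                 pchl=30.6, fias=0.246, chl_number=5.0),
}

#: Wild-type reference for each mutant line.
WILD_TYPE_OF = {"arc12": "colwt", "arc8": "wswt"}


@dataclass(frozen=True)
class TrueLeaf:
    """Ground-truth parameter bundle of one synthetic leaf.

    Gas exchange: vcmax, jcmax, rd (umol m-2 s-1), gamma_star (umol mol-1),
    gm, gs (mol m-2 s-1), alpha_beta, theta (light-response curvature).
    Anatomy (um, m2 m-2): fias, tmes, tcw, tcyt, tstr, sm, plus the
    chloroplast population (number per cell, cross-section area um^2) and
    the coverage-mechanism constants.
    """

    vcmax: float = 30.5
    jcmax: float = 57.8
    rd: float = 1.61
    gamma_star: float = 41.3
    gm: float = 0.152
    gs: float = 0.085
    alpha_beta: float = 0.45
    theta: float = 0.9
    fias: float = 0.234
    tmes: float = 68.4
    tcw: float = 0.174
    tcyt: float = 0.100
    tstr: float = 1.98
    sm: float = 9.02
    chloroplast_number: float = 100.0
    chloroplast_size: float = 14.6
    narea: float = 0.847
    # coverage mechanism: exposed perimeter per cell (um), appressed-length
    # shape factor (length = shape * sqrt(area)), maximum coverage, and the
    # cytosol thickening per unit uncovered perimeter (um)
    cell_perimeter: float = 60.0
    chl_shape: float = 1.2
    coverage_max: float = 0.95
    tcyt_gain: float = 0.08
    label: str = "leaf"

    def __post_init__(self) -> None:
        for name in ("vcmax", "jcmax", "gamma_star", "gm", "gs", "alpha_beta", "fias",
                     "tmes", "tcw", "tcyt", "tstr", "sm", "chloroplast_size", "narea"):
            if getattr(self, name) <= 0:
                raise DataValidationError(f"TrueLeaf.{name} must be positive")
        if self.chloroplast_number < 1:
            raise DataValidationError("chloroplast_number must be >= 1")
        if self.rd < 0:
            raise DataValidationError("rd must be non-negative")

    def kinetics(self, low_o2: bool = False) -> KineticConstants:
        if low_o2:
            return KineticConstants(o=15.0, gamma_star=1e-6)
        return KineticConstants(gamma_star=self.gamma_star)

    def j_at(self, ppfd: float) -> float:
        """Potential electron transport at ``ppfd`` (non-rectangular hyperbola)."""
        i2 = self.alpha_beta * ppfd
        if i2 <= 0:
            return 0.0
        s = i2 + self.jcmax
        return float((s - np.sqrt(s * s - 4.0 * self.theta * i2 * self.jcmax)) / (2.0 * self.theta))

    def coverage(self, size: float | None = None, number: float | None = None) -> float:
        """Fraction of the exposed cell perimeter appressed by chloroplasts.

        Saturating in total appressed length n*shape*sqrt(area): many small
        chloroplasts approach ``coverage_max``, a few large ones cover less.
        """
        a = self.chloroplast_size if size is None else size
        n = self.chloroplast_number if number is None else number
        demand = n * self.chl_shape * np.sqrt(a)
        return float(self.coverage_max * (1.0 - np.exp(-demand / (self.coverage_max * self.cell_perimeter))))

    @property
    def sc(self) -> float:
        """Chloroplast surface exposed to airspace implied by the coverage model."""
        return self.coverage() * self.sm

    @property
    def ci_star(self) -> float:
        """Apparent (intercellular-basis) CO2 compensation point."""
        return self.gamma_star - self.rd / self.gm


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description for the generators.

    Multiplicative Gaussian noise on fluxes and fluorescence, additive
    Gaussian on thicknesses (um), multiplicative on traced lengths/areas;
    everything truncated at physical bounds.
    """

    rel_a: float = 0.0
    rel_gs: float = 0.0
    rel_fluor: float = 0.0
    abs_thickness_um: float = 0.0
    rel_anatomy: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rel_a", "rel_gs", "rel_fluor", "abs_thickness_um", "rel_anatomy"):
            if getattr(self, name) < 0:
                raise DataValidationError(f"noise sd {name} must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def with_seed(self, seed: int) -> "NoiseModel":
        return dataclasses.replace(self, seed=seed)


NOISELESS = NoiseModel()

FMP_BASE = 2500.0  # arbitrary fluorometer units for the emitted Fm'


def make_preset(name: str) -> TrueLeaf:
    """Build the ground-truth leaf for one of the four study lines.

    Biochemistry, conductances and anatomy truth come from the published
    trait means; the fluorescence-derived gm (Harley/variable-J route)
    serves as the true mesophyll conductance.
    """
    try:
        t = REFERENCE_TRAITS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(REFERENCE_TRAITS)}") from None
    return TrueLeaf(
        vcmax=t["vcmax"], jcmax=t["jcmax"], rd=t["rd"], gamma_star=t["gamma_star"],
        gm=t["gm_harley"], gs=t["gs"], fias=t["fias"], tmes=t["tmes"], tcw=t["tcw"],
        tcyt=t["tcyt"], tstr=t["tstr"], sm=t["sm"], chloroplast_number=t["chl_number"],
        chloroplast_size=t["chl_size"], narea=t["narea"], label=name,
    )


# ----------------------------------------------------------- forward solver


def _solve_operating(leaf: TrueLeaf, ca: float, ppfd: float, k: KineticConstants):
    """Solve the coupled supply-demand system at one (Ca, PPFD) point.

    Returns (A, Ci, Cc, J_op) where J_op is the electron transport actually
    flowing: the RuBP-limited potential when RuBP-limited, otherwise the
    rate sustaining the Rubisco-limited carboxylation.
    """
    if ca <= 0:
        raise SimulationError("Ca setpoint must be positive")
    j_in = leaf.j_at(ppfd)
    r = 1.0 / leaf.gs + 1.0 / leaf.gm

    def demand(cc: float) -> float:
        wc = leaf.vcmax * (cc - k.gamma_star) / (cc + k.km)
        wj = j_in * (cc - k.gamma_star) / (4.0 * cc + 8.0 * k.gamma_star) if j_in > 0 else 0.0
        return min(wc, wj) - leaf.rd

    def f(a: float) -> float:
        cc = ca - a * r
        return demand(cc) - a

    a_lo, a_hi = -leaf.rd - 5.0, ca / r - 1e-9
    if f(a_lo) <= 0 or f(a_hi) >= 0:
        raise SimulationError(f"no physical operating point at Ca={ca}, PPFD={ppfd}")
    a = brentq(f, a_lo, a_hi, xtol=1e-12, rtol=1e-15)
    ci = ca - a / leaf.gs
    cc = ci - a / leaf.gm
    wc = leaf.vcmax * (cc - k.gamma_star) / (cc + k.km)
    wj = j_in * (cc - k.gamma_star) / (4.0 * cc + 8.0 * k.gamma_star) if j_in > 0 else 0.0
    if j_in > 0 and wc <= wj:
        j_op = 4.0 * leaf.vcmax * (cc + 2.0 * k.gamma_star) / (cc + k.km)
    else:
        j_op = j_in
    return float(a), float(ci), float(cc), float(j_op)


def _fluorescence_pair(j_op: float, ppfd: float, alpha_beta: float, rng, rel_fluor: float):
    """Emit an (Fs, Fm') pair consistent with J_op = Phi_PSII * PPFD * ab."""
    if ppfd <= 0:
        phi = 0.0
    else:
        phi = j_op / (ppfd * alpha_beta)
    if phi > 1.0 + 1e-9:
        raise SimulationError("operating electron transport exceeds the photon supply")
    phi = min(phi, 1.0)
    fmp = FMP_BASE
    fs = fmp * (1.0 - phi)
    if rel_fluor > 0.0:
        fmp = fmp * (1.0 + rel_fluor * rng.standard_normal())
        fs = fs * (1.0 + rel_fluor * rng.standard_normal())
        fmp = max(fmp, 1.0)
        fs = float(np.clip(fs, 0.0, fmp))
    return float(fs), float(fmp)


def _transpiration(gs: float) -> float:
    # nominal VPD of 1.1 kPa at ambient pressure; gs_water ~ 1.6 gs_CO2
    return 1.6 * gs * 1.1 / 101.325 * 1e3


def _emit(leaf, a, ci, ca, gs, ppfd, fs, fmp, o2):
    return GasExchangeRecord(a=a, ci=ci, ca=ca, gs=gs, e=_transpiration(gs), ppfd=ppfd,
                             tleaf=25.0, fs=fs, fmp=fmp, o2=o2)


# ------------------------------------------------------------- curve makers


def simulate_aci(leaf: TrueLeaf, ca_series=DEFAULT_CA_SERIES, ppfd: float = 300.0,
                 noise: NoiseModel = NOISELESS, replicate: str = "r1") -> CurveSet:
    """CO2 response curve with fluorescence; noiseless output satisfies the
    variable-J round trip exactly at every point."""
    if any(ca <= 0 for ca in ca_series):
        raise SimulationError("all Ca setpoints must be positive")
    rng = noise.rng()
    k = leaf.kinetics()
    records = []
    for ca in ca_series:
        a, ci, cc, j_op = _solve_operating(leaf, float(ca), ppfd, k)
        if noise.rel_a > 0.0:
            a = a * (1.0 + noise.rel_a * rng.standard_normal())
        gs = leaf.gs
        if noise.rel_gs > 0.0:
            gs = max(gs * (1.0 + noise.rel_gs * rng.standard_normal()), 1e-4)
        ci_obs = ca - a / gs
        fs, fmp = _fluorescence_pair(j_op, ppfd, leaf.alpha_beta, rng, noise.rel_fluor)
        records.append(_emit(leaf, a, ci_obs, float(ca), gs, ppfd, fs, fmp, 21.0))
    return CurveSet(kind="aci", genotype=leaf.label, replicate=replicate, records=records)


def simulate_light(leaf: TrueLeaf, ppfds=DEFAULT_LIGHT_SERIES, ca: float = 400.0,
                   noise: NoiseModel = NOISELESS, replicate: str = "r1") -> CurveSet:
    """Light-response curve at a fixed CO2 setpoint."""
    rng = noise.rng()
    k = leaf.kinetics()
    records = []
    for ppfd in ppfds:
        a, ci, cc, j_op = _solve_operating(leaf, ca, float(ppfd), k)
        if noise.rel_a > 0.0:
            a = a * (1.0 + noise.rel_a * rng.standard_normal())
        gs = leaf.gs
        if noise.rel_gs > 0.0:
            gs = max(gs * (1.0 + noise.rel_gs * rng.standard_normal()), 1e-4)
        fs, fmp = _fluorescence_pair(j_op, float(ppfd), leaf.alpha_beta, rng, noise.rel_fluor)
        records.append(_emit(leaf, a, ca - a / gs, ca, gs, float(ppfd), fs, fmp, 21.0))
    return CurveSet(kind="light", genotype=leaf.label, replicate=replicate, records=records)


def simulate_low_o2_calibration(leaf: TrueLeaf, ppfds=(50.0, 100.0, 150.0, 200.0, 300.0, 500.0),
                                ca: float = 400.0, noise: NoiseModel = NOISELESS,
                                replicate: str = "r1") -> CurveSet:
    """Light series under <2% O2 for the alpha*beta calibration.

    With a vanishing photorespiratory compensation point, gross uptake is
    exactly J/4 and the calibration regression is exact in the noiseless
    case.
    """
    rng = noise.rng()
    k = leaf.kinetics(low_o2=True)
    records = []
    for ppfd in ppfds:
        a, ci, cc, j_op = _solve_operating(leaf, ca, float(ppfd), k)
        if noise.rel_a > 0.0:
            a = a * (1.0 + noise.rel_a * rng.standard_normal())
        gs = leaf.gs
        if noise.rel_gs > 0.0:
            gs = max(gs * (1.0 + noise.rel_gs * rng.standard_normal()), 1e-4)
        fs, fmp = _fluorescence_pair(j_op, float(ppfd), leaf.alpha_beta, rng, noise.rel_fluor)
        records.append(_emit(leaf, a, ca - a / gs, ca, gs, float(ppfd), fs, fmp, 1.5))
    return CurveSet(kind="lowO2-calibration", genotype=leaf.label, replicate=replicate, records=records)


def simulate_laisk_set(leaf: TrueLeaf, ppfds=DEFAULT_LAISK_PPFDS,
                       ci_grid=(55.0, 80.0, 105.0, 130.0, 150.0),
                       noise: NoiseModel = NOISELESS) -> list[CurveSet]:
    """Low-Ci curve family whose common intersection is exactly (Ci*, -Rd).

    Each irradiance contributes the tangent-line response through the true
    intersection, with slope equal to the RuBP-limited supply-demand slope
    at the compensation point; fluorescence is omitted (the estimator uses
    only A and Ci).
    """
    ppfds = tuple(float(p) for p in ppfds)
    if len(set(ppfds)) < 2:
        raise InsufficientDataError("Laisk simulation needs >= 2 distinct irradiances")
    rng = noise.rng()
    curves = []
    for idx, ppfd in enumerate(ppfds):
        j = leaf.j_at(ppfd)
        s_cc = j / (12.0 * leaf.gamma_star)  # RuBP-limited dA/dCc at Cc = GammaStar
        slope = s_cc / (1.0 + s_cc / leaf.gm)  # drawdown through gm
        records = []
        for ci in ci_grid:
            a = slope * (float(ci) - leaf.ci_star) - leaf.rd
            if noise.rel_a > 0.0:
                a = a + abs(a if a != 0 else leaf.rd) * noise.rel_a * rng.standard_normal()
            gs = leaf.gs
            if noise.rel_gs > 0.0:
                gs = max(gs * (1.0 + noise.rel_gs * rng.standard_normal()), 1e-4)
            ca = float(ci) + a / gs
            records.append(GasExchangeRecord(a=a, ci=float(ci), ca=ca, gs=gs,
                                             e=_transpiration(gs), ppfd=ppfd, tleaf=25.0, o2=21.0))
        curves.append(CurveSet(kind="laisk", genotype=leaf.label, replicate=f"L{idx}", records=records))
    return curves


# ---------------------------------------------------------------- anatomy


def simulate_anatomy(leaf: TrueLeaf, n_sections: int = 5, noise: NoiseModel = NOISELESS,
                     section_width: float = 400.0, n_chl_measured: int = 8) -> list[SectionMeasurement]:
    """Per-section stereology measurements from the ground-truth leaf.

    Noiseless sections aggregate back to the generating fias, Sm and the
    coverage-model Sc exactly.  The cytosol sleeve thickens by
    ``tcyt_gain * (1 - coverage)``: sparsely covered (few-large-chloroplast)
    cells put more cytosol between plasmalemma and chloroplast envelope.
    """
    if n_sections < 1:
        raise InsufficientDataError("need at least one section")
    rng = noise.rng()
    f_eff = mixed_curvature_factor(0.98, 1.26, 0.5)
    sections = []
    for _ in range(n_sections):
        def jitter_rel(x):
            return x * max(1.0 + noise.rel_anatomy * rng.standard_normal(), 0.05) if noise.rel_anatomy > 0 else x

        def jitter_abs(x):
            return max(x + noise.abs_thickness_um * rng.standard_normal(), 1e-3) if noise.abs_thickness_um > 0 else x

        tmes = jitter_abs(leaf.tmes)
        smes = section_width * tmes
        fias = min(jitter_rel(leaf.fias), 0.95)
        sias = fias * smes
        sm = jitter_rel(leaf.sm)
        lm = sm * section_width / f_eff
        areas = tuple(float(jitter_rel(leaf.chloroplast_size)) for _ in range(n_chl_measured))
        cover = leaf.coverage(size=float(np.mean(areas)))
        lc = cover * lm
        sections.append(
            SectionMeasurement(
                genotype=leaf.label,
                L=section_width,
                smes=smes,
                sias=sias,
                lm=lm,
                lc=lc,
                tcw=jitter_abs(leaf.tcw),
                tcyt=jitter_abs(leaf.tcyt + leaf.tcyt_gain * (1.0 - cover)),
                tstr=jitter_abs(leaf.tstr),
                tleaf=jitter_abs(leaf.tmes + 11.0),
                tmes=tmes,
                chloroplast_areas=areas,
                f_spongy=0.98,
                f_palisade=1.26,
                tissue_fraction=0.5,
            )
        )
    return sections


def chloroplast_contrast(base: TrueLeaf, n_few: float = 1.5, n_sections: int = 30,
                         ca: float = 400.0, ppfd: float = 300.0) -> dict[str, dict[str, float]]:
    """Compare a leaf against a variant differing only in chloroplast population.

    The variant carries ``n_few`` chloroplasts per cell with the same total
    chloroplast volume (cross-section area scaled by n/n_few).  For each
    leaf, noiseless sections are generated, aggregated, pushed through the
    anatomical gm model, and the resulting gm drives a steady-state
    gas-exchange solution at (Ca, PPFD).  Returns per-variant Sc, Tcyt,
    modelled gm and steady-state A.
    """
    from .anatomy_gm_model import PhysicalConstants, gm_from_anatomy

    few = dataclasses.replace(
        base,
        chloroplast_number=n_few,
        chloroplast_size=base.chloroplast_size * base.chloroplast_number / n_few,
        label=base.label + "-few",
    )
    pc = PhysicalConstants()
    out = {}
    for tag, leaf in (("many", base), ("few", few)):
        an = aggregate_anatomy(simulate_anatomy(leaf, n_sections=n_sections))
        part = gm_from_anatomy(an, pc)
        leaf_gm = dataclasses.replace(leaf, gm=part.gm_mol)
        a, ci, cc, j_op = _solve_operating(leaf_gm, ca, ppfd, leaf_gm.kinetics())
        out[tag] = {
            "sc": an.sc,
            "tcyt": an.tcyt,
            "gm_model": part.gm_mol,
            "a_steady": a,
            "coverage": leaf.coverage(),
        }
    return out
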