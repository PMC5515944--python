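"""Farquhar-von Caemmerer-Berry (FvCB) C3 photosynthesis model and curve fits.

Net assimilation is the minimum of the Rubisco-limited and RuBP-regeneration-
limited gross rates minus day respiration,

    Ac = Vcmax (Cc - GammaStar) / (Cc + Km),        Km = Kc (1 + O/Ko)
    Aj = J (Cc - GammaStar) / (4 Cc + 8 GammaStar)
    A  = min(Ac, Aj) - Rd

with Cc the chloroplast CO2 mole fraction.  Two fitting routes are provided:

* :func:`fit_aci_standard` -- classic two-parameter (Vcmax, Jcmax) fit of a
  response curve expressed on a Cc (or Ci) basis, gm assumed known/infinite;
* :func:`fit_aci_ethier` -- the finite-gm variant in which Cc = Ci - A/gm is
  eliminated analytically, turning each limitation state into a quadratic in
  A, and (Vcmax, Jcmax, gm) are estimated jointly.

The fitted "Jcmax" is the RuBP-regeneration capacity expressed at the
measurement irradiance; no light-response model is applied during fitting.
Kinetic constants default to widely used tobacco-derived 25 degC values and
are fully configurable; all fits are performed with constants held at their
reference temperature (no Arrhenius scaling).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import DataValidationError, DomainError, FitError, InsufficientDataError

__all__ = [
    "KineticConstants",
    "BiochemParams",
    "FitResult",
    "fvcb_forward",
    "limitation_state",
    "dA_dCc",
    "fit_aci_standard",
    "fit_aci_ethier",
    "ethier_forward",
]

#: Multistart grid of gm initial values (mol m-2 s-1) for the finite-gm fit.
GM_MULTISTART = (0.01, 0.05, 0.1, 0.3, 1.0)

#: gm estimates above this (mol m-2 s-1) are flagged as unidentifiable
#: (indistinguishable from infinite mesophyll conductance).
GM_IDENTIFIABLE_MAX = 2.0


@dataclass(frozen=True)
class KineticConstants:
    """Rubisco kinetics and gas composition at the reference temperature.

    kc : Michaelis constant for CO2 (umol mol-1)
    ko : Michaelis constant for O2 (mmol mol-1)
    o : oxygen mole fraction (mmol mol-1); 210 is ambient, ~15 is the
        non-photorespiratory 1.5% O2 used for fluorescence calibration
    gamma_star : photorespiratory CO2 compensation point (umol mol-1)
    tref : reference temperature (degC)
    """

    kc: float = 404.9
    ko: float = 278.4
    o: float = 210.0
    gamma_star: float = 42.75
    tref: float = 25.0

    def __post_init__(self) -> None:
        for name in ("kc", "ko", "o", "gamma_star"):
            if getattr(self, name) <= 0:
                raise DataValidationError(f"kinetic constant {name} must be positive")
        if not 0.0 <= self.tref <= 50.0:
            raise DataValidationError("reference temperature must lie in 0-50 degC")
        if self.km <= self.gamma_star:
            raise DataValidationError("effective Km must exceed GammaStar")

    @property
    def km(self) -> float:
        """Effective Michaelis constant Kc (1 + O/Ko) in umol mol-1."""
        return self.kc * (1.0 + self.o / self.ko)

    def with_gamma_star(self, gamma_star: float) -> "KineticConstants":
        return dataclasses.replace(self, gamma_star=gamma_star)


@dataclass(frozen=True)
class BiochemParams:
    """Fitted biochemical capacities (umol m-2 s-1) and optional gm (mol m-2 s-1)."""

    vcmax: float
    jcmax: float
    rd: float = 0.0
    gm: float | None = None
    basis: str = "cc"

    def __post_init__(self) -> None:
        if self.vcmax <= 0 or self.jcmax <= 0:
            raise DataValidationError("Vcmax and Jcmax must be positive")
        if self.rd < 0:
            raise DataValidationError("Rd must be non-negative")
        if self.gm is not None and self.gm <= 0:
            raise DataValidationError("gm must be positive when present")
        if self.basis not in ("ci", "cc"):
            raise DataValidationError("basis must be 'ci' or 'cc'")


@dataclass
class FitResult:
    """Outcome of an A/Ci or A/Cc fit."""

    params: BiochemParams
    residual_norm: float
    states: list[str] = field(default_factory=list)
    converged: bool = True
    unidentifiable: tuple[str, ...] = ()
    message: str = ""


# ---------------------------------------------------------------- forward model


def _gross_rates(cc, vcmax, j, k: KineticConstants):
    cc = np.asarray(cc, dtype=float)
    wc = vcmax * (cc - k.gamma_star) / (cc + k.km)
    wj = j * (cc - k.gamma_star) / (4.0 * cc + 8.0 * k.gamma_star)
    return wc, wj


def fvcb_forward(cc, p: BiochemParams, k: KineticConstants, j: float | None = None):
    """Net assimilation A = min(Ac, Aj) - Rd at chloroplast CO2 ``cc``.

    ``j`` overrides ``p.jcmax`` as the operating electron transport rate.
    At cc == gamma_star the result is exactly -Rd.
    """
    if np.any(np.asarray(cc, dtype=float) < 0):
        raise DomainError("Cc must be non-negative")
    wc, wj = _gross_rates(cc, p.vcmax, p.jcmax if j is None else j, k)
    out = np.minimum(wc, wj) - p.rd
    return out if out.ndim else float(out)


def limitation_state(cc, p: BiochemParams, k: KineticConstants, j: float | None = None):
    """Per-point active limitation: 'rubisco' where Ac <= Aj, else 'rubp'."""
    wc, wj = _gross_rates(cc, p.vcmax, p.jcmax if j is None else j, k)
    states = np.where(wc <= wj, "rubisco", "rubp")
    return states if states.ndim else str(states)


def dA_dCc(p: BiochemParams, k: KineticConstants, cc, j: float | None = None):
    """Analytic slope of the active limitation state at the operating point.

    Rubisco-limited: Vcmax (GammaStar + Km) / (Cc + Km)^2
    RuBP-limited:    12 J GammaStar / (4 Cc + 8 GammaStar)^2

    The result carries units of (umol m-2 s-1)/(umol mol-1) = mol m-2 s-1,
    directly commensurate with diffusive conductances.
    """
    cc = np.asarray(cc, dtype=float)
    if np.any(cc < 0):
        raise DomainError("Cc must be non-negative")
    jv = p.jcmax if j is None else j
    wc, wj = _gross_rates(cc, p.vcmax, jv, k)
    dc = p.vcmax * (k.gamma_star + k.km) / (cc + k.km) ** 2
    dj = 12.0 * jv * k.gamma_star / (4.0 * cc + 8.0 * k.gamma_star) ** 2
    out = np.where(wc <= wj, dc, dj)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------- standard fit


def _initial_capacities(x, y, rd, k: KineticConstants):
    """Heuristic Vcmax/Jcmax starting values from the curve itself."""
    gross = np.maximum(y + rd, 0.05)
    lo = x <= np.median(x)
    with np.errstate(divide="ignore", invalid="ignore"):
        vc = gross * (x + k.km) / np.maximum(x - k.gamma_star, 1.0)
        jj = gross * (4.0 * x + 8.0 * k.gamma_star) / np.maximum(x - k.gamma_star, 1.0)
    v0 = float(np.nanmedian(vc[lo])) if lo.any() else float(np.nanmedian(vc))
    j0 = float(np.nanmax(jj))
    return np.clip(v0, 1.0, 500.0), np.clip(j0, 1.0, 1000.0)


def fit_aci_standard(
    curve,
    k: KineticConstants,
    rd: float,
    cc=None,
    basis: str = "cc",
) -> FitResult:
    """Least-squares (Vcmax, Jcmax) fit of the hard-minimum FvCB model.

    Parameters
    ----------
    curve
        A ``CurveSet``; assimilation is taken from its records.
    cc
        Optional array of chloroplast CO2 values matching the records.  When
        omitted the records' Ci is used directly (infinite-gm assumption),
        which is what ``basis='ci'`` documents.
    """
    y = np.array([r.a for r in curve.records], dtype=float)
    if cc is not None:
        x = np.asarray(cc, dtype=float)
        basis = "cc"
    else:
        x = np.array([r.ci for r in curve.records], dtype=float)
    if len(x) < 5:
        raise InsufficientDataError("A/Ci fitting needs >= 5 points")
    if np.ptp(x) < 100.0:
        raise InsufficientDataError("A/Ci fitting needs points spanning low and high CO2")

    v0, j0 = _initial_capacities(x, y, rd, k)

    def resid(theta):
        vcmax, jcmax = theta
        wc, wj = _gross_rates(x, vcmax, jcmax, k)
        return np.minimum(wc, wj) - rd - y

    sol = least_squares(resid, x0=[v0, j0], bounds=([1e-3, 1e-3], [1e4, 1e4]),
                        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400)
    if not np.isfinite(sol.cost):
        raise FitError(f"standard A/Ci fit did not converge: {sol.message}")
    vcmax, jcmax = map(float, sol.x)
    params = BiochemParams(vcmax=vcmax, jcmax=jcmax, rd=rd, basis=basis)
    states = list(limitation_state(x, params, k))
    unident: tuple[str, ...] = ()
    if all(s == "rubisco" for s in states):
        unident = ("jcmax",)
    elif all(s == "rubp" for s in states):
        unident = ("vcmax",)
    return FitResult(
        params=params,
        residual_norm=float(np.linalg.norm(sol.fun)),
        states=states,
        converged=True,
        unidentifiable=unident,
        message="single-regime curve" if unident else "",
    )


# ---------------------------------------------------------------- Ethier fit


def _ethier_root(ci, vmax_like, kconst, gamma_star, rd, gm):
    """Physical root of the finite-gm quadratic for one limitation state.

    Eliminating Cc = Ci - A/gm from A = V (Cc - GammaStar)/(Cc + K) - Rd
    yields a A^2 + b A + c = 0 with a = -1/gm; the smaller (physical) root is
    (-b + sqrt(b^2 - 4ac)) / (2a).
    """
    a = -1.0 / gm
    b = (vmax_like - rd) / gm + ci + kconst
    c = rd * (ci + kconst) - vmax_like * (ci - gamma_star)
    disc = np.maximum(b * b - 4.0 * a * c, 0.0)
    return (-b + np.sqrt(disc)) / (2.0 * a)


def ethier_forward(ci, vcmax, jcmax, gm, rd, k: KineticConstants, gamma_star: float | None = None):
    """Net assimilation on a Ci basis under finite mesophyll conductance."""
    ci = np.asarray(ci, dtype=float)
    gs_ = k.gamma_star if gamma_star is None else gamma_star
    ac = _ethier_root(ci, vcmax, k.km, gs_, rd, gm)
    aj = _ethier_root(ci, jcmax / 4.0, 2.0 * gs_, gs_, rd, gm)
    out = np.minimum(ac, aj)
    return out if out.ndim else float(out)


def fit_aci_ethier(curve, k: KineticConstants, rd: float, laisk: tuple[float, float] | None = None) -> FitResult:
    """Joint (Vcmax, Jcmax, gm) fit of the finite-gm quadratic FvCB form.

    The likelihood in gm is notoriously flat, so the optimiser is restarted
    from each value of :data:`GM_MULTISTART` and the best solution kept.
    Estimates above :data:`GM_IDENTIFIABLE_MAX` are flagged unidentifiable.

    When ``laisk`` supplies the apparent compensation point and respiration
    ``(ci_star, rd_laisk)``, the photorespiratory compensation point is tied
    to the fitted gm through GammaStar = Ci* + Rd/gm during optimisation, so
    the fit and the compensation-point conversion are mutually consistent
    without any outer iteration.
    """
    x = np.array([r.ci for r in curve.records], dtype=float)
    y = np.array([r.a for r in curve.records], dtype=float)
    if len(x) < 6:
        raise InsufficientDataError("finite-gm fitting needs >= 6 points")
    if np.ptp(x) < 300.0:
        raise InsufficientDataError("finite-gm fitting needs a Ci span >= 300 umol mol-1")

    v0, j0 = _initial_capacities(x, y, rd, k)

    def tied_gamma_star(gm: float) -> float:
        ci_star, rd_l = laisk
        return float(np.clip(ci_star + rd_l / gm, 1e-3, 0.9 * k.km))

    def resid(theta):
        vcmax, jcmax, gm = theta
        gs_ = tied_gamma_star(gm) if laisk is not None else None
        return ethier_forward(x, vcmax, jcmax, gm, rd, k, gamma_star=gs_) - y

    # the hard-min model is only piecewise smooth, so the optimiser may stop
    # on its evaluation budget while chattering at the limitation crossover;
    # any finite-cost solution is kept and the best across starts is used
    best = None
    lb, ub = [1e-3, 1e-3, 1e-4], [1e4, 1e4, 10.0]
    for gm0 in GM_MULTISTART:
        sol = least_squares(resid, x0=[v0, j0, gm0], bounds=(lb, ub),
                            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400)
        if np.isfinite(sol.cost) and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitError("finite-gm A/Ci fit produced no usable solution from any start")

    vcmax, jcmax, gm = map(float, best.x)
    params = BiochemParams(vcmax=vcmax, jcmax=jcmax, rd=rd, gm=gm, basis="ci")
    k_eff = k if laisk is None else k.with_gamma_star(tied_gamma_star(gm))
    a_hat = ethier_forward(x, vcmax, jcmax, gm, rd, k_eff)
    cc = np.maximum(x - a_hat / gm, 0.0)
    states = list(limitation_state(cc, params, k_eff))
    unident: tuple[str, ...] = ()
    msg = ""
    if gm >= GM_IDENTIFIABLE_MAX or gm >= ub[2] * 0.99 or gm <= lb[2] * 1.01:
        unident = ("gm",)
        msg = f"gm estimate {gm:.3g} is at/near a bound; mesophyll conductance unidentifiable"
    return FitResult(
        params=params,
        residual_norm=float(np.linalg.norm(best.fun)),
        states=states,
        converged=bool(best.success),
        unidentifiable=unident,
        message=msg,
    )
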