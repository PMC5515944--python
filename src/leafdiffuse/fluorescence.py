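"""Chlorophyll-fluorescence signals to PSII efficiency and electron transport rate.

The operating efficiency of photosystem II is obtained from steady-state
(``Fs``) and light-adapted maximal (``Fm'``) fluorescence,

    Phi_PSII = (Fm' - Fs) / Fm'

and the linear electron transport rate from

    J = Phi_PSII * PPFD * alpha * beta

where ``alpha`` is leaf absorptance and ``beta`` the fraction of absorbed
quanta partitioned to PSII.  The product ``alpha*beta`` is not measured
directly: it is calibrated as the slope of the regression of the quantum
efficiency of gross CO2 uptake, Phi_CO2 = (A + Rd)/PPFD, on Phi_PSII/4,
using light curves measured under non-photorespiratory (<2% O2) conditions
where gross carboxylation consumes exactly one quarter of the electron flux.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import CalibrationError, DomainError, InsufficientDataError

__all__ = ["AlphaBeta", "phi_psii", "calibrate_alpha_beta", "electron_transport"]

#: Oxygen mole fraction (%) below which a curve counts as non-photorespiratory.
LOW_O2_THRESHOLD_PCT = 2.0


@dataclass(frozen=True)
class AlphaBeta:
    """Calibrated absorptance-partitioning product alpha*beta.

    Attributes
    ----------
    value : float
        The dimensionless product, in (0, 1].
    stderr : float
        Standard error of the regression slope.
    n : int
        Number of calibration points used.
    """

    value: float
    stderr: float
    n: int

    def __post_init__(self) -> None:
        if not 0.0 < self.value <= 1.0:
            raise CalibrationError(
                f"alpha*beta must lie in (0, 1], got {self.value:.4g}"
            )

    def __float__(self) -> float:
        return self.value


def phi_psii(fs, fmp):
    """Operating PSII photochemical efficiency (Fm' - Fs)/Fm'.

    Accepts scalars or arrays; the result lies in [0, 1].
    """
    fs = np.asarray(fs, dtype=float)
    fmp = np.asarray(fmp, dtype=float)
    if np.any(fmp <= 0):
        raise DomainError("Fm' must be strictly positive")
    if np.any(fs < 0):
        raise DomainError("Fs must be non-negative")
    if np.any(fs > fmp):
        raise DomainError("Fs exceeds Fm'; fluorescence pair is unphysical")
    out = (fmp - fs) / fmp
    return out if out.ndim else float(out)


def electron_transport(phi, ppfd, ab) -> float:
    """Linear electron transport rate J = Phi_PSII * PPFD * alpha*beta.

    ``ab`` may be an :class:`AlphaBeta` or a bare float.
    """
    value = float(getattr(ab, "value", ab))
    phi = np.asarray(phi, dtype=float)
    ppfd = np.asarray(ppfd, dtype=float)
    if np.any(phi < 0) or np.any(ppfd < 0) or value < 0:
        raise DomainError("phi, PPFD and alpha*beta must be non-negative")
    out = phi * ppfd * value
    return out if out.ndim else float(out)


def calibrate_alpha_beta(cal, rd: float, through_origin: bool = False) -> AlphaBeta:
    """Calibrate alpha*beta from a low-O2 light-response curve set.

    Regresses Phi_CO2 = (A + Rd)/PPFD on Phi_PSII/4 by ordinary least
    squares and returns the slope.  The intercept is estimated but
    discarded unless ``through_origin`` forces a no-intercept fit.

    Parameters
    ----------
    cal
        A ``CurveSet`` of kind ``"lowO2-calibration"`` whose records carry
        fluorescence and were measured below 2% O2 at >= 3 distinct PPFD.
    rd : float
        Day respiration used to form gross assimilation A + Rd.
    """
    if cal.kind != "lowO2-calibration":
        raise CalibrationError(f"expected a lowO2-calibration curve, got kind={cal.kind!r}")
    recs = [r for r in cal.records if r.ppfd > 0]
    if any(r.o2 >= LOW_O2_THRESHOLD_PCT for r in recs):
        raise CalibrationError("calibration records must be measured below 2% O2")
    ppfds = np.array([r.ppfd for r in recs])
    if len(recs) < 3 or len(np.unique(ppfds)) < 3:
        raise InsufficientDataError(
            "alpha*beta calibration needs >= 3 points at >= 3 distinct PPFD levels"
        )
    phi = np.array([phi_psii(r.fs, r.fmp) for r in recs])
    x = phi / 4.0
    y = (np.array([r.a for r in recs]) + rd) / ppfds

    if through_origin:
        sxx = float(x @ x)
        if sxx == 0.0:
            raise InsufficientDataError("degenerate calibration design: all Phi_PSII zero")
        slope = float(x @ y) / sxx
        resid = y - slope * x
        dof = max(len(x) - 1, 1)
        stderr = float(np.sqrt((resid @ resid) / dof / sxx))
    else:
        if np.ptp(x) == 0.0:
            raise InsufficientDataError("degenerate calibration design: constant Phi_PSII")
        fit = stats.linregress(x, y)
        slope, stderr = float(fit.slope), float(fit.stderr)

    if slope <= 0.0:
        raise CalibrationError(f"calibration slope is non-positive ({slope:.4g})")
    return AlphaBeta(value=slope, stderr=stderr, n=len(recs))
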