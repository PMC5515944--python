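"""Mesophyll conductance from combined gas exchange and fluorescence.

The variable-J method inverts the RuBP-regeneration-limited FvCB equation at
each observation, using the fluorescence-derived electron transport rate J:

    Cc = GammaStar (J + 8 (A + Rd)) / (J - 4 (A + Rd))
    gm = A / (Ci - Cc)

The Laisk method estimates the apparent CO2 photocompensation point Ci* and
day respiration Rd as the common intersection of low-Ci A/Ci lines measured
at several irradiances, from which GammaStar = Ci* + Rd/gm.  Stomatal and
mesophyll conductances combine in series to the total CO2 diffusion
conductance gt = 1/(1/gs + 1/gm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegeneracyError, DomainError, InsufficientDataError, NoIntersectionError
from .fluorescence import electron_transport, phi_psii

__all__ = [
    "VariableJResult",
    "LaiskResult",
    "cc_variable_j",
    "gm_variable_j",
    "total_conductance",
    "variable_j_curve",
    "fit_laisk",
]

#: Reference operating CO2 setpoint (umol mol-1) for curve-level summaries.
OPERATING_CA = 400.0


def cc_variable_j(a, rd, gamma_star, j):
    """Chloroplast CO2 from the variable-J inversion (scalar or array).

    Requires J > 4 (A + Rd); a collapsed denominator raises
    :class:`DegeneracyError`.  At A = -Rd the expression reduces to
    Cc = GammaStar regardless of J.
    """
    a = np.asarray(a, dtype=float)
    j = np.asarray(j, dtype=float)
    denom = j - 4.0 * (a + rd)
    if np.any(denom <= 0):
        raise DegeneracyError("variable-J degeneracy: J <= 4(A + Rd)")
    out = gamma_star * (j + 8.0 * (a + rd)) / denom
    return out if out.ndim else float(out)


def gm_variable_j(a, ci, cc):
    """Mesophyll conductance gm = A/(Ci - Cc); Ci == Cc is singular."""
    a = np.asarray(a, dtype=float)
    ci = np.asarray(ci, dtype=float)
    cc = np.asarray(cc, dtype=float)
    if np.any(ci == cc):
        raise DegeneracyError("gm singularity: Ci equals Cc")
    out = np.where(a == 0.0, 0.0, a / (ci - cc))
    return out if out.ndim else float(out)


def total_conductance(gs, gm):
    """Series (harmonic) combination gt = 1/(1/gs + 1/gm) < min(gs, gm)."""
    gs = np.asarray(gs, dtype=float)
    gm = np.asarray(gm, dtype=float)
    if np.any(gs <= 0) or np.any(gm <= 0):
        raise DomainError("conductances must be strictly positive")
    out = 1.0 / (1.0 / gs + 1.0 / gm)
    return out if out.ndim else float(out)


@dataclass
class VariableJResult:
    """Per-record variable-J output for one curve.

    ``valid`` marks records usable for curve means: positive assimilation,
    J above the degeneracy bound, Cc below Ci, positive gm, and Ci inside
    the aggregation window.
    """

    cc: np.ndarray
    gm: np.ndarray
    j: np.ndarray
    physical: np.ndarray
    valid: np.ndarray
    gm_mean: float
    cc_mean: float
    gt: float | None
    operating: dict | None


def variable_j_curve(curve, rd: float, gamma_star: float, alpha_beta, ci_window=(150.0, 500.0)) -> VariableJResult:
    """Apply the variable-J method to every record of an A/Ci curve.

    Degenerate records (J <= 4(A+Rd), Cc >= Ci, non-positive gm) are flagged
    invalid and excluded from the curve-level means rather than raising.
    The curve mean is taken over valid points whose Ci falls inside
    ``ci_window``; the operating point is the first record whose Ca is
    nearest the 400 umol mol-1 setpoint.
    """
    a = curve.array("a")
    ci = curve.array("ci")
    ca = curve.array("ca")
    gs = curve.array("gs")
    fs = curve.array("fs")
    fmp = curve.array("fmp")
    ppfd = curve.array("ppfd")
    if np.any(np.isnan(fs)) or np.any(np.isnan(fmp)):
        raise InsufficientDataError("variable-J needs fluorescence on every record")
    j = electron_transport(phi_psii(fs, fmp), ppfd, alpha_beta)

    denom = j - 4.0 * (a + rd)
    cc = np.full_like(a, np.nan)
    gm = np.full_like(a, np.nan)
    ok = denom > 0
    cc[ok] = gamma_star * (j[ok] + 8.0 * (a[ok] + rd)) / denom[ok]
    drawdown = ci - cc
    ok &= (a > 0) & (drawdown > 0)
    gm[ok] = a[ok] / drawdown[ok]
    ok &= gm > 0
    in_window = ok & (ci >= ci_window[0]) & (ci <= ci_window[1])

    if in_window.any():
        gm_mean = float(np.mean(gm[in_window]))
        cc_mean = float(np.mean(cc[in_window]))
        gt = total_conductance(float(np.mean(gs[in_window])), gm_mean)
    else:
        gm_mean = cc_mean = float("nan")
        gt = None

    operating = None
    if ok.any():
        cand = int(np.flatnonzero(ok)[np.argmin(np.abs(ca[ok] - OPERATING_CA))])
        operating = {
            "a": float(a[cand]),
            "gs": float(gs[cand]),
            "ci": float(ci[cand]),
            "cc": float(cc[cand]),
            "gm": float(gm[cand]),
            "j": float(j[cand]),
        }
    return VariableJResult(cc=cc, gm=gm, j=j, physical=ok, valid=in_window, gm_mean=gm_mean, cc_mean=cc_mean, gt=gt, operating=operating)


# ------------------------------------------------------------------- Laisk


@dataclass
class LaiskResult:
    """Common-intersection estimate from low-Ci curves at several irradiances."""

    ci_star: float
    rd: float
    gamma_star: float | None
    slopes: np.ndarray
    intercepts: np.ndarray
    residual: float
    quality_warning: bool


def fit_laisk(
    curves,
    ci_window=(0.0, 150.0),
    gm: float | None = None,
    slope_tol: float = 1e-4,
    residual_tol: float = 0.05,
) -> LaiskResult:
    """Estimate (Ci*, Rd) from the common intersection of low-Ci lines.

    A straight line is fitted per curve inside ``ci_window``; the
    intersection is the least-squares point minimising the summed squared
    vertical distances to all lines (a symmetric, deterministic rule).  With
    a caller-supplied mesophyll conductance, GammaStar = Ci* + Rd/gm.

    Raises
    ------
    NoIntersectionError
        When the slope spread is below ``slope_tol`` (near-parallel lines).
    """
    ppfds = [float(np.mean(c.array("ppfd"))) for c in curves]
    if len(curves) < 3 or len({round(p, 6) for p in ppfds}) < 3:
        raise InsufficientDataError("Laisk needs >= 3 curves at distinct PPFD")
    slopes, intercepts = [], []
    for c in curves:
        ci = c.array("ci")
        a = c.array("a")
        sel = (ci >= ci_window[0]) & (ci <= ci_window[1])
        if sel.sum() < 3:
            raise InsufficientDataError(
                f"Laisk needs >= 3 points inside the Ci window for curve at PPFD {np.mean(c.array('ppfd')):.0f}"
            )
        b, a0 = np.polyfit(ci[sel], a[sel], 1)
        slopes.append(float(b))
        intercepts.append(float(a0))
    slopes = np.array(slopes)
    intercepts = np.array(intercepts)
    if np.ptp(slopes) < slope_tol:
        raise NoIntersectionError("Laisk lines are near-parallel; no common intersection")

    # minimise f(x, y) = sum_i (y - a_i - b_i x)^2 -> linear normal equations
    n = len(slopes)
    mat = np.array([[float(slopes @ slopes), -float(slopes.sum())], [-float(slopes.sum()), float(n)]])
    rhs = np.array([-float(slopes @ intercepts), float(intercepts.sum())])
    x, y = np.linalg.solve(mat, rhs)
    resid = float(np.sqrt(np.mean((y - intercepts - slopes * x) ** 2)))
    rd = -float(y)
    ci_star = float(x)
    gamma_star = ci_star + rd / gm if gm is not None else None
    return LaiskResult(
        ci_star=ci_star,
        rd=rd,
        gamma_star=gamma_star,
        slopes=slopes,
        intercepts=intercepts,
        residual=resid,
        quality_warning=resid > residual_tol,
    )
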