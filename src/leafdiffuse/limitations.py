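"""Quantitative partitioning of photosynthesis limitations, PNUE, and LSD letters.

At an operating point the relative limitations imposed by stomata, mesophyll
and biochemistry are

    ls = (gt/gs) * dA/dCc / (gt + dA/dCc)
    lm = (gt/gm) * dA/dCc / (gt + dA/dCc)
    lb =  gt             / (gt + dA/dCc)

which sum to exactly 1 whenever gt is the series combination of gs and gm.
Differences between a mutant and its wild-type reference are decomposed as

    dA/A = Ls + Lm + Lb = (dgs/gs) ls + (dgm/gm) lm + (dVcmax/Vcmax) lb

with the relative limitations evaluated at the reference.  The decomposition
is reported alongside the observed dA/A and their mismatch; the two are not
forced to agree.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DataValidationError, DomainError, InsufficientDataError
from .gm_estimation import total_conductance

__all__ = [
    "OperatingPoint",
    "LimitationResult",
    "relative_limitations",
    "limitation_contributions",
    "pnue",
    "lsd_groups",
]


@dataclass(frozen=True)
class OperatingPoint:
    """State of one leaf at its measurement point (conductances mol m-2 s-1)."""

    a: float
    gs: float
    gm: float
    gt: float
    cc: float
    vcmax: float
    dadcc: float

    def __post_init__(self) -> None:
        if min(self.gs, self.gm, self.gt) <= 0:
            raise DomainError("all conductances must be positive")
        if abs(self.gt - total_conductance(self.gs, self.gm)) > 1e-9:
            raise DataValidationError(
                "gt is not the series combination of gs and gm (|mismatch| > 1e-9)"
            )


@dataclass
class LimitationResult:
    """Eq-15-style decomposition of a wild-type to mutant change in A."""

    ls: float
    lm: float
    lb: float
    Ls: float
    Lm: float
    Lb: float
    dA_over_A: float
    mismatch: float


def relative_limitations(op: OperatingPoint) -> tuple[float, float, float]:
    """Stomatal, mesophyll and biochemical relative limitations (sum to 1)."""
    if op.dadcc <= 0:
        raise DomainError("dA/dCc must be positive")
    denom = op.gt + op.dadcc
    ls = op.gt / op.gs * op.dadcc / denom
    lm = op.gt / op.gm * op.dadcc / denom
    lb = op.gt / denom
    return float(ls), float(lm), float(lb)


def limitation_contributions(ref: OperatingPoint, mutant: OperatingPoint) -> LimitationResult:
    """Attribute the mutant's change in A to gs, gm and Vcmax changes.

    The wild-type is the reference: relative limitations are evaluated at
    ``ref`` and multiplied by the fractional declines of gs, gm and Vcmax.
    """
    ls, lm, lb = relative_limitations(ref)
    dgs = (ref.gs - mutant.gs) / ref.gs
    dgm = (ref.gm - mutant.gm) / ref.gm
    dvc = (ref.vcmax - mutant.vcmax) / ref.vcmax
    Ls, Lm, Lb = dgs * ls, dgm * lm, dvc * lb
    da_over_a = (ref.a - mutant.a) / ref.a
    return LimitationResult(
        ls=ls, lm=lm, lb=lb, Ls=Ls, Lm=Lm, Lb=Lb,
        dA_over_A=da_over_a, mismatch=da_over_a - (Ls + Lm + Lb),
    )


def pnue(a: float, narea: float) -> float:
    """Photosynthetic nitrogen use efficiency A/Narea (umol g-1 N s-1)."""
    if narea <= 0:
        raise DomainError("leaf N per area must be positive")
    return float(a) / float(narea)


def lsd_groups(values: dict[str, "np.ndarray"], alpha: float = 0.05) -> dict[str, str]:
    """Fisher-LSD compact letter display after one-way ANOVA.

    Groups sharing a letter are not significantly different at ``alpha``.
    Letters are assigned greedily in descending order of group mean (table
    convention: 'a' marks the largest mean), then repaired so every
    non-significant pair shares at least one letter.
    """
    names = list(values)
    if len(names) < 2:
        raise InsufficientDataError("LSD grouping needs >= 2 groups")
    arrs = {g: np.asarray(values[g], dtype=float) for g in names}
    if any(len(v) < 2 for v in arrs.values()):
        raise InsufficientDataError("LSD grouping needs >= 2 replicates per group")
    n_tot = sum(len(v) for v in arrs.values())
    df_err = n_tot - len(names)
    mse = sum(((v - v.mean()) ** 2).sum() for v in arrs.values()) / df_err
    if mse == 0.0:
        raise DomainError("zero within-group variance everywhere; LSD undefined")
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df_err)

    def differs(g: str, h: str) -> bool:
        vg, vh = arrs[g], arrs[h]
        lsd = tcrit * np.sqrt(mse * (1.0 / len(vg) + 1.0 / len(vh)))
        return abs(vg.mean() - vh.mean()) > lsd

    order = sorted(names, key=lambda g: -arrs[g].mean())
    classes: list[set[str]] = []
    for g in order:
        placed = False
        for cls in classes:
            if all(not differs(g, h) for h in cls):
                cls.add(g)
                placed = True
        if not placed:
            classes.append({g})
    # repair: every non-significant pair must share a class
    for g, h in itertools.combinations(order, 2):
        if not differs(g, h) and not any(g in c and h in c for c in classes):
            cls = {g, h}
            for other in order:
                if other not in cls and all(not differs(other, m) for m in cls):
                    cls.add(other)
            classes.append(cls)
    # drop classes fully contained in another
    classes = [c for i, c in enumerate(classes) if not any(i != j and c < d for j, d in enumerate(classes))]
    letters = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in names}
    for letter, cls in zip(letters, classes):
        for g in order:
            if g in cls:
                out[g] += letter
    return out
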