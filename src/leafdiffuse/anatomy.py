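"""Stereology: cross-section measurements to leaf-level anatomical traits.

From traced cross sections the pipeline derives the volume fraction of
intercellular airspace,

    fias = Sias / Smes,

and surface areas per unit leaf area from exposed lengths via the curvature
correction factor F of Thain,

    S = (l / L) * F,

applied separately to palisade and spongy tissue (each with its own F) and
combined as a tissue-fraction-weighted mean, since sections mix both cell
types.  S is Sm when l is the exposed mesophyll wall length lm, and Sc when
l is the chloroplast length appressed to the exposed plasma membrane lc.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataValidationError, DomainError

__all__ = [
    "SectionMeasurement",
    "LeafAnatomy",
    "airspace_fraction",
    "surface_per_area",
    "mixed_curvature_factor",
    "curvature_factor_prolate",
    "aggregate_anatomy",
]


@dataclass(frozen=True)
class SectionMeasurement:
    """Raw measurements from one traced leaf cross section (lengths um, areas um^2).

    L : analysed section width
    smes / sias : mesophyll / intercellular-airspace cross-section areas
    lm / lc : exposed mesophyll wall length / chloroplast length appressed
        to the exposed plasma membrane
    tcw, tcyt, tstr, tleaf, tmes : thicknesses
    f_spongy / f_palisade : Thain curvature factors for the two tissues
    tissue_fraction : palisade share of the exposed length
    """

    L: float
    smes: float
    sias: float
    lm: float
    lc: float
    tcw: float
    tcyt: float
    tstr: float
    tleaf: float
    tmes: float
    chloroplast_areas: tuple[float, ...] = ()
    f_spongy: float = 0.98
    f_palisade: float = 1.26
    tissue_fraction: float = 0.5
    genotype: str = ""

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise DataValidationError("section width L must be positive")
        for name in ("smes", "sias", "lm", "lc", "tcw", "tcyt", "tstr", "tleaf", "tmes"):
            if getattr(self, name) < 0:
                raise DataValidationError(f"{name} must be non-negative")
        if self.sias > self.smes:
            raise DataValidationError("airspace area Sias cannot exceed mesophyll area Smes")
        if self.lc > self.lm * (1 + 1e-12):
            raise DataValidationError("chloroplast length lc cannot exceed exposed wall length lm")
        for name in ("f_spongy", "f_palisade"):
            if not 0.8 <= getattr(self, name) <= 1.6:
                raise DataValidationError(f"curvature factor {name} outside the plausible range [0.8, 1.6]")
        if not 0.0 <= self.tissue_fraction <= 1.0:
            raise DataValidationError("tissue_fraction must lie in [0, 1]")
        if any(a < 0 for a in self.chloroplast_areas):
            raise DataValidationError("chloroplast areas must be non-negative")


@dataclass
class LeafAnatomy:
    """Aggregated stereological traits of one leaf/genotype.

    fias is a fraction; sm and sc are m^2 m^-2 leaf; thicknesses in um;
    chloroplast_size in um^2; lma in g m^-2.
    """

    fias: float
    sm: float
    sc: float
    tcw: float
    tcyt: float
    tstr: float
    tmes: float
    tleaf: float
    chloroplast_size: float = float("nan")
    pchl: float | None = None
    lma: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.fias <= 1.0:
            raise DataValidationError("fias must lie in [0, 1]")
        if self.sc > self.sm * (1 + 1e-9):
            raise DataValidationError("Sc cannot exceed Sm")


def airspace_fraction(sias, smes):
    """Volume fraction of intercellular airspace, Sias/Smes."""
    sias = np.asarray(sias, dtype=float)
    smes = np.asarray(smes, dtype=float)
    if np.any(smes <= 0):
        raise DomainError("mesophyll area Smes must be positive")
    if np.any(sias > smes):
        raise DomainError("Sias cannot exceed Smes")
    out = sias / smes
    return out if out.ndim else float(out)


def surface_per_area(l, L, F):
    """Surface area per leaf area, (l/L)*F, for one tissue with factor F."""
    l = np.asarray(l, dtype=float)
    if np.any(np.asarray(L, dtype=float) <= 0):
        raise DomainError("section width L must be positive")
    if np.any(np.asarray(F, dtype=float) <= 0):
        raise DomainError("curvature factor F must be positive")
    out = l / L * F
    return out if out.ndim else float(out)


def mixed_curvature_factor(f_spongy, f_palisade, tissue_fraction):
    """Effective F for a section mixing palisade (weight = tissue_fraction) and spongy tissue."""
    return tissue_fraction * f_palisade + (1.0 - tissue_fraction) * f_spongy


def curvature_factor_prolate(aspect_ratio: float, n: int = 2000) -> float:
    """Optional helper: curvature factor for cells idealised as prolate spheroids.

    Leaf cross sections cut parallel to the palisade (polar) axis sample a
    spheroidal cell as ellipses.  F compares the true surface-to-volume
    ratio with the perimeter-to-area ratio of such sections, normalised so a
    sphere (spongy-like isodiametric cell) gives exactly 1; elongated
    palisade-like cells (``aspect_ratio`` = polar/equatorial > 1) give
    F > 1, mirroring the measured spongy ~1.0 vs palisade ~1.2-1.4 split.
    """
    if aspect_ratio < 1.0:
        raise DomainError("aspect ratio must be >= 1 (polar >= equatorial)")

    def _ratio(c: float) -> float:
        # surface and volume of spheroid with semi-axes (1, 1, c)
        if abs(c - 1.0) < 1e-12:
            surface = 4.0 * np.pi
        else:
            e = np.sqrt(1.0 - 1.0 / c**2)
            surface = 2.0 * np.pi * (1.0 + c / e * np.arcsin(e))
        volume = 4.0 * np.pi * c / 3.0
        # planes parallel to the polar axis at offset d in [0, 1): elliptical
        # sections with semi-axes (s, c*s), s = sqrt(1 - d^2)
        d = (np.arange(n) + 0.5) / n
        s = np.sqrt(1.0 - d * d)
        aa, bb = s, c * s
        h = ((aa - bb) / (aa + bb)) ** 2
        perim = np.pi * (aa + bb) * (1.0 + 3.0 * h / (10.0 + np.sqrt(4.0 - 3.0 * h)))
        area = np.pi * aa * bb
        return (surface / volume) / (float(np.mean(perim)) / float(np.mean(area)))

    return float(_ratio(aspect_ratio) / _ratio(1.0))


def aggregate_anatomy(sections, lma: float | None = None) -> LeafAnatomy:
    """Average per-section traits into one :class:`LeafAnatomy`.

    Sm and Sc come from the exposed lengths via the tissue-weighted curvature
    factor; thicknesses and fias are plain means; chloroplast size is the
    mean over all measured chloroplast cross-section areas.  The rule is
    permutation-invariant and idempotent under duplication of the whole list.
    """
    sections = list(sections)
    if not sections:
        raise DomainError("aggregate_anatomy needs at least one section")
    fias = float(np.mean([airspace_fraction(s.sias, s.smes) for s in sections]))
    f_eff = [mixed_curvature_factor(s.f_spongy, s.f_palisade, s.tissue_fraction) for s in sections]
    sm = float(np.mean([surface_per_area(s.lm, s.L, f) for s, f in zip(sections, f_eff)]))
    sc = float(np.mean([surface_per_area(s.lc, s.L, f) for s, f in zip(sections, f_eff)]))
    areas = [a for s in sections for a in s.chloroplast_areas]
    return LeafAnatomy(
        fias=fias,
        sm=sm,
        sc=min(sc, sm),
        tcw=float(np.mean([s.tcw for s in sections])),
        tcyt=float(np.mean([s.tcyt for s in sections])),
        tstr=float(np.mean([s.tstr for s in sections])),
        tmes=float(np.mean([s.tmes for s in sections])),
        tleaf=float(np.mean([s.tleaf for s in sections])),
        chloroplast_size=float(np.mean(areas)) if areas else float("nan"),
        lma=lma,
    )
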