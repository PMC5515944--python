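"""Tabular I/O, configuration, and the pipeline orchestrator.

All tables are comma-separated text with one header row.  The canonical
gas-exchange dialect uses the columns

    genotype, replicate, kind, A, Ci, Ca, gs, E, PPFD, Tleaf, Fs, Fmp, O2_pct

with fixed units (umol m-2 s-1 for fluxes, umol mol-1 for CO2 mole
fractions, mol m-2 s-1 for gs, mmol m-2 s-1 for E, degC for Tleaf, percent
for O2).  Vendor exports are adapted by a column-mapping dictionary, never
parsed natively, and units are never inferred on the fly: a header may carry
a parenthesised unit annotation, which is validated against the convention
above and rejected on mismatch.  Grouping keys (genotype, replicate, kind)
are explicit columns, not filename conventions.
"""

from __future__ import annotations

import dataclasses
import io
import os
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataValidationError, FormatError, PipelineError

__all__ = [
    "GasExchangeRecord",
    "CurveSet",
    "AnalysisConfig",
    "read_gas_exchange",
    "write_gas_exchange",
    "read_anatomy",
    "write_anatomy",
    "run_pipeline",
]

CURVE_KINDS = ("aci", "light", "laisk", "lowO2-calibration")

GASX_COLUMNS = ["genotype", "replicate", "kind", "A", "Ci", "Ca", "gs", "E", "PPFD", "Tleaf", "Fs", "Fmp", "O2_pct"]

#: Unit convention used to validate optional "(unit)" header annotations.
EXPECTED_UNITS = {
    "A": "umol m-2 s-1",
    "Ci": "umol mol-1",
    "Ca": "umol mol-1",
    "gs": "mol m-2 s-1",
    "E": "mmol m-2 s-1",
    "PPFD": "umol m-2 s-1",
    "Tleaf": "degC",
    "O2_pct": "%",
}


@dataclass(frozen=True)
class GasExchangeRecord:
    """One simultaneous gas-exchange + fluorescence observation.

    a : net CO2 assimilation (umol m-2 s-1)
    ci / ca : intercellular / chamber-reference CO2 (umol mol-1)
    gs : stomatal conductance to CO2 (mol m-2 s-1)
    e : transpiration (mmol m-2 s-1)
    ppfd : incident photon flux (umol m-2 s-1)
    tleaf : leaf temperature (degC)
    fs / fmp : steady-state / light-adapted maximal fluorescence (arbitrary;
        NaN when the fluorometer signal is absent)
    o2 : oxygen mole fraction (%)
    """

    a: float
    ci: float
    ca: float
    gs: float
    e: float
    ppfd: float
    tleaf: float
    fs: float = float("nan")
    fmp: float = float("nan")
    o2: float = 21.0

    def __post_init__(self) -> None:
        if self.gs <= 0:
            raise DataValidationError(f"gs must be positive, got {self.gs}")
        if self.ppfd < 0:
            raise DataValidationError("PPFD must be non-negative")
        if self.ci < 0:
            raise DataValidationError("Ci must be non-negative")
        if self.has_fluorescence:
            if self.fs < 0 or self.fmp < self.fs:
                raise DataValidationError(
                    f"fluorescence must satisfy Fmp >= Fs >= 0, got Fs={self.fs}, Fmp={self.fmp}"
                )

    @property
    def has_fluorescence(self) -> bool:
        return not (np.isnan(self.fs) or np.isnan(self.fmp))


@dataclass
class CurveSet:
    """An ordered response curve measured on one leaf.

    kind : one of 'aci', 'light', 'laisk', 'lowO2-calibration'
    """

    kind: str
    genotype: str
    replicate: str
    records: list[GasExchangeRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in CURVE_KINDS:
            raise DataValidationError(f"unknown curve kind {self.kind!r}; expected one of {CURVE_KINDS}")
        if self.kind == "aci" and self.records:
            ppfds = {r.ppfd for r in self.records}
            if max(ppfds) - min(ppfds) > 1e-9 * max(ppfds):
                raise DataValidationError("aci curve records must share one PPFD")

    def __len__(self) -> int:
        return len(self.records)

    def array(self, attr: str) -> np.ndarray:
        return np.array([getattr(r, attr) for r in self.records], dtype=float)


# ------------------------------------------------------------- configuration


@dataclass
class AnalysisConfig:
    """Flat configuration for every pipeline stage.

    Stored as a plain ``key = value`` text file; every key below is a valid
    file key.  Kinetic constants feed the FvCB fits, physical constants the
    anatomical diffusion model; the remaining keys steer aggregation windows
    and fitting behaviour.
    """

    # Rubisco kinetics (see fvcb.KineticConstants)
    kc: float = 404.9
    ko: float = 278.4
    o2_mmol: float = 210.0
    gamma_star: float = 42.75
    tref: float = 25.0
    # respiration / fluorescence fallbacks when no Laisk or calibration set exists
    rd: float = 1.5
    alpha_beta: float = 0.45
    alpha_beta_through_origin: int = 0
    # Laisk stage
    laisk_ci_max: float = 150.0
    laisk_slope_tol: float = 1e-4
    laisk_residual_tol: float = 0.05
    # variable-J aggregation window (umol mol-1)
    ci_window_lo: float = 150.0
    ci_window_hi: float = 500.0
    # physical constants of the anatomical model (see anatomy_gm_model)
    da: float = 1.51e-5
    dw: float = 1.79e-9
    zeta: float = 1.57
    henry: float = 2941.0
    tk: float = 298.15
    pressure: float = 101325.0
    g_pl: float = 0.0035
    g_en: float = 0.0035
    gamma_cyt: float = 0.3
    gamma_str: float = 0.3
    stroma_divisor: float = 2.0
    # misc
    seed: int = 0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if f.name in ("seed", "alpha_beta_through_origin"):
                continue
            if getattr(self, f.name) <= 0:
                raise DataValidationError(f"config constant {f.name} must be strictly positive")
        if not 0.0 <= self.tref <= 50.0:
            raise DataValidationError("tref must lie in 0-50 degC")

    def kinetics(self):
        from .fvcb import KineticConstants

        return KineticConstants(kc=self.kc, ko=self.ko, o=self.o2_mmol, gamma_star=self.gamma_star, tref=self.tref)

    def physical(self):
        from .anatomy_gm_model import PhysicalConstants

        return PhysicalConstants(
            da=self.da,
            dw=self.dw,
            zeta=self.zeta,
            henry=self.henry,
            tk=self.tk,
            pressure=self.pressure,
            g_pl=self.g_pl,
            g_en=self.g_en,
            gamma_cyt=self.gamma_cyt,
            gamma_str=self.gamma_str,
            stroma_divisor=self.stroma_divisor,
        )

    def to_text(self) -> str:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in dataclasses.fields(self)]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        known = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise FormatError(f"{path}:{lineno}: expected 'key = value'")
                key, val = (s.strip() for s in line.split("=", 1))
                if key not in known:
                    raise FormatError(f"{path}:{lineno}: unknown config key {key!r}")
                try:
                    kwargs[key] = int(val) if key in ("seed", "alpha_beta_through_origin") else float(val)
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-numeric value for {key!r}") from exc
        return cls(**kwargs)


# ------------------------------------------------------------------ reading


def _strip_units(columns) -> tuple[list[str], dict[str, str]]:
    """Split 'A (umol m-2 s-1)' headers into names and unit annotations."""
    names, units = [], {}
    for col in columns:
        m = re.match(r"^\s*([^(]+?)\s*(?:\(([^)]*)\))?\s*$", str(col))
        name = m.group(1) if m else str(col)
        names.append(name)
        if m and m.group(2):
            units[name] = m.group(2).strip()
    return names, units


def _numeric(df: pd.DataFrame, col: str, path) -> np.ndarray:
    # cells are parsed with Python's exact float conversion so that tables
    # written by this package round-trip bit-for-bit
    out = np.empty(len(df), dtype=float)
    for i, cell in enumerate(df[col].to_numpy()):
        if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
            out[i] = np.nan
            continue
        try:
            out[i] = float(cell)
        except (TypeError, ValueError):
            raise FormatError(
                f"{path}: non-numeric value {cell!r} in column {col!r} at data row {i}"
            ) from None
    return out


def read_gas_exchange(path, dialect: dict[str, str] | None = None) -> list[CurveSet]:
    """Read a gas-exchange table into curve sets grouped by (genotype, replicate, kind).

    ``dialect`` maps source column names to canonical ones, adapting vendor
    exports.  Row order inside each group is preserved.
    """
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    names, units = _strip_units(df.columns)
    df.columns = names
    if dialect:
        df = df.rename(columns=dialect)
        units = {dialect.get(k, k): v for k, v in units.items()}
    for col, unit in units.items():
        want = EXPECTED_UNITS.get(col)
        if want is not None and unit != want:
            raise FormatError(f"{path}: column {col!r} annotated with unit {unit!r}, expected {want!r}")
    mandatory = ["genotype", "replicate", "kind", "A", "Ci", "Ca", "gs", "E", "PPFD", "Tleaf"]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")

    numeric = {c: _numeric(df, c, path) for c in ["A", "Ci", "Ca", "gs", "E", "PPFD", "Tleaf"]}
    for opt in ("Fs", "Fmp", "O2_pct"):
        numeric[opt] = _numeric(df, opt, path) if opt in df.columns else np.full(len(df), np.nan)
    o2 = np.where(np.isnan(numeric["O2_pct"]), 21.0, numeric["O2_pct"])

    curves: dict[tuple[str, str, str], CurveSet] = {}
    for i in range(len(df)):
        key = (str(df["genotype"].iloc[i]), str(df["replicate"].iloc[i]), str(df["kind"].iloc[i]))
        try:
            rec = GasExchangeRecord(
                a=numeric["A"][i],
                ci=numeric["Ci"][i],
                ca=numeric["Ca"][i],
                gs=numeric["gs"][i],
                e=numeric["E"][i],
                ppfd=numeric["PPFD"][i],
                tleaf=numeric["Tleaf"][i],
                fs=numeric["Fs"][i],
                fmp=numeric["Fmp"][i],
                o2=float(o2[i]),
            )
        except DataValidationError as exc:
            raise DataValidationError(f"{path}: data row {i}: {exc}") from exc
        if key not in curves:
            curves[key] = CurveSet(kind=key[2], genotype=key[0], replicate=key[1])
        curves[key].records.append(rec)
    return list(curves.values())


def write_gas_exchange(curves: list[CurveSet], path) -> None:
    """Write curve sets in the canonical dialect; exact round-trip with the reader."""
    rows = []
    for cs in curves:
        for r in cs.records:
            rows.append(
                {
                    "genotype": cs.genotype,
                    "replicate": cs.replicate,
                    "kind": cs.kind,
                    "A": r.a,
                    "Ci": r.ci,
                    "Ca": r.ca,
                    "gs": r.gs,
                    "E": r.e,
                    "PPFD": r.ppfd,
                    "Tleaf": r.tleaf,
                    "Fs": r.fs,
                    "Fmp": r.fmp,
                    "O2_pct": r.o2,
                }
            )
    pd.DataFrame(rows, columns=GASX_COLUMNS).to_csv(path, index=False)


ANATOMY_COLUMNS = [
    "genotype",
    "L",
    "Smes",
    "Sias",
    "lm",
    "lc",
    "Tcw",
    "Tcyt",
    "Tstr",
    "Tleaf",
    "Tmes",
    "Fspongy",
    "Fpalisade",
    "tissue_fraction",
    "chloroplast_areas",
]


def read_anatomy(path) -> list:
    """Read per-section anatomical measurements (one SectionMeasurement per row).

    The ``chloroplast_areas`` cell holds semicolon-separated areas (um^2).
    """
    from .anatomy import SectionMeasurement

    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    names, _ = _strip_units(df.columns)
    df.columns = names
    missing = [c for c in ANATOMY_COLUMNS if c not in df.columns and c not in ("genotype", "chloroplast_areas")]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    numeric_cols = [c for c in ANATOMY_COLUMNS if c not in ("genotype", "chloroplast_areas")]
    numeric = {c: _numeric(df, c, path) for c in numeric_cols}
    sections = []
    for i in range(len(df)):
        areas: tuple[float, ...] = ()
        if "chloroplast_areas" in df.columns and isinstance(df["chloroplast_areas"].iloc[i], str):
            cell = df["chloroplast_areas"].iloc[i].strip()
            if cell:
                try:
                    areas = tuple(float(tok) for tok in cell.split(";"))
                except ValueError as exc:
                    raise FormatError(f"{path}: bad chloroplast_areas cell at data row {i}") from exc
        try:
            sections.append(
                SectionMeasurement(
                    genotype=str(df["genotype"].iloc[i]) if "genotype" in df.columns else "",
                    L=numeric["L"][i],
                    smes=numeric["Smes"][i],
                    sias=numeric["Sias"][i],
                    lm=numeric["lm"][i],
                    lc=numeric["lc"][i],
                    tcw=numeric["Tcw"][i],
                    tcyt=numeric["Tcyt"][i],
                    tstr=numeric["Tstr"][i],
                    tleaf=numeric["Tleaf"][i],
                    tmes=numeric["Tmes"][i],
                    f_spongy=numeric["Fspongy"][i],
                    f_palisade=numeric["Fpalisade"][i],
                    tissue_fraction=numeric["tissue_fraction"][i],
                    chloroplast_areas=areas,
                )
            )
        except DataValidationError as exc:
            raise DataValidationError(f"{path}: data row {i}: {exc}") from exc
    return sections


def write_anatomy(sections, path) -> None:
    rows = []
    for s in sections:
        rows.append(
            {
                "genotype": s.genotype,
                "L": s.L,
                "Smes": s.smes,
                "Sias": s.sias,
                "lm": s.lm,
                "lc": s.lc,
                "Tcw": s.tcw,
                "Tcyt": s.tcyt,
                "Tstr": s.tstr,
                "Tleaf": s.tleaf,
                "Tmes": s.tmes,
                "Fspongy": s.f_spongy,
                "Fpalisade": s.f_palisade,
                "tissue_fraction": s.tissue_fraction,
                "chloroplast_areas": ";".join(repr(a) for a in s.chloroplast_areas),
            }
        )
    pd.DataFrame(rows, columns=ANATOMY_COLUMNS).to_csv(path, index=False)


# ------------------------------------------------------------------ pipeline

REPORT_COLUMNS = [
    "genotype",
    "A",
    "gs",
    "Ci",
    "Cc",
    "gm_variable_j",
    "gm_ethier",
    "gm_anatomy",
    "gt",
    "Rd",
    "GammaStar",
    "alpha_beta",
    "J",
    "Vcmax",
    "Jcmax",
    "PNUE",
    "ls",
    "lm",
    "lb",
]


def _stage(stage: str, genotype: str):
    """Context manager that renames any failure after its stage and genotype."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {stage!r} failed for genotype {genotype!r}: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: AnalysisConfig, gasx: list[CurveSet], anatomy=None, narea: dict[str, float] | None = None) -> pd.DataFrame:
    """Chain every analysis stage and emit one summary row per genotype.

    Per genotype: Laisk intersection (Rd, Ci*) when laisk curves exist,
    alpha*beta calibration when a low-O2 set exists, finite-gm (Ethier) and
    standard FvCB fits, variable-J Cc/gm at the operating point, the
    anatomical gm model when sections exist, and the relative limitation
    partition.  Output is a pure function of (inputs, config).

    ``narea`` optionally maps genotype to leaf N per area (g m-2) for PNUE.
    """
    from . import anatomy as anat
    from . import gm_estimation as gme
    from .anatomy_gm_model import gm_from_anatomy
    from .fluorescence import calibrate_alpha_beta
    from .fvcb import dA_dCc, fit_aci_ethier, fit_aci_standard
    from .limitations import OperatingPoint, pnue, relative_limitations

    anatomy = anatomy or []
    k = config.kinetics()
    pc = config.physical()
    genotypes = sorted({cs.genotype for cs in gasx})
    if not genotypes:
        raise PipelineError("no gas-exchange curves supplied")
    rows = []
    for g in genotypes:
        mine = [cs for cs in gasx if cs.genotype == g]
        aci = [cs for cs in mine if cs.kind == "aci"]
        laisk = [cs for cs in mine if cs.kind == "laisk"]
        cal = [cs for cs in mine if cs.kind == "lowO2-calibration"]
        if not aci:
            raise PipelineError(f"stage 'input' failed for genotype {g!r}: no A/Ci curve")

        row: dict[str, float | str] = {c: np.nan for c in REPORT_COLUMNS}
        row["genotype"] = g

        rd, ci_star = config.rd, None
        if len(laisk) >= 3:
            with _stage("laisk", g):
                lres = gme.fit_laisk(laisk, ci_window=(0.0, config.laisk_ci_max))
                rd, ci_star = lres.rd, lres.ci_star
        row["Rd"] = rd

        ab = config.alpha_beta
        if cal:
            with _stage("alpha-beta calibration", g):
                ab = calibrate_alpha_beta(cal[0], rd, through_origin=bool(config.alpha_beta_through_origin)).value
        row["alpha_beta"] = ab

        # GammaStar and the finite-gm fit are mutually dependent (the Laisk
        # conversion needs a gm, the fit needs GammaStar): resolved by tying
        # GammaStar = Ci* + Rd/gm inside the fit itself, which keeps the two
        # mutually consistent without an outer iteration.
        gamma_star = config.gamma_star
        with _stage("ethier fit", g):
            kg = k.with_gamma_star(gamma_star)
            constraint = (ci_star, rd) if ci_star is not None else None
            efits = [fit_aci_ethier(cs, kg, rd, laisk=constraint) for cs in aci]
            gm_eth = float(np.mean([f.params.gm for f in efits]))
            if ci_star is not None:
                gamma_star = ci_star + rd / gm_eth
                kg = k.with_gamma_star(gamma_star)
            row["gm_ethier"] = gm_eth
            row["GammaStar"] = gamma_star

        with _stage("variable-j", g):
            vjs = [
                gme.variable_j_curve(cs, rd=rd, gamma_star=gamma_star, alpha_beta=ab, ci_window=(config.ci_window_lo, config.ci_window_hi))
                for cs in aci
            ]
            gm_vj = float(np.mean([v.gm_mean for v in vjs]))
            row["gm_variable_j"] = gm_vj

        with _stage("operating point", g):
            ops = [v.operating for v in vjs if v.operating is not None]
            if not ops:
                raise PipelineError(f"stage 'operating point' failed for genotype {g!r}: no valid record near Ca=400")
            a_op = float(np.mean([o["a"] for o in ops]))
            gs_op = float(np.mean([o["gs"] for o in ops]))
            ci_op = float(np.mean([o["ci"] for o in ops]))
            cc_op = float(np.mean([o["cc"] for o in ops]))
            j_op = float(np.mean([o["j"] for o in ops]))
            row.update(A=a_op, gs=gs_op, Ci=ci_op, Cc=cc_op, J=j_op)
            gt = gme.total_conductance(gs_op, gm_vj)
            row["gt"] = gt

        with _stage("standard fit (A/Cc)", g):
            sfits = []
            for cs, v in zip(aci, vjs):
                ok = v.physical
                if ok.sum() >= 5:
                    sub = CurveSet(kind="aci", genotype=g, replicate=cs.replicate, records=[r for r, m in zip(cs.records, ok) if m])
                    sfits.append(fit_aci_standard(sub, kg, rd, cc=v.cc[ok]))
            if sfits:
                row["Vcmax"] = float(np.mean([f.params.vcmax for f in sfits]))
                row["Jcmax"] = float(np.mean([f.params.jcmax for f in sfits]))

        sections = [s for s in anatomy if getattr(s, "genotype", "") in (g, "")]
        if sections:
            with _stage("anatomy", g):
                leaf_an = anat.aggregate_anatomy(sections)
                part = gm_from_anatomy(leaf_an, pc)
                row["gm_anatomy"] = part.gm_mol

        with _stage("limitations", g):
            if np.isfinite(row["Vcmax"]):
                from .fvcb import BiochemParams

                p = BiochemParams(vcmax=row["Vcmax"], jcmax=row["Jcmax"], rd=rd)
                dadcc = float(dA_dCc(p, kg, cc_op))
                op = OperatingPoint(a=a_op, gs=gs_op, gm=gm_vj, gt=gt, cc=cc_op, vcmax=row["Vcmax"], dadcc=dadcc)
                ls, lm, lb = relative_limitations(op)
                row.update(ls=ls, lm=lm, lb=lb)

        if narea and g in narea:
            row["PNUE"] = pnue(a_op, narea[g])
        rows.append(row)

    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def report_to_csv(report: pd.DataFrame) -> str:
    """Deterministic text rendering of a pipeline report."""
    buf = io.StringIO()
    report.to_csv(buf, index=False)
    return buf.getvalue()
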