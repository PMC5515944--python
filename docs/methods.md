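# Methods

This note documents the models implemented in `leafdiffuse`, the defaults
chosen where the underlying methodology leaves a choice open, and what the
synthetic-data tests do and do not demonstrate about real measurements.

## Biochemical model

Net CO2 assimilation follows the FvCB scheme with a hard minimum of the two
limitation states,

    Ac = Vcmax (Cc − Γ*) / (Cc + Km),   Km = Kc (1 + O/Ko)
    Aj = J (Cc − Γ*) / (4 Cc + 8 Γ*)
    A  = min(Ac, Aj) − Rd

No co-limitation smoothing and no triose-phosphate limitation are applied.
All constants are held at their 25 °C reference values; no Arrhenius
temperature scaling is performed, because the analysis chain this package
implements reports everything at a single measurement temperature.

Default kinetics are the widely used tobacco-derived values at 25 °C:
Kc = 404.9 µmol mol⁻¹, Ko = 278.4 mmol mol⁻¹, O = 210 mmol mol⁻¹
(Km ≈ 710 µmol mol⁻¹), Γ* = 42.75 µmol mol⁻¹ as a prior when no Laisk
estimate exists.  Every constant is a config key.  Because published trait
tables in this field rarely state which kinetics were used, fitted
Vcmax/Jcmax values from different sources are comparable only in rank, and
the package treats published capacity values as recovery-style references,
never as bit targets.

The fitted "Jcmax" of both A/Ci routes is the RuBP-regeneration capacity
expressed at the measurement irradiance.  No light-response model enters
the fitting; the synthetic generator uses a non-rectangular hyperbola
(curvature θ = 0.9) only to produce realistic operating electron-transport
rates, and recovery tests compare fitted J against the generator's J at
the measurement PPFD.

## Fitting

Both fits minimise unweighted least squares with `scipy.optimize.
least_squares` (trust-region reflective, bounds keeping all parameters
positive).  The hard-min model is only piecewise smooth, so on noisy data
the optimiser may exhaust its evaluation budget (400 per start) while
chattering at the Rubisco/RuBP crossover; the best finite-cost solution is
kept and the convergence flag records whether a formal tolerance (1e-12)
was met.  The finite-gm fit is restarted from gm ∈ {0.01, 0.05, 0.1, 0.3,
1.0} mol m⁻² s⁻¹ because its likelihood is notoriously flat in gm;
estimates above 2 mol m⁻² s⁻¹ or at a bound are flagged unidentifiable
(indistinguishable from infinite mesophyll conductance).  Single-regime
curves (all points Rubisco- or all RuBP-limited) flag the unconstrained
capacity as unidentifiable instead of reporting a spurious value.

## Variable-J method and the Γ* circularity

The variable-J inversion is algebraically exact: substituting
Cc = Γ*(J + 8(A+Rd))/(J − 4(A+Rd)) into the RuBP-limited equation returns
A identically, which the property tests exercise at random points.  Points
with J ≤ 4(A+Rd), non-positive assimilation, or Cc ≥ Ci are flagged and
excluded from curve means rather than raising; the curve-level gm is the
mean over valid points inside a configurable Ci window (default
150–500 µmol mol⁻¹), and the reported operating point is the record nearest
the 400 µmol mol⁻¹ setpoint.

Γ* from the Laisk intersection requires a gm (Γ* = Ci* + Rd/gm), while
both gm estimators require Γ*.  Resolving this by alternating between the
two estimates turned out to be unreliable: on noiseless synthetic leaves
the alternation possesses multiple fixed points, and for low-gm leaves it
converges to a self-consistent but wrong (Γ*, gm) pair.  The pipeline
therefore ties Γ* to gm *inside* the finite-gm fit — the residual is
evaluated with Γ*(gm) = Ci* + Rd/gm — making the fit and the conversion
mutually consistent in a single optimisation.  With this scheme the
noiseless pipeline recovers the generating parameters exactly for three of
the four preset leaves; the fourth (gm ≈ 0.02 mol m⁻² s⁻¹ with a nearly
flat A/Ci curve) remains weakly identified, which is a genuine property of
finite-gm fitting at very low conductance, not of the implementation.

## Laisk estimation

A straight line is fitted per irradiance inside the low-Ci window (default
Ci ≤ 150 µmol mol⁻¹), and the common intersection is the least-squares
point minimising the summed squared vertical distances to all lines — a
symmetric, deterministic rule that uses all curves at once instead of
averaging pairwise intersections.  Near-parallel line families (slope
spread < 1e-4) raise an error; an intersection residual above tolerance
sets a quality flag rather than failing.

## Anatomical model

Stereology: fias = Sias/Smes and S = (l/L)·F with separate curvature
factors for spongy (default 0.98) and palisade (default 1.26) tissue,
combined as a tissue-fraction-weighted factor (default palisade share 0.5).
The defaults sit mid-way in the measured ranges (0.95–1.04 spongy,
1.18–1.35 palisade); a helper derives F from a prolate-spheroid aspect
ratio for users who prefer a geometric rule.  A single pooled F per section
is used for both Sm and Sc, since measured factors for the two have been
reported indistinguishable.

Diffusion: gm = 1/(1/gias + R·Tk/(H·gliq)), gias = Da·fias/(ΔLias·ζ) with
ΔLias = Tmes/2 and ζ = 1.57, Da = 1.51e-5 m² s⁻¹ at 25 °C.  Liquid chain
(per unit Sc, m s⁻¹): cell wall, plasmalemma, cytosol, envelope, stroma in
series, gi = Dw·pi·γi/ΔLi with Dw = 1.79e-9 m² s⁻¹, membranes fixed at
0.0035 m s⁻¹.  Defaults for the quantities the methodology leaves open:

- Henry constant H = 2941 Pa m³ mol⁻¹ (R·Tk/H ≈ 0.84 at 25 °C) — standard
  handbook dimensionless solubility for CO2.
- Cell-wall effective porosity: piecewise linear in wall thickness, 1.0 at
  ≤ 0.1 µm falling to 0.1 at ≥ 0.5 µm, p = 1 elsewhere.  This is the
  dominant uncertainty of the model and is fully configurable.
- γcyt = γstr = 0.3, γwall = 1 (cytoplasm diffusivity reduction relative to
  water, following the model lineage this implementation belongs to).
- Path lengths ΔLcw = Tcw, ΔLcyt = Tcyt, ΔLstr = Tstr/2 (carboxylation
  distributed through the stroma, mid-stroma on average); each divisor is a
  config key because the half-thickness convention for the stroma is not
  universal.

Because porosity and γ are not tightly constrained, modelled gm values are
rank-order quantities: with the defaults and the preset anatomies the model
reproduces the wild-type > mutant ordering and the published gas-phase
share (~4% of total resistance) but overestimates the absolute gm of the
published genotype means by ~20–25%.  The resistance partition uses the
component form l_i = gm·(R·Tk/H)/(gi·Sc) and l_ias = gm/gias; written this
way the shares sum to exactly 1 as an algebraic identity of the series law
(the alternative normalisation by total conductance instead of g_i breaks
the closure and is not used).  The stroma is the largest liquid-phase term
(~half or more of the cellular resistance) for all realistic inputs.

## Limitation analysis

ls, lm, lb follow the conductance-weighted partitioning with ∂A/∂Cc taken
as the Rubisco-limited analytic derivative at the operating Cc (the
standard choice for light-saturated operating points; configurable through
the kinetics).  Their sum equals 1 exactly whenever gt is the series
combination of gs and gm — an input consistency the `OperatingPoint` type
enforces at 1e-9.  The wild-type-referenced decomposition
dA/A = (dgs/gs)ls + (dgm/gm)lm + (dVcmax/Vcmax)lb is reported together
with the observed dA/A and their mismatch; the two are *not* forced to
agree, because with realistic trait contrasts the first-order decomposition
accounts for only part of the observed assimilation change.

LSD letters: one-way ANOVA pooled MSE, Fisher-LSD pairwise tests at α, and
a compact letter display assigned greedily in descending-mean order (letter
'a' marks the largest mean, the table convention), followed by a repair
pass guaranteeing that every non-significant pair shares a letter.

## Synthetic leaves

The generator solves A = FvCB(Cc), Cc = Ci − A/gm, Ci = Ca − A/gs by
bracketed root finding (Brent, xtol 1e-12) at each CO2 setpoint, using the
standard nine-point setpoint protocol (400, 200, 150, 100, 50, 400, 600,
800, 1000 µmol mol⁻¹) at 300 µmol m⁻² s⁻¹ PPFD.  Fluorescence is emitted
from the *operating* electron transport — the RuBP-limited potential when
RuBP-limited, otherwise the rate sustaining Rubisco-limited carboxylation —
so the noiseless variable-J round trip is exact by construction.  Low-O2
calibration sets use a vanishing Γ*, under which Phi_CO2 = αβ·Phi_PSII/4
holds in both limitation states and the calibration slope is exact.

Laisk families are emitted as tangent lines: exactly linear low-Ci
responses through the true (Ci*, −Rd) with per-irradiance slopes from the
RuBP-limited supply–demand slope at the compensation point.  The true FvCB
response is slightly convex over the Laisk window, so straight-line fits
to it could never recover Rd to high precision; emitting the tangent makes
"noiseless recovery is exact" a meaningful statement about the estimator
rather than about linearisation error.  Fluorescence is omitted on these
curves (the estimator uses only A and Ci).

Anatomy sections place chloroplasts as non-overlapping arcs on the
airspace-facing cell perimeter.  The appressed length per chloroplast
scales with the square root of its cross-section area, and coverage
saturates as c = cmax(1 − exp(−n·ℓ/(cmax·P))) with cmax = 0.95,
P = 60 µm exposed perimeter per cell, ℓ = 1.2·√area.  At fixed total
chloroplast volume, dividing the population into more, smaller chloroplasts
strictly raises coverage (hence Sc = c·Sm) and thins the cytosol sleeve
(Tcyt + 0.08·(1 − c) µm) — the minimal mechanism that reproduces the
few-large versus many-small contrast this analysis chain was built to
quantify.  Noise is multiplicative Gaussian on fluxes and fluorescence
signals, additive on thicknesses, multiplicative on traced lengths and
areas, truncated at physical bounds; all generators are deterministic under
a fixed seed.

The presets seed biochemistry, conductances and anatomy truth from
published mean traits of two Arabidopsis wild-types and two chloroplast
division (*arc*-type) mutants, with αβ = 0.45 (not published; chosen so the
generated operating electron transport matches the published J at
300 µmol m⁻² s⁻¹ within a few percent).

What the passing tests show — and do not.  Synthetic leaves obey the
estimators' own model exactly: there is no chamber leakage, no lateral
diffusion, no patchy stomatal closure, no temperature drift, no
Kok/light-enhanced respiration effect, and the noise is independent across
records.  Recovery at 1e-8 therefore verifies algebra and code, and the
noisy studies (2% relative noise, 200 replicates) verify statistical
robustness of the estimators under idealised errors; neither guarantees
accuracy on real gas-exchange data, where method-specific biases (most
prominently the αβ calibration and chamber leaks for variable-J, and the
gm flatness for finite-gm fitting) dominate.

## Problem sizes and runtime

The test suite and the acceptance script use nine-point CO2 response
curves, three-irradiance Laisk families of five points, 1000 random draws
for each closure identity, 200 replicates for each noisy recovery study,
30 sections for anatomy aggregation, and 25-point sensitivity sweeps per
trait.  These sizes give stable medians (Monte-Carlo error well below the
tolerances tested) while keeping the whole suite under a minute of compute
plus ~30 s for the noisy studies.

## Known limitations

- Published per-genotype means in this literature are means of
  per-replicate ratios; recomputing derived quantities (gt, Cc) from
  printed means therefore reproduces the printed derived values only to
  their last printed digit, and sometimes only within one unit of it.
- Published limitation contributions (Ls/Lm/Lb percentages) cannot be
  regenerated from published trait means under any standard kinetics; the
  package reports the decomposition alongside dA/A and their mismatch, and
  tests assert only the ordering (mesophyll > stomatal > biochemical).
- Finite-gm fitting at gm ≲ 0.02 mol m⁻² s⁻¹ is weakly identified even
  noiselessly; treat such estimates (and their tied Γ*) with caution.
- The anatomical model ignores cell-wall porosity mechanisms and aquaporin
  (facilitated transport) contributions, and its absolute gm scale is set
  by the porosity and γ defaults.
- No chamber-leakage correction is applied to gas-exchange inputs.
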