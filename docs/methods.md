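# Methods

This note records the models implemented in `dectspr`, their assumptions,
the defaults and why, and what the synthetic data does and does not emulate.

## Beam kinematics and the Bethe SPR model

The stopping-power ratio of a material relative to water is evaluated at a
fixed kinetic energy per nucleon (default 100 MeV/u):

    β² = 1 − 1/γ²,  γ = 1 + T/m_n c²,  m_n c² = 938.272 MeV
    SPR = ρₑ · L(I) / L(I_w),   L(I) = ln(2 mₑc² β² / (I(1−β²))) − β²

Using the nucleon rest energy rather than the atomic mass unit
(931.494 MeV) changes SPR by under 0.1%. The fixed-energy approximation is
justified by the near-cancellation of the energy dependence in the
stopping-number ratio: over EAN ∈ [6, 14] and RED ∈ [0.3, 2] the SPR
difference between 80 and 200 MeV/u stays below 0.5% (asserted in the test
suite). Inputs where the Bethe logarithm argument would drop below 1
(I-value too large for the beam energy) are rejected with a diagnostic
rather than silently extrapolated.

## Mean excitation energy I(Z_eff)

I is estimated from the effective atomic number by a piecewise-linear fit,
linear between knots and clamped outside. The shipped default knots are
three tissue anchors — adipose-like (6.2, 63.2 eV), water (7.45, 78.73 eV,
ICRU-90-consistent), cortical-bone-like (13.5, 106.4 eV) — built from
standard tissue reference values. The knots are *data*, not code:
institutions using a different published tissue fit substitute their own
set, and the PMMA benchmark test states its tolerance (±0.5 percentage
points on the residual) precisely because the prediction inherits the
knot-set choice. Above the bone anchor the clamp keeps metal-range EANs at
106.4 eV, which is deliberate: the fit is a *tissue* parametrisation and
extrapolating the line into metals would be less defensible than clamping.

## Two-parameter stoichiometric CT-number model

Forward CT numbers and the HLUT calibration share one cross-section
decomposition (photoelectric ~ Z^3.62, coherent ~ Z^1.86, Klein–Nishina
flat):

    u = ρₑ (k₁ Z^3.62 + k₂ Z^1.86 + k₃) / (k₁ Z_w^3.62 + k₂ Z_w^1.86 + k₃)
    CTN = 1000 (u − 1), clipped to [−1024, 3071]

k₃ is fixed at 1 (only coefficient ratios are identifiable), so (k₁, k₂)
are the two free spectrum parameters. The exponents are config constants
with these defaults. Default per-kVp coefficients are frozen constants
solved from two anchors — PMMA at its characteristic HU per tube potential
and a cortical-bone-like point at a typical bone HU (harder spectrum →
lower bone HU; the 80 kVp spectrum is the softest). The clip to the
standard Hounsfield scale is the saturation mechanism: any material whose
unclipped value exceeds 3071 HU reads exactly 3071, as on scanners without
an extended scale.

Water EAN defaults to Z_eff,w = 7.45 everywhere (configurable); vendors do
not publish the value their decompositions assume.

## Mass density from (ρₑ, Z_eff)

    ρ = ρₑ (1 + e₀ + e₁x + e₂x²),  x = (Z_eff/Z_eff,w)^m − 1,  m = 3.3

The published tissue-fitted eₙ coefficients are not reproduced here; the
shipped defaults (e₀ = 0, e₁ = 0.0221468, e₂ = −0.0016133) were fitted once
to the bundled tissue-surrogate catalog with e₀ pinned to zero so that
water maps exactly to 1 g/cm³. On the surrogates the fit is good to ~3%
worst-case; all substantive tests pass explicit coefficients, and users
with a published fit should override the defaults.

## HLUT calibration and application

Calibration follows the clinical stoichiometric procedure: (i) least-squares
fit of (k₁, k₂) to the measured CT numbers of the calibration surrogates;
(ii) forward-predict CT numbers of the reference tissues; (iii) Bethe SPR of
each reference tissue; (iv) monotone piecewise-linear nodes through
(CTN, SPR) with a forced water node (0 HU, 1.0), duplicate CTNs averaged;
(v) a clamp at `max_spr`. A non-monotone node set is an error, not silently
re-sorted. Application interpolates linearly, holds the first node's SPR
below the table, and returns `max_spr` above the last node — the
institutional "maximum SPR" behaviour that produces the large SECT
underestimation for saturated metals. Whether a clinical table inserts
extra soft-tissue/bone segment breaks is institution-specific; this package
uses one node per reference tissue plus the water anchor.

## Water-column SPR measurement

The four characteristic depths are: the grid dose maximum (plateau ties
broken to the deepest point, with a warning), the vertex of a parabola
fitted over ±2 mm around the grid maximum (window width is config), and the
distal 90%/80% crossings by linear interpolation. The distal levels
reference the *fitted* maximum dose, which is robust to single-sample noise
spikes; whether the original procedure referenced the fitted or raw maximum
is not documented, so this choice is stated here. Curves are not
renormalised — only relative levels enter. `SPR = (P_w − P_m)/d` with P the
mean of the four depths; a negative result is returned with a warning since
it signals swapped curves or geometry errors.

## Range analysis

Rays are defined in volume mm coordinates (voxel-center convention,
zero-based indices); SPR is sampled trilinearly at 0.1 mm steps (default)
and accumulated by the trapezoid rule, which is exact for the piecewise
linear fields the trilinear interpolant produces along an axis-aligned ray.
Dose at geometric depth z is the water curve evaluated at WEPL(z); R80 is
the distal-80% depth of that geometric profile. The sign convention
ΔR80 = R80(reference) − R80(test) makes an SPR *overestimate* in the test
map a *positive* shift (predicted range too short); this orientation is
pinned by an explicit fixture in the test suite.

This 1D placement deliberately replaces a pencil-beam engine: no lateral
scatter, no spot superposition, no fragmentation tail. ΔR80 values are
therefore comparable *between* SPR maps of the same geometry but not to
absolute treatment-planning-system output, which additionally carries
~1 mm delineation/voxel uncertainty.

## Synthetic data: what it emulates, what it does not

The insert phantom reproduces the study geometry (46 cm × 8 cm-radius PMMA
cylinder, 28 mm inserts with optional 6–13 mm cores stacked along the bore,
8 cm or 2 cm spacing), per-map Gaussian noise with SDs taken from the
bundled characterisation table, Hounsfield saturation, and radial sinusoidal
streaks seeded at high-Z inserts (purely phenomenological, matched to the
four-point severity proxy). The head phantom is a simplified
water-equivalent slab — the real anthropomorphic phantom's tissue-equivalent
layer stack is not published — with a 7 mm sphere or 1 mm crown cap of
restoration material on a PMMA base. Bragg curves are parametric
(Bragg–Kleeman power-law rise convolved with a Gaussian), not Monte Carlo;
helium/carbon fragmentation tails are irrelevant to distal-depth metrics at
the fidelity needed.

Consequently, passing tests demonstrate the *methods* — calibration
recovery, measurement round trips, residual arithmetic, range-shift
ordering — under controlled conditions; they do not demonstrate robustness
to real beam-hardening physics, projection-domain artifacts, or vendor
decomposition behaviour, all of which enter only through the bundled
measured tables.

Ground-truth SPR values for materials whose measured SPR was never
published (all except PMMA, cobalt-chrome and the tooth surrogates) are
literature-typical nominals, marked synthetic in `dectspr.datasets`; they
parameterise the generator only and carry no benchmark weight. The head
scenario uses 2.1 for lithium disilicate on that basis.

## Default problem sizes

Tests and the acceptance script run on reduced grids chosen as the package's
own defaults for desk-scale work: a 40×40-voxel, 40–60 mm phantom section at
1 mm isotropic voxels, a (60, 60, 100) mm head slab, a 65 mm-range beam for
head rays and a 150 mm-range beam for water-column simulations, 0.1 mm
depth grids throughout. All geometry is configurable; the full-size phantom
(320×320×460 at 1 mm) is generated identically, just larger.

## Numerical choices and degenerate inputs

- CTN clipped, never wrapped; generated volumes are validated against the
  standard scale on construction.
- ROI statistics pool voxels over retained slices (pooled-voxel SD, ddof 1);
  end-slice exclusion defaults to one slice per end. ROI diameter is
  0.70 × insert diameter (core diameter when a core exists).
- Cross-technique relative deviation uses the symmetric denominator
  (mean of the two means); a zero denominator is rejected.
- Overrides are idempotent and commute when masks are disjoint; an empty
  mask warns and no-ops.
- Determinism: every stochastic element takes a seed through
  `numpy.random.default_rng`; identical seed and configuration give
  bit-identical volumes.
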