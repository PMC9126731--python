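# Methods

`ruesim` simulates C3 crop photosynthesis from the chloroplast to the
season and uses that machinery for one purpose: to ask how much season
biomass and radiation-use efficiency (RUE) improve when individual
photosynthetic, morpho-physiological or nitrogen-uptake traits are moved
20% in their favourable direction, alone or stacked. This note documents
the model, its assumptions, the parameters that matter, and what the
synthetic test bed does and does not show.

## Leaf biochemistry

Net assimilation of a leaf is the minimum of three steady-state
limitation rates at chloroplast CO2 pressure `Cc` (all rates in
umol CO2 m-2 s-1, CO2 as partial pressures in ubar, O2 in mbar):

- Rubisco-limited: `Ac = (Cc - G*) Vcmax / (Cc + KmC (1 + O/KmO)) - Rd`
- electron-transport-limited: `Aj = (Cc - G*) J / (4 (Cc + 2 G*)) - Rd`
- TPU-limited: `Ap = (Cc - G*) 3Tp / (Cc - (1 + 4 aS) G*) - Rd`, which
  with the default glycolate-export fraction `aS = 0` reduces to the
  simplest form `3 Tp - Rd`.

Electron flux `J` follows a non-rectangular hyperbola of incident PAR
with initial slope `kappa2LL` and asymptote `Jmax`; curvature
`theta_J = 0.85` (the standard range is 0.7-0.9; the upper-mid value
reflects the near-linear light response of healthy leaves below
saturation). `kappa2LL` is not free: it is composed from leaf
absorptance `beta = 0.85`, PSII photochemical efficiency at limiting
light `Phi2LL = 0.78`, the conserved PSII:PSI efficiency ratio 0.85 and
the cyclic/pseudocyclic electron fractions (`f_cyc = 0`,
`f_pseudo = 0.05`), giving `kappa2LL = 0.340` and an apparent quantum
yield of CO2 fixation on the incident-light basis of ~0.05 at ambient
CO2 — mid-range for C3 leaves. The identity
`beta * phi_co2(Cc) = phi_co2_inc(Cc)` holds exactly and is tested.

CO2 diffusion couples the biochemistry to the atmosphere:
`Cc = Ca - A (1/gm + 1/gs)`. Stomatal conductance for CO2 uses a
Ball-Berry-Leuning closure
`gs = g0 + a1 A / ((Ca - G*) (1 + VPD/D0))` with `g0 = 0.01`,
`a1 = 12` and `D0 = 2.0 kPa`; at a top-leaf rate of ~25 umol m-2 s-1
this gives gs(H2O) ~ 0.7 mol m-2 s-1, typical of well-watered lowland
rice, whose observed range extends above 1 mol m-2 s-1. Mesophyll
conductance `gm` scales linearly with leaf N (below). The coupled
system is solved by bisection on `Cc`; the residual is strictly
decreasing, the solution unique, and the solver is verified against an
independent `scipy.optimize.brentq` root-find to 1e-4. In darkness
(A <= 0) the convention `Cc = Ci = Ca`, `gs = g0`, limitation tag
"electron" applies.

Temperature scaling uses peaked Arrhenius responses for `Vcmax`,
`Jmax` and `Tp` and plain Arrhenius for `Rd`, `KmC`, `KmO` and `G*`
(Bernacchi-type activation energies; all factors equal 1 at 25 degC).
`Tp` gets a low activation energy (25 kJ mol-1) so the TPU ceiling
remains a live constraint for warm, high-light top leaves rather than
vanishing with the first few degrees of warming. Leaf temperature is
set equal to air temperature (no energy balance), interpolated
diurnally between Tmin at sunrise and Tmax in early afternoon.

Rubisco kinetics at 25 degC: `G* = 37.5 ubar`, `KmC = 272 ubar`,
`KmO = 166 mbar`; atmospheric CO2 380 ubar, O2 210 mbar.

## Canopy scaling

Light decays with cumulative green area index following Beer-Lambert.
The beam extinction coefficient comes from Campbell's ellipsoidal
leaf-angle distribution evaluated at the current solar elevation; a
canopy-representative (diffuse) coefficient `kL` integrates black-leaf
transmission over three sky bands at a reference depth of 2 and is
reduced by sqrt(1 - sigma) for leaf scattering (sigma = 0.2). With the
baseline mean leaf inclination of 65 deg this gives `kL ~ 0.57`.

Leaf nitrogen per unit leaf area declines exponentially with cumulative
*leaf* area: `n(L) = (n0 - nb) exp(-kN L) + nb`, with base content
`nb = 0.3 g N m-2` at or below which photosynthesis is nil, and
`kN = 0.80 kL` at baseline. The top-leaf content `n0` is derived by
inverting the profile integral against the canopy's photosynthetically
active N budget. Capacities are linear in N above the base:
`Vcmax = 75 (n - nb)`, `Jmax = 100 (n - nb)`, `Tp = 5 (n - nb)`
(umol g-1 N s-1) and `gm = 0.125 (n - nb)` (mol g-1 N s-1 bar-1),
with `Rd = 0.01 Vcmax`. At the baseline operating point the top leaf
carries ~2.3-2.6 g N m-2 and a light-saturated rate of ~22-25
umol m-2 s-1, inside the observed cultivar range.

Instantaneous canopy assimilation integrates the coupled leaf model
over depth with 5-point Gaussian quadrature, splitting each layer into
a sunlit fraction `exp(-kb_black L)` receiving direct + diffuse light
and a shaded fraction receiving diffuse and scattered beam only; the
scheme conserves energy (summed layer absorption equals the closed-form
component interception) and agrees with a 500-layer trapezoid reference
within 1%. Green non-leaf tissue (sheaths, stems, panicles; 0.35 m2
per m2 of leaf) intercepts light like leaf area and photosynthesizes at
a relative efficiency of 0.5; its nitrogen sits in the
non-photosynthetic pool, not in the leaf profile. Daily totals use a
second 5-point Gaussian over the daylight period, with the daily solar
radiation spread as a half-sine and the diffuse fraction from a daily
clearness-index rule (fully diffuse below 0.07, 23% diffuse above
0.75, piecewise in between).

Consistent with canopy-optimization theory, a scan over `kN` at fixed
canopy N under diffuse light with `nb = 0` puts the optimum within one
grid step of the representative `kL`; this is a test, not an input.

## Season surrogate

The season is a fixed 110-day run (emergence day-of-year 10) with two
phases: vegetative growth to the start of grain filling at day 60, then
filling. Each day, canopy gross assimilation (g CO2 m-2) becomes
above-ground biomass via `dW = eps_conv (1 - f_resp) (30/44) gross`,
with conversion efficiency `eps_conv = 0.75` and a respired fraction
`f_resp` (calibrated, ~0.27) covering night-time and maintenance
respiration. RUE = biomass / cumulative intercepted PAR holds exactly
by construction.

Nitrogen follows a normalized logistic season uptake reaching `Numax`
(20 g N m-2) exactly at maturity, with midpoint day 50 and time scale
14 d, so most N arrives by heading as observed in irrigated rice;
scaling `Numax` scales every daily increment equally. A fraction
`f_nonphot = 0.55` of pre-filling uptake goes to non-photosynthetic
organs (stems, roots, and non-leaf green tissue N); the rest feeds the
canopy, where it is split between structural leaf N (`nb` per unit leaf
area), the active pool that drives the vertical profile, and a stem
reserve that catches any excess above a top-leaf guard of 4 g N m-2
(rarely binding). The 0.55 share keeps the leaf pool at a realistic
mid-season ~5 g N m-2 (mean SLN ~1.4); routing the classic "canopy"
share of uptake into leaves alone would force top-leaf N beyond any
observed value.

Green-area expansion is carbon-nitrogen co-limited: the carbon
potential is `SLA(t) * f_leaf(t) * dW` of new leaf area (SLA 0.030
m2 g-1 early, declining to 0.022 by filling; leaf allocation declining
linearly from `f_leaf` at emergence to zero at filling), while nitrogen
permits only as much new leaf area as can be filled at a minimum
specific leaf N of 1.0 g m-2 after paying the structural cost. Total
green area is capped at 7.5.

During filling, grain N demand is sink-driven: a fixed 0.20 g N m-2 d-1
(a ~10 g N grain requirement over 50 days), met first by concurrent
root uptake and the stem reserve; only the shortfall is remobilized
from the active canopy pool, scaled by the stay-green factor
(baseline 1.0, improved 0.8 = 20% slower remobilization). Canopy
remobilization drives senescence: green area falls by the exported N
divided by 1.1 g N per m2. This sink-driven form is what couples extra
N uptake to longer green-area duration — with a source-proportional
remobilization rule the N-uptake trait's stay-green benefit cancels by
construction. Mass and nitrogen ledgers balance exactly at every step
(tested to 1e-9).

## Synthetic weather

The study climate emulates a lowland humid-tropics station at 14.2 deg N:
daily shortwave = annual mean 17.5 MJ m-2 d-1 + a single seasonal
harmonic (amplitude 3.5, dry-season peak around day 120) + an AR(1)
anomaly (rho = 0.6, stationary s.d. 3.0), clipped to a clear-sky
envelope of 0.75 x extraterrestrial radiation; Tmax/Tmin around 31/23
degC with small harmonics and a weak positive coupling to the radiation
anomaly; relative humidity ~80%. Years are 365 days; everything is
reproducible from a single seed. The generator captures the mean
seasonality and day-to-day persistence that a multi-decade record
contributes to 31-year means; it does not reproduce typhoon extremes,
multi-day monsoon spells, or inter-annual regime shifts, so passing
results demonstrate the trait rankings under a stylized climate, not
forecasts for any particular station-year.

## Calibration and the trait experiment

Two coefficients are free: `f_resp` and `f_leaf`. They are fitted once
by Nelder-Mead (on logit-transformed coordinates, deterministic fixed
start) so that the 31-year baseline means hit the anchors
2.57 g MJ-1 RUE and 19.6 t ha-1 above-ground biomass, then frozen;
scenario runs never re-calibrate. All 19 scenarios (baseline, 12
single traits, 6 stacks) run on the same weather years (common random
numbers), and advantages are percentages of the 31-year means, not
means of per-year ratios.

The trait overrides are: capacity-per-N slopes `chi_Vcmax` 75→90 and
`chi_Jmax` 100→120; `Phi2LL` 0.78→0.85 with `kappa2LL` recomposed;
stomatal conductance x1.2; `chi_gm` 0.125→0.150; TPU limitation
removed; early-phase leaf angle 65→52 deg; `kN:kL` 0.80→0.96;
stay-green factor 0.8; early-phase SLA 0.030→0.036; non-leaf area and
efficiency coefficients x1.2; `Numax` 20→24. "Early phase" means the
first 30 days (leaf angle and SLA are early-vigour traits).

## Numerical choices

- Depth and diurnal quadrature: 5-point Gauss-Legendre each (verified
  against 500-layer / dense references within 1%).
- Coupled-leaf bisection: 40-48 iterations, residual < 1e-6 ubar;
  ties between limitation rates resolve to the "electron" tag.
- Degenerate inputs: `GAI = 0` yields zero fluxes; leaf N at or below
  `nb` yields zero capacity (and A = 0, not an error); `theta_J -> 0`
  uses the rectangular-hyperbola closed form.
- The 31 years run as a vectorized batch (all numpy); a 19-scenario
  experiment takes well under a minute on one core, and calibration
  about as long again.

## Limitations

- The season surrogate has fixed phenology, no organ-level carbon
  allocation, no root or water balance, and tracks grain only as an N
  sink; it reproduces the mechanisms the trait set acts on, nothing
  more. Biomass and RUE are its only season outputs.
- Leaf temperature equals air temperature; no photoinhibition, no
  fluctuating-light (non-steady-state) photosynthesis.
- One known shortfall: stay-green and N uptake both act by shrinking
  the same grain-N remobilization shortfall, so stacking them is
  mildly subadditive here, whereas the reference analysis reports a
  small synergy for the morpho-physiological + N-uptake combination.
  Variants that scale grain N demand with sink size restore the synergy
  but distort several single-trait responses, so the simpler form was
  kept.
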