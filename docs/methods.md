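# Methods

## Overview

`zostera-sdm` projects the occurrence of eelgrass (*Zostera marina*) across a
coastal depth grid under combinations of nutrient-load scenarios and
wave-climate realizations.  The chain is:

1. **Light predictor (PFD).**  Surface irradiance is converted to
   photosynthetic photon flux density and attenuated to canopy height with
   the Beer–Lambert law; the attenuation coefficient comes from Secchi depth.
2. **Wave predictor (MOV).**  Sea states are converted to the maximum
   orbital velocity at the seabed via Rayleigh maximum-wave statistics, a
   depth-limited breaking cap, an empirical period–height relation and the
   linear-wave-theory dispersion relation.
3. **Occurrence model.**  A binomial GAM with logit link and one cubic
   spline smooth (4 df) per predictor, fitted on a class-balanced sample so
   predicted probability reads as expected coverage.
4. **Scenario projection.**  2007–2066 is tiled into twelve 5-year slices;
   predictors are averaged per slice and the fitted model is applied to each
   run of the scenario matrix (92 runs for 2 nutrient × 4 wave paths).
   Outputs are probability maps, total expected area with 30-year running
   means, depth-binned coverage change, and ceteris-paribus attribution of
   areal change to each predictor.

## Light availability

PFD at 0.5 m above the sea floor (top of the canopy) is
`I_z = I_0 · exp(−k·z)` with `z = max(d − 0.5, 0)`.  Choices:

- **Irradiance→PFD factor 4.15** (µmol photons m⁻² s⁻¹ per W m⁻²), the
  standard broadband conversion for daylight over water.
- **Secchi→attenuation: k = 1.7 / SD** (Poole–Atkins).  The constant is a
  config knob (`secchi_coefficient`); 1.7 is the classical coastal value.
- **Monthly climatology.**  A single representative station's monthly mean
  irradiance is applied to the whole grid (12-value config vector; defaults
  approximate a southwestern Baltic station near 54.5° N).  Because the
  attenuation field is annual, averaging Beer's law over months equals one
  evaluation at the month-mean surface PFD; a month subset (e.g. growing
  season) can be selected in config.
- **No surface corrections.**  Plane-surface optics; the ~6 % air–water
  reflection loss is available as `reflection_loss` but off by default, so
  absolute light levels are slightly optimistic.
- **Cells shallower than 0.5 m** clamp the light path at zero (surface PFD).

## Hydrodynamic exposure

Per cell and year: `H_max = 1.86·H_m0` (largest of N = 1000
Rayleigh-distributed waves, `sqrt(ln N / 2)`; the constant is asserted
against its Rayleigh derivation at load), capped at the local depth
(`H_max ≤ d`), period `T_Hmax = 0.83·H_max + 3.17`, wavelength from
`L = (g T² / 2π) tanh(2π d / L)`, and near-bed velocity
`U = π H_max / (T sinh(2π d / L))`.

- **Cap ordering.**  The breaking cap is applied *before* the period
  relation, so the period belongs to the physically realisable wave.
- **Dispersion solver.**  Vectorised Newton iteration on the wavenumber
  started from the deep-water value, with a bisection fallback on
  `[10⁻³ m, g T²/2π]`; absolute tolerance 10⁻⁶ m on the wavelength, 200
  iteration cap, and a hard residual check that raises on failure.
- **Slice statistic.**  The 5-year slice value is the arithmetic mean of the
  yearly MOV; a 90th-percentile option exists for storm-weighted sensitivity
  runs.  The mean wave period `T_m02` is carried through the data model and
  can replace `T_Hmax` via `use_tm02=True` for sensitivity analyses, but the
  default chain uses `T_Hmax`.

## Occurrence model

- **Balancing.**  The majority class is subsampled without replacement to
  the minority size.  With training prevalence ½, the logistic output is
  read directly as probability of plant encounter (expected coverage).
- **Smooths.**  Per predictor, a cubic B-spline basis with `df = 4` columns
  (one interior knot at the median; first basis column dropped; columns
  centred on their training means so the intercept is the linear predictor
  at average conditions).  Outside the training range the basis continues
  linearly (first-order Taylor expansion from the boundary), and prediction
  there emits a warning rather than failing.
- **Fitting.**  Penalized IRLS with a small ridge (10⁻⁶) on the spline
  coefficients; the ridge keeps the solve well-posed even under complete
  separation while leaving ~4 effective df per term.  Convergence: relative
  deviance change below 10⁻⁶.  The coefficient covariance
  `(XᵀWX + λI)⁻¹` provides the pointwise 95 % bands (±1.96 SE) of the
  response curves.  With the ridge sent to ~0 the fit matches an
  unpenalized GLM on the same design to numerical precision (tested against
  statsmodels).
- **Contributions.**  Drop-one refits: a predictor's contribution is the
  explained deviance lost when it is removed, normalized across predictors
  to sum to 100 %.
- **Validation.**  Stratified, seeded 5-fold cross-validation of the
  held-out AUC.  AUC is the rank-based Mann–Whitney statistic (ties count
  half), identical to the area under the empirical ROC curve.  The
  conventional discrimination labels (0.5 none, <0.7 low, 0.7–0.8
  acceptable, 0.8–0.9 excellent) are exposed as a pure labelling function.

## Scenario pipeline

- **Slices and runs.**  Twelve inclusive 5-year slices tile 2007–2066; the
  baseline slice (2007–2011) precedes the divergence of the nutrient paths
  and therefore contributes one run per wave realization; every later slice
  contributes one run per nutrient × wave pair (92 runs in the default
  matrix).  Ordering (slice, nutrient, wave) is deterministic.
- **Total area** is the expectation Σ p · cell area (km²), consistent with
  the coverage reading of p; a 0.5-threshold alternative is a config
  switch.  The single baseline reference map for difference maps is the mean
  across the per-realization baseline runs (configurable).
- **Running means.**  Slice areas are expanded to an annual series (each
  year inherits its slice value) and smoothed with a centred 30-year window,
  truncated at the series edges.
- **Depth profile.**  Percent change of mean coverage per 1-m depth bin over
  (0, 12] m, with the baseline mean floored at 10⁻⁶ in the denominator;
  empty bins carry NaN.
- **Attribution.**  Projections are rerun with one predictor frozen at its
  baseline-slice field; a predictor's share is 100 × (change with only it
  varying) / (change with both varying), per nutrient × wave combination.
  When the total change is negligible the shares are flagged undefined
  instead of silently divided; the interaction residual (total minus the sum
  of single-predictor changes) is reported alongside.

## Synthetic study conditions

The generator emulates the statistical structure of the real inputs
(composite bathymetry, biogeochemical Secchi projections, spectral-wave sea
states, video-transect survey) without simulating their physics:

- **Bathymetry**: 100 × 120 grid of 100 m cells, a 0.13 m-per-row
  shore-normal ramp (≈13 m at the offshore edge, so the deepest rows fall
  outside the 12 m model domain), sinusoidal bay indentations that create
  land near shore, and small seeded relief.  In-scope area ≈ 107 km².
- **Water clarity**: base Secchi depth 4 m plus 0.5 m offshore gain.  BSAP
  ramps up linearly 2012–2020 to a +2 m plateau (clarity restored with the
  nutrient-load reduction); BAU stays flat apart from a −0.5 m Gaussian
  mid-century dip centred on 2040 (climate-driven chlorophyll increase) and
  year-to-year noise (SD 0.15 m) shared between scenarios, which makes the
  baseline slice scenario-independent by construction.
- **Sea states**: mean H_m0 0.6 m offshore (75 % of it at the shore), an
  alongshore sheltered/exposed modulation (±50 %, two sectors, seeded phase)
  so exposure is not a pure function of depth, per-realization linear trends
  (−0.08, −0.05, +0.05, −0.01 % yr⁻¹ for A1B_1, A1B_2, B1_1, B1_2 — signs
  and magnitudes follow the published per-century MOV changes of these
  realizations) and 5 % interannual noise.  `T_m02 = 2.8 + 1.4·√H_m0`.
- **Survey**: 7150 cells sampled uniformly without replacement from the
  in-scope domain; presence ~ Bernoulli with
  `logit p = β₀ + f(PFD) + g(MOV)`, where f is linear (0.01 logit per µmol)
  up to saturation at 350 µmol photons m⁻² s⁻¹ and zero at 150, and g
  declines at 6 logit per m s⁻¹ through half-occurrence at 0.4 m s⁻¹,
  flattening above 1 m s⁻¹.  The light term is recentred on its mean over
  the sampled cells (the stored truth records the offset), which keeps the
  wave threshold the marginal half-occurrence point and the survey
  prevalence near one half.

What the generator does **not** emulate: transect spatial autocorrelation
(cells are sampled independently), tides, currents, fetch geometry, spectral
wave physics, sediment–light feedback, and biotic interactions.  Passing
tests therefore demonstrate that the pipeline recovers a known response and
propagates scenario forcing correctly — not that the fitted curves would be
unbiased on autocorrelated field transects.

## Problem sizes and numerical choices

The default synthetic domain (12 000 cells, 60 forcing years, 92 runs,
7150-record survey) runs end to end in well under a minute on one core;
tests use the same conditions with reduced grids where the full domain adds
nothing.  Seeds enter every stochastic step explicitly (generators, survey,
balancing, fold assignment); reruns with the same config and seed are
bit-identical.  Degenerate inputs fail loudly: land cells in the light/wave
chain, single-class samples, constant predictors, non-divisible time spans,
unknown scenario labels, and non-convergent solves all raise.

## Known limitations

- The fitted smooths extrapolate linearly beyond the training predictor
  range; projections that push far outside it (e.g. extreme clarity gains)
  should be read with caution — the warning channel flags this.
- Expected area weights every cell by its probability; under strong spatial
  clustering of p the 0.5-threshold area can differ noticeably.
- The ceteris-paribus shares need not sum to 100 % (the interaction residual
  is reported); with near-zero total change the shares are undefined.
- A single irradiance climatology for the whole grid ignores latitudinal and
  nearshore shading gradients.
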