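# zostera-sdm

Scenario projection of eelgrass (*Zostera marina*) occurrence along a
coastal depth gradient, for ecologists and coastal managers who want to ask:
*if nutrient loads are cut while the wave climate changes, where and by how
much does eelgrass habitat expand?*

The package couples two physically derived predictors to a species
distribution model and projects it over a nutrient × wave scenario matrix:

- **Light (PFD)** — photosynthetic photon flux density at canopy height
  (0.5 m above the sea floor) from the Beer–Lambert law,
  `I_z = I₀·e^(−k·z)`, with `k = 1.7/SD` from Secchi depth and
  `PFD = 4.15 × irradiance (W m⁻²)`.
- **Wave exposure (MOV)** — maximum orbital velocity at the seabed from
  linear wave theory: `H_max = 1.86·H_m0` (largest of N = 1000 Rayleigh
  waves), capped at the local depth (`H_max/d ≤ 1`),
  `T_Hmax = 0.83·H_max + 3.17`, wavelength from
  `L = (gT²/2π)·tanh(2πd/L)`, and `U = πH/(T·sinh(2πd/L))`.
- **Occurrence model** — a binomial GAM (logit link, one 4-df cubic-spline
  smooth per predictor) fitted by penalized IRLS on a class-balanced sample,
  so the predicted probability reads directly as expected coverage.
  Validation is stratified 5-fold cross-validated ROC/AUC; predictor
  importance is normalized drop-one explained deviance.
- **Projection** — twelve 5-year slices over 2007–2066; the baseline slice
  runs once per wave realization and every later slice once per
  nutrient × wave pair (92 runs for 2 nutrient scenarios — BSAP
  nutrient abatement vs business as usual — and 4 wave realizations).
  Summaries: total expected area (Σ p·cell area, km²) with 30-year running
  means, difference maps, per-depth-bin coverage change, and
  ceteris-paribus attribution of areal change to light vs waves.

A fully seeded synthetic-domain module generates bathymetry, Secchi and
sea-state forcing, and Bernoulli survey records from a known response, so
the whole pipeline is testable end to end; real data enter through ESRI
ASCII grids, CSV observations and NetCDF forcing stacks.

## Worked example

```sh
zostera --seed 1 --outdir demo all
```

runs the full synthetic experiment (generate domain and forcing, draw a
7150-record survey, balance, fit, cross-validate, project all 92 runs,
summarise) and prints:

```
CV AUC 0.751 +- 0.011; final-slice area change by scenario (%):
nutrient
BAU      1.582891
BSAP    20.445996
```

Reading: the balanced occurrence model discriminates presences from absences
with acceptable skill (held-out AUC 0.75); by the 2062–2066 slice the
business-as-usual scenario stays within ~2 % of the ~54 km² baseline
eelgrass area while nutrient abatement expands it by ~20 %, concentrated at
4–8 m depth where improved water clarity relieves light limitation.
`demo/` then holds the run maps (`maps/run_*.asc`), `areas.csv`,
`depth_profile.csv`, `attribution.csv`, `contributions.csv`, the serialized
model (`model.json`) and a run manifest.  The same steps are available
separately (`simulate`, `predictors`, `fit`, `project`, `summarize`) for
file-based workflows, and from Python:

```python
from zostera.experiment import run_experiment
result = run_experiment(seed=1)
result.depth_profile("BSAP", "A1B_1")   # per-bin coverage change
result.attribution.table                # ceteris-paribus shares
```

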