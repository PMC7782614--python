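"""Seeded synthetic inputs for the eelgrass scenario analysis.

Real applications of the pipeline consume a composite bathymetry, Secchi-depth
projections from a biogeochemical model and sea-state projections from a
spectral wave model.  This module generates statistically analogous inputs on
a synthetic coastal grid: a shore-parallel depth ramp indented by shallow
bays, per-year Secchi fields following either a nutrient-abatement ramp
(BSAP) or stagnating loads with a mid-century clarity dip (BAU), per-year
sea states for four wave-climate realizations differing in long-term trend,
and Bernoulli presence/absence surveys drawn from a known saturating light
response and declining wave-exposure response.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .domain import (
    NUTRIENT_SCENARIOS,
    WAVE_REALIZATIONS,
    DepthGrid,
    ObservationSet,
    ResponseTruth,
    ScenarioFields,
)

#: Modelled period (inclusive) of the scenario analysis.
FIRST_YEAR = 2007
LAST_YEAR = 2066


@dataclass(frozen=True)
class BathymetryConfig:
    """Synthetic coastal bathymetry: a depth ramp with bay indentations.

    ``shore_slope`` is metres of depth gained per row moving offshore;
    ``bay_amplitude`` scales alongshore depth perturbations (which may raise
    nearshore cells above water, creating land); ``roughness`` adds
    small-scale seeded relief.
    """

    n_rows: int = 100
    n_cols: int = 120
    cell_size: float = 100.0
    shore_slope: float = 0.13
    bay_amplitude: float = 1.5
    n_bays: int = 3
    roughness: float = 0.15


@dataclass(frozen=True)
class SecchiConfig:
    """Water-clarity trajectories for the two nutrient-load scenarios.

    BSAP: clarity improves linearly while loads are reduced
    (``ramp_start``..``ramp_end``) and plateaus ``bsap_improvement`` metres
    above the baseline from ``ramp_end + 1`` on.  BAU: flat mean with a
    Gaussian mid-century clarity dip (``bau_oscillation`` metres around
    ``oscillation_year``) emulating climate-driven chlorophyll increases.
    """

    base: float = 4.0
    offshore_gain: float = 0.5
    bsap_improvement: float = 2.0
    ramp_start: int = 2012
    ramp_end: int = 2020
    bau_oscillation: float = 0.5
    oscillation_year: int = 2040
    oscillation_width: float = 8.0
    interannual_sd: float = 0.15
    min_secchi: float = 0.2


@dataclass(frozen=True)
class WaveClimateConfig:
    """Sea-state climatology and per-realization long-term trends.

    ``hm0_base`` is the offshore-edge mean significant wave height;
    nearshore cells see ``hm0_shore_fraction`` of it.  ``alongshore_amp``
    modulates exposure along the coast (sheltered bays vs exposed headlands,
    ``alongshore_sectors`` sheltered/exposed pairs with a seeded phase) so
    that wave exposure is not a pure function of depth.  Realizations share
    the spatial pattern and differ in the linear trend (fraction per year)
    and their interannual noise stream.  The mean period is tied to wave
    height through ``tm02 = tm02_intercept + tm02_slope * sqrt(hm0)``.
    """

    hm0_base: float = 0.6
    hm0_shore_fraction: float = 0.75
    alongshore_amp: float = 0.5
    alongshore_sectors: int = 2
    trend_per_year: Mapping[str, float] = field(
        default_factory=lambda: {
            "A1B_1": -0.0008,
            "A1B_2": -0.0005,
            "B1_1": 0.0005,
            "B1_2": -0.0001,
        }
    )
    interannual_sd: float = 0.05
    tm02_intercept: float = 2.8
    tm02_slope: float = 1.4


def _offshore_fraction(n_rows: int) -> np.ndarray:
    """Offshore-distance proxy per row: 0 at the shoreline row, 1 at the edge."""
    if n_rows == 1:
        return np.zeros(1)
    return np.arange(n_rows) / (n_rows - 1)


def make_bathymetry(config: BathymetryConfig, seed: int) -> DepthGrid:
    """Generate a synthetic coastal depth grid (row 0 at the shoreline)."""
    if config.n_rows < 1 or config.n_cols < 1:
        raise ValueError("grid dimensions must be positive")
    if config.shore_slope <= 0:
        raise ValueError("shore_slope must be positive")
    if config.cell_size <= 0:
        raise ValueError("cell_size must be positive")
    rng = np.random.default_rng(seed)
    rows = np.arange(1, config.n_rows + 1)[:, None]
    depth = config.shore_slope * rows * np.ones((1, config.n_cols))
    if config.bay_amplitude > 0 and config.n_bays > 0:
        phase = rng.uniform(0, 2 * np.pi)
        alongshore = np.sin(
            2 * np.pi * config.n_bays * np.arange(config.n_cols) / config.n_cols + phase
        )
        # bays are shallow indentations that fade offshore
        taper = np.exp(-np.arange(config.n_rows) / max(config.n_rows / 4.0, 1.0))
        depth = depth - config.bay_amplitude * taper[:, None] * alongshore[None, :]
    if config.roughness > 0:
        depth = depth + rng.normal(0.0, config.roughness, size=depth.shape)
    return DepthGrid(depth=depth, cell_size=config.cell_size)


def _check_years(years: Sequence[int]) -> tuple[int, ...]:
    years = tuple(int(y) for y in years)
    if not years:
        raise ValueError("at least one year required")
    if min(years) < FIRST_YEAR or max(years) > LAST_YEAR:
        raise ValueError(f"years must lie within {FIRST_YEAR}-{LAST_YEAR}")
    return years


def secchi_trajectory(year: int, nutrient_scenario: str, config: SecchiConfig) -> float:
    """Domain-wide Secchi offset (m) of a scenario for one year (noise-free)."""
    if nutrient_scenario == "BSAP":
        span = config.ramp_end + 1 - (config.ramp_start - 1)
        frac = np.clip((year - (config.ramp_start - 1)) / span, 0.0, 1.0)
        return config.bsap_improvement * float(frac)
    if nutrient_scenario == "BAU":
        z = (year - config.oscillation_year) / config.oscillation_width
        return -config.bau_oscillation * float(np.exp(-0.5 * z * z))
    raise ValueError(f"unknown nutrient scenario {nutrient_scenario!r}")


def make_secchi_series(
    grid: DepthGrid,
    nutrient_scenario: str,
    years: Sequence[int],
    config: SecchiConfig = SecchiConfig(),
    seed: int = 0,
) -> np.ndarray:
    """Per-year Secchi-depth fields, shape ``(n_years, n_rows, n_cols)``.

    The interannual noise stream depends only on (years, seed), never on the
    scenario label, so the two nutrient scenarios are identical until their
    deterministic trajectories diverge in ``ramp_start`` — which makes the
    baseline slice scenario-independent by construction.
    """
    if nutrient_scenario not in NUTRIENT_SCENARIOS:
        raise ValueError(f"unknown nutrient scenario {nutrient_scenario!r}")
    years = _check_years(years)
    rng = np.random.default_rng([int(seed), 11])
    noise = rng.normal(0.0, 1.0, size=len(years)) * config.interannual_sd
    base = config.base + config.offshore_gain * _offshore_fraction(grid.n_rows)
    base_field = np.broadcast_to(base[:, None], grid.shape)
    out = np.empty((len(years),) + grid.shape)
    for i, year in enumerate(years):
        offset = secchi_trajectory(year, nutrient_scenario, config)
        offset = 0.0 if year < config.ramp_start else offset
        out[i] = np.maximum(base_field + offset + noise[i], config.min_secchi)
    return out


def make_wave_series(
    grid: DepthGrid,
    wave_realization: str,
    years: Sequence[int],
    config: WaveClimateConfig = WaveClimateConfig(),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-year (H_m0, T_m02) fields for one wave-climate realization.

    H_m0 scales an offshore exposure gradient by a realization-specific
    linear trend plus seeded interannual noise; realizations differ only in
    trend and noise stream.
    """
    if wave_realization not in config.trend_per_year:
        raise ValueError(f"unknown wave realization {wave_realization!r}")
    years = _check_years(years)
    realization_index = sorted(config.trend_per_year).index(wave_realization)
    rng = np.random.default_rng([int(seed), 23, realization_index])
    noise = rng.normal(0.0, 1.0, size=len(years)) * config.interannual_sd
    trend = config.trend_per_year[wave_realization]
    exposure = config.hm0_base * (
        config.hm0_shore_fraction
        + (1.0 - config.hm0_shore_fraction) * _offshore_fraction(grid.n_rows)
    )
    exposure_field = np.broadcast_to(exposure[:, None], grid.shape).copy()
    if config.alongshore_amp > 0 and config.alongshore_sectors > 0:
        # sheltered-to-exposed coastline sectors, shared by all realizations
        phase = np.random.default_rng([int(seed), 29]).uniform(0, 2 * np.pi)
        sectors = 1.0 + config.alongshore_amp * np.sin(
            2 * np.pi * config.alongshore_sectors * np.arange(grid.n_cols) / grid.n_cols
            + phase
        )
        exposure_field = exposure_field * sectors[None, :]
    hm0 = np.empty((len(years),) + grid.shape)
    for i, year in enumerate(years):
        factor = (1.0 + trend * (year - FIRST_YEAR)) * (1.0 + noise[i])
        hm0[i] = np.maximum(exposure_field * factor, 0.0)
    tm02 = config.tm02_intercept + config.tm02_slope * np.sqrt(hm0)
    return hm0, tm02


def make_scenario_fields(
    grid: DepthGrid,
    nutrient_scenario: str,
    wave_realization: str,
    years: Sequence[int],
    secchi_config: SecchiConfig = SecchiConfig(),
    wave_config: WaveClimateConfig = WaveClimateConfig(),
    seed: int = 0,
) -> ScenarioFields:
    """Assemble the full forcing for one nutrient x wave combination."""
    secchi = make_secchi_series(grid, nutrient_scenario, years, secchi_config, seed)
    hm0, tm02 = make_wave_series(grid, wave_realization, years, wave_config, seed)
    fields = ScenarioFields(
        years=tuple(years),
        nutrient_scenario=nutrient_scenario,
        wave_realization=wave_realization,
        secchi=secchi,
        hm0=hm0,
        tm02=tm02,
    )
    fields.validate(grid)
    return fields


def sample_observations(
    grid: DepthGrid,
    pfd_field: np.ndarray,
    mov_field: np.ndarray,
    truth: ResponseTruth = ResponseTruth(),
    n: int = 7150,
    seed: int = 0,
    survey_years: Sequence[int] = (2010, 2011),
    with_replacement: bool = False,
    center_light_term: bool = True,
) -> ObservationSet:
    """Draw a synthetic presence/absence survey from baseline predictor fields.

    Cells are sampled uniformly from the in-scope domain (without replacement
    by default); each receives ``presence ~ Bernoulli(p_true)`` with
    ``logit p_true = intercept + f(PFD) + g(MOV)`` from ``truth``.  With
    ``center_light_term`` the light term is recentred on its mean over the
    sampled cells (the recorded truth carries the applied offset), keeping
    the wave threshold the marginal half-occurrence point and the survey
    prevalence near one half.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    pfd_field = np.asarray(pfd_field, dtype=float)
    mov_field = np.asarray(mov_field, dtype=float)
    if pfd_field.shape != grid.shape or mov_field.shape != grid.shape:
        raise ValueError("predictor fields must match the grid")
    scope = grid.in_scope_mask & np.isfinite(pfd_field) & np.isfinite(mov_field)
    flat = np.flatnonzero(scope)
    if not with_replacement and n > flat.size:
        raise ValueError(f"cannot sample {n} distinct cells from {flat.size} in scope")
    rng = np.random.default_rng([int(seed), 37])
    chosen = rng.choice(flat, size=n, replace=with_replacement)
    row, col = np.unravel_index(chosen, grid.shape)
    pfd = pfd_field[row, col]
    mov = mov_field[row, col]
    if center_light_term:
        offset = float(
            truth.pfd_slope
            * (np.minimum(pfd, truth.pfd_saturation) - truth.pfd_reference).mean()
        )
        truth = replace(truth, light_offset=truth.light_offset + offset)
    p_true = truth.probability(pfd, mov)
    presence = rng.binomial(1, p_true)
    return ObservationSet(
        row=row,
        col=col,
        presence=presence,
        survey_years=tuple(int(y) for y in survey_years),
        pfd=pfd,
        mov=mov,
        truth=truth,
    )
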