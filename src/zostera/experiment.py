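"""End-to-end orchestration of the synthetic scenario experiment.

``run_experiment`` performs the whole chain: generate the synthetic domain
and forcing, derive baseline predictors, draw the survey, fit and
cross-validate the balanced-prevalence occurrence model, project the full
run matrix and summarise areas, depth profiles and predictor attribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pipeline, sdm, synthetic
from .config import ExperimentConfig
from .domain import DepthGrid, ObservationSet, ScenarioFields, training_table
from .pipeline import BASELINE, AttributionResult, RunSpec, TimeSlice
from .sdm import BalancedSample, CVResult, FittedSDM


@dataclass
class ExperimentResult:
    """Everything one synthetic experiment produces."""

    config: ExperimentConfig
    seed: int
    grid: DepthGrid
    fields_by: dict[tuple[str, str], ScenarioFields]
    observations: ObservationSet
    sample: BalancedSample
    model: FittedSDM
    cv: CVResult
    contributions: pd.Series
    slices: list[TimeSlice]
    plan: list[RunSpec]
    maps: dict[RunSpec, np.ndarray]
    areas: pd.DataFrame
    attribution: AttributionResult

    @property
    def baseline_slice(self) -> TimeSlice:
        return self.slices[0]

    @property
    def final_slice(self) -> TimeSlice:
        return self.slices[-1]

    def final_map(self, nutrient: str, wave: str) -> np.ndarray:
        return self.maps[RunSpec(self.final_slice, nutrient, wave)]

    def baseline_map(self, wave: str) -> np.ndarray:
        return self.maps[RunSpec(self.baseline_slice, BASELINE, wave)]

    def depth_profile(self, nutrient: str, wave: str, bin_width: float = 1.0) -> pd.DataFrame:
        return pipeline.depth_binned_change(
            self.baseline_map(wave), self.final_map(nutrient, wave), self.grid, bin_width
        )

    def annual_area_series(self, nutrient: str, wave: str) -> pd.Series:
        """30-year running mean of the slice-wise total area, expanded to years."""
        sub = self.areas[
            (self.areas["wave"] == wave)
            & (self.areas["nutrient"].isin([nutrient, BASELINE]))
        ]
        slice_values = {
            TimeSlice(int(r.start_year), int(r.end_year)): float(r.area_km2)
            for r in sub.itertuples()
        }
        annual = pipeline.expand_slices_to_annual(slice_values)
        return pipeline.running_mean_30y(annual)


def build_forcing(
    config: ExperimentConfig, grid: DepthGrid, seed: int
) -> dict[tuple[str, str], ScenarioFields]:
    fields_by = {}
    for nut in config.nutrient_scenarios:
        for wave in config.wave_realizations:
            fields_by[(nut, wave)] = synthetic.make_scenario_fields(
                grid, nut, wave, config.years, config.secchi, config.waves, seed
            )
    return fields_by


def baseline_survey(
    config: ExperimentConfig,
    grid: DepthGrid,
    fields_by: dict[tuple[str, str], ScenarioFields],
    seed: int,
) -> tuple[ObservationSet, dict[str, np.ndarray]]:
    """Draw the survey from baseline-slice predictors (forcing averaged
    across wave realizations, as a survey integrates the ambient climate)."""
    baseline_slice = pipeline.make_time_slices(
        config.start_year, config.end_year, config.slice_width
    )[0]
    preds_per_wave = []
    for wave in config.wave_realizations:
        fields = fields_by[(config.nutrient_scenarios[0], wave)]
        preds_per_wave.append(
            pipeline.slice_predictor_fields(
                grid, fields, baseline_slice, config.irradiance_wm2
            )
        )
    preds = {
        name: np.mean([p[name] for p in preds_per_wave], axis=0)
        if len(preds_per_wave) > 1
        else preds_per_wave[0][name]
        for name in ("pfd", "mov")
    }
    obs = synthetic.sample_observations(
        grid,
        preds["pfd"],
        preds["mov"],
        truth=config.truth,
        n=config.n_observations,
        seed=seed,
    )
    return obs, preds


def run_experiment(config: ExperimentConfig = ExperimentConfig(), seed: int = 0) -> ExperimentResult:
    """Run the full synthetic analysis for one seed."""
    grid = synthetic.make_bathymetry(config.bathymetry, seed)
    fields_by = build_forcing(config, grid, seed)
    obs, preds = baseline_survey(config, grid, fields_by, seed)
    table = training_table(obs, preds)
    sample = sdm.balance_prevalence(table, seed=seed)
    model = sdm.fit_gam(sample, df=config.smooth_df)
    cv = sdm.crossvalidate_auc(sample, k=config.cv_folds, seed=seed, df=config.smooth_df)
    contributions = sdm.predictor_contributions(sample, model, df=config.smooth_df)
    slices = pipeline.make_time_slices(config.start_year, config.end_year, config.slice_width)
    plan = pipeline.enumerate_runs(slices, config.nutrient_scenarios, config.wave_realizations)
    maps = pipeline.run_projection(
        model, grid, fields_by, plan, config.irradiance_wm2
    )
    areas = pipeline.area_series(maps, grid)
    attribution = pipeline.ceteris_paribus(
        model,
        grid,
        fields_by,
        slices,
        config.nutrient_scenarios,
        config.wave_realizations,
        config.irradiance_wm2,
    )
    return ExperimentResult(
        config=config,
        seed=seed,
        grid=grid,
        fields_by=fields_by,
        observations=obs,
        sample=sample,
        model=model,
        cv=cv,
        contributions=contributions,
        slices=slices,
        plan=plan,
        maps=maps,
        areas=areas,
        attribution=attribution,
    )
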