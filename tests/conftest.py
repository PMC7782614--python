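import dataclasses

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from zostera import (
    BathymetryConfig,
    DepthGrid,
    ExperimentConfig,
    balance_prevalence,
    fit_gam,
    make_bathymetry,
    training_table,
)
from zostera.experiment import baseline_survey, build_forcing, run_experiment


@pytest.fixture
def ramp_grid() -> DepthGrid:
    """Plain shore-normal depth ramp, 10 rows x 8 cols, 1.2 m per row."""
    cfg = BathymetryConfig(
        n_rows=10, n_cols=8, shore_slope=1.2, bay_amplitude=0.0, roughness=0.0
    )
    return make_bathymetry(cfg, seed=0)


@pytest.fixture(scope="session")
def default_experiment():
    """Full synthetic experiment under the default study conditions."""
    return run_experiment(ExperimentConfig(), seed=0)


@pytest.fixture(scope="session")
def recovery_fit():
    """Balanced sample and fitted model from a 5000-record synthetic survey."""
    cfg = dataclasses.replace(ExperimentConfig(), n_observations=5000)
    grid = make_bathymetry(cfg.bathymetry, seed=0)
    fields_by = build_forcing(cfg, grid, seed=0)
    obs, preds = baseline_survey(cfg, grid, fields_by, seed=0)
    table = training_table(obs, preds)
    sample = balance_prevalence(table, seed=0)
    model = fit_gam(sample)
    return obs, sample, model
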