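"""Experiment configuration: one document holding every knob and default.

The defaults define the synthetic study conditions: a 100 x 120 grid of 100 m
cells sloping to ~13 m, a 2 m BSAP clarity improvement ramped over
2012-2020, four wave realizations with mild opposing trends, and a survey of
7150 presence/absence records drawn from a saturating light response
(saturation 350 umol photons m-2 s-1, zero point 150) and a declining
wave-exposure response crossing half-occurrence at 0.4 m s-1.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import yaml

from .domain import NUTRIENT_SCENARIOS, WAVE_REALIZATIONS, ResponseTruth
from .light import DEFAULT_IRRADIANCE_WM2
from .synthetic import (
    FIRST_YEAR,
    LAST_YEAR,
    BathymetryConfig,
    SecchiConfig,
    WaveClimateConfig,
)


@dataclass(frozen=True)
class ExperimentConfig:
    """Full configuration of a synthetic scenario experiment."""

    bathymetry: BathymetryConfig = field(default_factory=BathymetryConfig)
    secchi: SecchiConfig = field(default_factory=SecchiConfig)
    waves: WaveClimateConfig = field(default_factory=WaveClimateConfig)
    truth: ResponseTruth = field(default_factory=ResponseTruth)
    irradiance_wm2: tuple[float, ...] = DEFAULT_IRRADIANCE_WM2
    start_year: int = FIRST_YEAR
    end_year: int = LAST_YEAR
    slice_width: int = 5
    nutrient_scenarios: tuple[str, ...] = NUTRIENT_SCENARIOS
    wave_realizations: tuple[str, ...] = WAVE_REALIZATIONS
    n_observations: int = 7150
    cv_folds: int = 5
    smooth_df: int = 4

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(range(self.start_year, self.end_year + 1))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["waves"]["trend_per_year"] = dict(d["waves"]["trend_per_year"])
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        kwargs = dict(d)
        for key, sub in (
            ("bathymetry", BathymetryConfig),
            ("secchi", SecchiConfig),
            ("waves", WaveClimateConfig),
            ("truth", ResponseTruth),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        for key in ("irradiance_wm2", "nutrient_scenarios", "wave_realizations"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _plain(obj):
    """Recursively coerce to YAML-safe builtin types."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj
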