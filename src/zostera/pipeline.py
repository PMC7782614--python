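"""Scenario projection: time slices, run matrix, maps and summaries.

The modelled period 2007-2066 is tiled into twelve 5-year slices; the first
(2007-2011) is the baseline.  The baseline contributes one run per wave
realization (nutrient paths have not yet diverged), every later slice one run
per nutrient x wave combination — 92 runs for 12 slices, 2 nutrient scenarios
and 4 wave realizations.  Per run, 5-year-mean light (PFD) and wave-exposure
(MOV) fields feed the fitted occurrence model; the resulting probability maps
are summarised as total expected area, difference maps against baseline,
depth-binned coverage change and ceteris-paribus attribution of the areal
change to each predictor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import light, waves
from .domain import DepthGrid, ScenarioFields
from .sdm import FittedSDM, predict_probability

#: Nutrient label of baseline-slice runs (scenario paths are still identical).
BASELINE = "BASELINE"


@dataclass(frozen=True, order=True)
class TimeSlice:
    """Inclusive 5-year span of the run matrix."""

    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        if self.end_year < self.start_year:
            raise ValueError("end_year must not precede start_year")

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(range(self.start_year, self.end_year + 1))

    @property
    def width(self) -> int:
        return self.end_year - self.start_year + 1

    @property
    def label(self) -> str:
        return f"{self.start_year}-{self.end_year}"


def make_time_slices(start: int = 2007, end: int = 2066, width: int = 5) -> list[TimeSlice]:
    """Tile [start, end] into consecutive inclusive slices of equal width."""
    span = end - start + 1
    if width < 1 or span % width != 0:
        raise ValueError(f"period {start}-{end} is not divisible into {width}-year slices")
    return [TimeSlice(s, s + width - 1) for s in range(start, end + 1, width)]


@dataclass(frozen=True, order=True)
class RunSpec:
    """One model run: a time slice under a nutrient scenario and wave realization."""

    time_slice: TimeSlice
    nutrient: str
    wave: str

    @property
    def is_baseline(self) -> bool:
        return self.nutrient == BASELINE

    @property
    def label(self) -> str:
        return f"{self.time_slice.label}_{self.nutrient}_{self.wave}"


def enumerate_runs(
    slices: Sequence[TimeSlice],
    nutrient_scenarios: Sequence[str],
    wave_realizations: Sequence[str],
) -> list[RunSpec]:
    """Build the run matrix: baseline slice once per wave realization, every
    later slice once per nutrient x wave combination; ordered by
    (slice, nutrient, wave)."""
    if not slices or not nutrient_scenarios or not wave_realizations:
        raise ValueError("slices, nutrient scenarios and wave realizations must be non-empty")
    baseline, *future = sorted(slices)
    runs = [RunSpec(baseline, BASELINE, w) for w in wave_realizations]
    for ts in future:
        for nut in nutrient_scenarios:
            for w in wave_realizations:
                runs.append(RunSpec(ts, nut, w))
    return runs


def _fields_for(
    fields_by: Mapping[tuple[str, str], ScenarioFields], nutrient: str, wave: str
) -> ScenarioFields:
    if nutrient == BASELINE:
        # nutrient paths are identical over the baseline years; use any of them
        candidates = sorted(k for k in fields_by if k[1] == wave)
        if not candidates:
            raise KeyError(f"no scenario fields for wave realization {wave!r}")
        return fields_by[candidates[0]]
    return fields_by[(nutrient, wave)]


def slice_predictor_fields(
    grid: DepthGrid,
    fields: ScenarioFields,
    time_slice: TimeSlice,
    irradiance_wm2: Sequence[float] = light.DEFAULT_IRRADIANCE_WM2,
    light_kwargs: Mapping | None = None,
    wave_kwargs: Mapping | None = None,
) -> dict[str, np.ndarray]:
    """5-year-mean PFD and MOV fields for one slice of one forcing set."""
    pfd = light.pfd_predictor_field(
        grid, fields, time_slice.years, irradiance_wm2, **(light_kwargs or {})
    )
    mov = waves.mov_predictor_field(grid, fields, time_slice.years, **(wave_kwargs or {}))
    return {"pfd": pfd.pfd, "mov": mov.mov}


def run_projection(
    model: FittedSDM,
    grid: DepthGrid,
    fields_by: Mapping[tuple[str, str], ScenarioFields],
    plan: Sequence[RunSpec],
    irradiance_wm2: Sequence[float] = light.DEFAULT_IRRADIANCE_WM2,
    freeze: Sequence[str] = (),
    light_kwargs: Mapping | None = None,
    wave_kwargs: Mapping | None = None,
) -> dict[RunSpec, np.ndarray]:
    """Occurrence-probability map per run of the plan.

    ``fields_by`` maps (nutrient scenario, wave realization) to its forcing.
    Predictors named in ``freeze`` are held at their baseline-slice field of
    the same forcing set for every run (ceteris-paribus projections).
    """
    plan = list(plan)
    if not plan:
        raise ValueError("empty run plan")
    freeze = tuple(freeze)
    unknown = set(freeze) - set(model.predictor_names)
    if unknown:
        raise KeyError(f"cannot freeze unknown predictors {sorted(unknown)}")
    baseline_slice = min(r.time_slice for r in plan)
    maps: dict[RunSpec, np.ndarray] = {}
    for run in sorted(plan):
        fields = _fields_for(fields_by, run.nutrient, run.wave)
        preds = slice_predictor_fields(
            grid, fields, run.time_slice, irradiance_wm2, light_kwargs, wave_kwargs
        )
        if freeze and run.time_slice != baseline_slice:
            frozen = slice_predictor_fields(
                grid, fields, baseline_slice, irradiance_wm2, light_kwargs, wave_kwargs
            )
            for name in freeze:
                preds[name] = frozen[name]
        maps[run] = predict_probability(model, grid, preds)
    return maps


def difference_map(final_map: np.ndarray, baseline_map: np.ndarray) -> np.ndarray:
    """Cellwise change in occurrence probability (final minus baseline)."""
    final_map = np.asarray(final_map, dtype=float)
    baseline_map = np.asarray(baseline_map, dtype=float)
    if final_map.shape != baseline_map.shape:
        raise ValueError("maps must share one shape")
    return final_map - baseline_map


def total_area(prob_map: np.ndarray, grid: DepthGrid, threshold: float | None = None) -> float:
    """Total eelgrass area (km^2) of a probability map.

    Default: the expected area, sum of probability x cell area (probability
    read as coverage).  With ``threshold``, the area of cells at or above it.
    """
    prob_map = np.asarray(prob_map, dtype=float)
    if prob_map.shape != grid.shape:
        raise ValueError("map does not match the grid")
    vals = prob_map[grid.in_scope_mask]
    vals = vals[np.isfinite(vals)]
    if vals.size and (vals.min() < 0 or vals.max() > 1):
        raise ValueError("probabilities outside [0, 1]")
    if threshold is None:
        return float(vals.sum() * grid.cell_area_km2)
    return float((vals >= threshold).sum() * grid.cell_area_km2)


def baseline_reference_map(
    maps: Mapping[RunSpec, np.ndarray], combine: str = "mean"
) -> np.ndarray:
    """Single reference map from the per-realization baseline runs (mean
    across wave realizations by default)."""
    base = [m for r, m in maps.items() if r.is_baseline]
    if not base:
        raise ValueError("no baseline runs in the map set")
    stack = np.stack(base)
    if combine == "mean":
        return stack.mean(axis=0)
    raise ValueError(f"unknown combine rule {combine!r}")


def area_series(
    maps: Mapping[RunSpec, np.ndarray], grid: DepthGrid, threshold: float | None = None
) -> pd.DataFrame:
    """Per-run total area with percent change against the matching baseline
    (same wave realization)."""
    rows = []
    base_area = {
        r.wave: total_area(m, grid, threshold) for r, m in maps.items() if r.is_baseline
    }
    for run in sorted(maps):
        a = total_area(maps[run], grid, threshold)
        ref = base_area.get(run.wave, np.nan)
        rows.append(
            {
                "start_year": run.time_slice.start_year,
                "end_year": run.time_slice.end_year,
                "nutrient": run.nutrient,
                "wave": run.wave,
                "area_km2": a,
                "baseline_km2": ref,
                "pct_change": 100.0 * (a - ref) / ref if ref else np.nan,
            }
        )
    return pd.DataFrame(rows)


def expand_slices_to_annual(slice_values: Mapping[TimeSlice, float]) -> pd.Series:
    """Annual series where each year inherits its slice's value."""
    if not slice_values:
        raise ValueError("no slice values")
    data = {}
    for ts, v in sorted(slice_values.items()):
        for y in ts.years:
            data[y] = v
    return pd.Series(data, name="value").sort_index()


def running_mean_30y(annual: pd.Series, window: int = 30) -> pd.Series:
    """Centred running mean, window truncated at the series edges."""
    if annual.empty:
        raise ValueError("empty series")
    return annual.rolling(window, center=True, min_periods=1).mean()


def depth_binned_change(
    baseline_map: np.ndarray,
    final_map: np.ndarray,
    grid: DepthGrid,
    bin_width: float = 1.0,
    eps: float = 1e-6,
) -> pd.DataFrame:
    """Percent change of mean coverage per depth bin over (0, max_depth].

    Bins with no in-scope cells carry NaN.  The baseline mean is floored at
    ``eps`` in the denominator to avoid blow-ups in unoccupied bins.
    """
    baseline_map = np.asarray(baseline_map, dtype=float)
    final_map = np.asarray(final_map, dtype=float)
    if baseline_map.shape != grid.shape or final_map.shape != grid.shape:
        raise ValueError("maps must match the grid")
    edges = np.arange(0.0, grid.max_depth + bin_width / 2, bin_width)
    scope = grid.in_scope_mask & np.isfinite(baseline_map) & np.isfinite(final_map)
    depth = grid.depth[scope]
    base = baseline_map[scope]
    fin = final_map[scope]
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (depth > lo) & (depth <= hi)
        n = int(sel.sum())
        if n == 0:
            rows.append(
                {"depth_lo": lo, "depth_hi": hi, "n_cells": 0,
                 "mean_baseline": np.nan, "mean_final": np.nan, "pct_change": np.nan}
            )
            continue
        mb = float(base[sel].mean())
        mf = float(fin[sel].mean())
        rows.append(
            {
                "depth_lo": lo,
                "depth_hi": hi,
                "n_cells": n,
                "mean_baseline": mb,
                "mean_final": mf,
                "pct_change": 100.0 * (mf - mb) / max(mb, eps),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AttributionResult:
    """Ceteris-paribus attribution of the baseline-to-final areal change.

    One row per nutrient x wave combination: the full change, the change with
    only one predictor varying (the other frozen at baseline), each
    predictor's share of the full change (percent), and the interaction
    residual.  Shares are NaN (and ``undefined`` True) when the full change
    is negligible.
    """

    table: pd.DataFrame


def ceteris_paribus(
    model: FittedSDM,
    grid: DepthGrid,
    fields_by: Mapping[tuple[str, str], ScenarioFields],
    slices: Sequence[TimeSlice],
    nutrient_scenarios: Sequence[str],
    wave_realizations: Sequence[str],
    irradiance_wm2: Sequence[float] = light.DEFAULT_IRRADIANCE_WM2,
    min_total_km2: float = 1e-9,
    **proj_kwargs,
) -> AttributionResult:
    """Attribute the baseline-to-final areal change to each predictor.

    Projections are rerun with one predictor frozen at its baseline-slice
    field; a predictor's share is 100 x (change with only it varying) /
    (change with both varying).
    """
    slices = sorted(slices)
    baseline_slice, final_slice = slices[0], slices[-1]
    plan = enumerate_runs([baseline_slice, final_slice], nutrient_scenarios, wave_realizations)
    names = model.predictor_names
    variants: dict[str, tuple[str, ...]] = {"full": ()}
    for name in names:
        variants[name] = tuple(n for n in names if n != name)  # freeze the others
    areas: dict[str, dict[RunSpec, float]] = {}
    for key, freeze in variants.items():
        maps = run_projection(
            model, grid, fields_by, plan, irradiance_wm2, freeze=freeze, **proj_kwargs
        )
        areas[key] = {r: total_area(m, grid) for r, m in maps.items()}
    rows = []
    for nut in nutrient_scenarios:
        for wave in wave_realizations:
            run_final = RunSpec(final_slice, nut, wave)
            run_base = RunSpec(baseline_slice, BASELINE, wave)
            a0 = areas["full"][run_base]
            d_full = areas["full"][run_final] - a0
            undefined = abs(d_full) < min_total_km2
            row = {
                "nutrient": nut,
                "wave": wave,
                "delta_total_km2": d_full,
                "undefined": undefined,
            }
            d_sum = 0.0
            for name in names:
                d_one = areas[name][run_final] - a0
                d_sum += d_one
                row[f"delta_{name}_only_km2"] = d_one
                row[f"{name}_share_pct"] = np.nan if undefined else 100.0 * d_one / d_full
            row["interaction_km2"] = d_full - d_sum
            rows.append(row)
    return AttributionResult(table=pd.DataFrame(rows))
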