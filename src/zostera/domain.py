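"""Core containers for the eelgrass habitat model.

The model domain is a regular grid of 100 m cells covering the coastal zone
from the shoreline down to 12 m water depth.  All spatial fields in the
package (bathymetry, Secchi depth, sea state, light, orbital velocity,
occurrence probability) live on this grid; cells outside the modelled depth
range carry NaN in derived fields and are excluded from every statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

#: Seaward limit of the modelled domain (m water depth).
MAX_MODEL_DEPTH = 12.0

#: Nutrient-load scenario labels: Baltic Sea Action Plan implementation
#: versus business as usual.
NUTRIENT_SCENARIOS = ("BSAP", "BAU")

#: Wave-climate realizations: two greenhouse-gas emission scenarios (A1B, B1),
#: each run twice from perturbed initial conditions.
WAVE_REALIZATIONS = ("A1B_1", "A1B_2", "B1_1", "B1_2")


@dataclass(frozen=True)
class DepthGrid:
    """Gridded bathymetry.

    Parameters
    ----------
    depth
        2-D array of water depth in metres, positive downward; values
        ``<= 0`` mark land.
    cell_size
        Edge length of a (square) grid cell in metres.
    max_depth
        Seaward depth limit of the modelled domain in metres; cells deeper
        than this are out of scope.
    """

    depth: np.ndarray
    cell_size: float = 100.0
    max_depth: float = MAX_MODEL_DEPTH

    def __post_init__(self) -> None:
        depth = np.asarray(self.depth, dtype=float)
        if depth.ndim != 2 or depth.shape[0] < 1 or depth.shape[1] < 1:
            raise ValueError("depth must be a non-empty 2-D array")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        if not self.max_depth > 0:
            raise ValueError("max_depth must be positive")
        object.__setattr__(self, "depth", depth)

    @property
    def n_rows(self) -> int:
        return self.depth.shape[0]

    @property
    def n_cols(self) -> int:
        return self.depth.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.depth.shape

    @property
    def in_scope_mask(self) -> np.ndarray:
        """Boolean mask, True where ``0 < depth <= max_depth``."""
        return (self.depth > 0) & (self.depth <= self.max_depth)

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    @property
    def total_area_km2(self) -> float:
        """Total in-scope area in km^2."""
        return float(self.in_scope_mask.sum()) * self.cell_area_km2

    def mask_field(self, values: np.ndarray) -> np.ndarray:
        """Return a copy of ``values`` with out-of-scope cells set to NaN."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.shape:
            raise ValueError("field shape does not match grid")
        out = values.copy()
        out[~self.in_scope_mask] = np.nan
        return out


@dataclass(frozen=True)
class ScenarioFields:
    """Per-year forcing fields for one nutrient scenario x wave realization.

    ``secchi`` (m), ``hm0`` (significant wave height, m) and ``tm02`` (mean
    wave period, s) are stacked ``(n_years, n_rows, n_cols)`` arrays aligned
    with ``years``.
    """

    years: tuple[int, ...]
    nutrient_scenario: str
    wave_realization: str
    secchi: np.ndarray
    hm0: np.ndarray
    tm02: np.ndarray

    def __post_init__(self) -> None:
        years = tuple(int(y) for y in self.years)
        object.__setattr__(self, "years", years)
        for name in ("secchi", "hm0", "tm02"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 3 or arr.shape[0] != len(years):
                raise ValueError(f"{name} must be (n_years, n_rows, n_cols)")
            object.__setattr__(self, name, arr)
        if self.hm0.shape != self.secchi.shape or self.tm02.shape != self.secchi.shape:
            raise ValueError("forcing fields must share one shape")

    def validate(self, grid: DepthGrid) -> None:
        """Check congruence with ``grid`` and in-scope physical bounds."""
        if self.secchi.shape[1:] != grid.shape:
            raise ValueError("forcing fields do not match the grid shape")
        scope = grid.in_scope_mask
        if not np.all(self.secchi[:, scope] > 0):
            raise ValueError("Secchi depth must be positive in scope")
        if not np.all(self.hm0[:, scope] >= 0):
            raise ValueError("significant wave height must be non-negative")
        if not np.all(self.tm02[:, scope] > 0):
            raise ValueError("mean wave period must be positive")

    def year_index(self, year: int) -> int:
        try:
            return self.years.index(int(year))
        except ValueError:
            raise KeyError(f"year {year} not covered by scenario fields") from None

    def select_years(self, years: Sequence[int]) -> "ScenarioFields":
        idx = [self.year_index(y) for y in years]
        return replace(
            self,
            years=tuple(int(y) for y in years),
            secchi=self.secchi[idx],
            hm0=self.hm0[idx],
            tm02=self.tm02[idx],
        )


@dataclass(frozen=True)
class ResponseTruth:
    """Generating truth of the synthetic occurrence response.

    The true occurrence probability is
    ``p = expit(intercept + light_effect(PFD) + wave_effect(MOV))`` with a
    saturating light term (linear in PFD up to ``pfd_saturation``, flat
    above, zero at ``pfd_reference``) and a declining wave term that crosses
    zero at ``mov_threshold`` (the half-occurrence orbital velocity) and
    flattens above ``mov_flat``.

    ``light_offset`` recentres the light term over the sampled predictor
    distribution; it is filled in by the observation sampler so that the
    wave threshold remains the marginal half-occurrence point.
    """

    intercept: float = 0.0
    pfd_slope: float = 0.01  # logit units per umol photons m-2 s-1
    pfd_reference: float = 150.0  # PFD with zero light contribution
    pfd_saturation: float = 350.0  # PFD above which the light term is flat
    mov_slope: float = 6.0  # logit units per m s-1
    mov_threshold: float = 0.4  # half-occurrence orbital velocity (m s-1)
    mov_flat: float = 1.0  # MOV above which the wave term is flat
    light_offset: float = 0.0

    def light_effect(self, pfd):
        pfd = np.asarray(pfd, dtype=float)
        raw = self.pfd_slope * (np.minimum(pfd, self.pfd_saturation) - self.pfd_reference)
        return raw - self.light_offset

    def wave_effect(self, mov):
        mov = np.asarray(mov, dtype=float)
        return -self.mov_slope * (np.minimum(mov, self.mov_flat) - self.mov_threshold)

    def linear_predictor(self, pfd, mov):
        return self.intercept + self.light_effect(pfd) + self.wave_effect(mov)

    def probability(self, pfd, mov):
        return expit(self.linear_predictor(pfd, mov))


@dataclass(frozen=True)
class ObservationSet:
    """Georeferenced presence/absence survey records on the model grid.

    ``row``/``col`` index grid cells; ``presence`` is binary.  When produced
    by the synthetic sampler, ``pfd``/``mov`` carry the predictor values the
    record was generated from and ``truth`` stores the generating response,
    enabling parameter-recovery tests.
    """

    row: np.ndarray
    col: np.ndarray
    presence: np.ndarray
    survey_years: tuple[int, ...] = ()
    pfd: np.ndarray | None = None
    mov: np.ndarray | None = None
    truth: ResponseTruth | None = None

    def __post_init__(self) -> None:
        row = np.asarray(self.row, dtype=int)
        col = np.asarray(self.col, dtype=int)
        presence = np.asarray(self.presence, dtype=int)
        if not (row.shape == col.shape == presence.shape) or row.ndim != 1:
            raise ValueError("row, col, presence must be 1-D and congruent")
        if presence.size and not np.isin(presence, (0, 1)).all():
            raise ValueError("presence must be binary")
        object.__setattr__(self, "row", row)
        object.__setattr__(self, "col", col)
        object.__setattr__(self, "presence", presence)
        for name in ("pfd", "mov"):
            val = getattr(self, name)
            if val is not None:
                val = np.asarray(val, dtype=float)
                if val.shape != row.shape:
                    raise ValueError(f"{name} must match record count")
                object.__setattr__(self, name, val)

    def __len__(self) -> int:
        return self.row.size

    @property
    def prevalence(self) -> float:
        return float(self.presence.mean())

    def validate(self, grid: DepthGrid) -> None:
        ok = (
            (self.row >= 0)
            & (self.row < grid.n_rows)
            & (self.col >= 0)
            & (self.col < grid.n_cols)
        )
        if not ok.all():
            raise ValueError("observation outside the grid")
        if not grid.in_scope_mask[self.row, self.col].all():
            raise ValueError("observation in an out-of-scope cell")

    def to_frame(self) -> pd.DataFrame:
        data = {"row": self.row, "col": self.col, "presence": self.presence}
        if self.pfd is not None:
            data["pfd"] = self.pfd
        if self.mov is not None:
            data["mov"] = self.mov
        return pd.DataFrame(data)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        survey_years: Sequence[int] = (),
        truth: ResponseTruth | None = None,
    ) -> "ObservationSet":
        return cls(
            row=frame["row"].to_numpy(),
            col=frame["col"].to_numpy(),
            presence=frame["presence"].to_numpy(),
            survey_years=tuple(int(y) for y in survey_years),
            pfd=frame["pfd"].to_numpy() if "pfd" in frame else None,
            mov=frame["mov"].to_numpy() if "mov" in frame else None,
            truth=truth,
        )


def training_table(
    obs: ObservationSet, predictor_fields: Mapping[str, np.ndarray]
) -> pd.DataFrame:
    """Attach gridded predictor values to survey records.

    Returns a frame with a ``presence`` column plus one column per predictor,
    sampled at each record's grid cell.  Records falling on cells where any
    predictor is NaN (out of scope) are rejected.
    """
    data = {"presence": obs.presence}
    for name, fld in predictor_fields.items():
        fld = np.asarray(fld, dtype=float)
        vals = fld[obs.row, obs.col]
        if np.isnan(vals).any():
            raise ValueError(f"predictor {name!r} undefined at some records")
        data[name] = vals
    return pd.DataFrame(data)
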