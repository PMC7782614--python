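"""Light availability at the eelgrass canopy.

Photosynthetic photon flux density (PFD, umol photons m-2 s-1) at 0.5 m
above the sea floor is computed from surface solar irradiance and water
clarity with the Beer-Lambert law, ``I_z = I_0 * exp(-k * z)``.  The
attenuation coefficient ``k`` is derived from Secchi depth via the
Poole-Atkins relation ``k = C / SD`` and surface irradiance (W m-2) is
converted to PFD with a factor of 4.15.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .domain import DepthGrid, ScenarioFields

#: Irradiance (W m-2) to PFD (umol photons m-2 s-1) conversion factor.
WATT_TO_PFD = 4.15

#: Poole-Atkins Secchi-depth to attenuation-coefficient constant (m * m-1).
SECCHI_ATTENUATION_COEFF = 1.7

#: Height of the eelgrass canopy top above the sea floor (m); light is
#: evaluated at this level.
CANOPY_OFFSET = 0.5

#: Monthly mean surface global irradiance (W m-2) for a single representative
#: station in the western Baltic (~54.5 N), January..December.  One station
#: stands in for the whole grid.
DEFAULT_IRRADIANCE_WM2 = (
    25.0, 55.0, 105.0, 175.0, 230.0, 245.0,
    235.0, 195.0, 135.0, 75.0, 32.0, 18.0,
)


def attenuation_from_secchi(sd, coefficient: float = SECCHI_ATTENUATION_COEFF):
    """Light attenuation coefficient k (m-1) from Secchi depth (m).

    ``k = coefficient / sd``; strictly decreasing in Secchi depth.
    """
    sd = np.asarray(sd, dtype=float)
    if np.any(sd <= 0):
        raise ValueError("Secchi depth must be positive")
    out = coefficient / sd
    return float(out) if out.ndim == 0 else out


def pfd_surface(irradiance):
    """Convert surface irradiance (W m-2) to PFD (umol photons m-2 s-1)."""
    irradiance = np.asarray(irradiance, dtype=float)
    if np.any(irradiance < 0):
        raise ValueError("irradiance must be non-negative")
    out = WATT_TO_PFD * irradiance
    return float(out) if out.ndim == 0 else out


def pfd_at_canopy(i0, k, d, canopy_offset: float = CANOPY_OFFSET):
    """PFD at canopy height from surface PFD ``i0``, attenuation ``k``, depth ``d``.

    The evaluation depth is ``z = max(d - canopy_offset, 0)``; no
    surface-reflection correction is applied (plane-surface simplification,
    so absolute light levels are slightly overestimated).
    """
    i0 = np.asarray(i0, dtype=float)
    k = np.asarray(k, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(i0 < 0):
        raise ValueError("surface PFD must be non-negative")
    if np.any(k < 0):
        raise ValueError("attenuation coefficient must be non-negative")
    if np.any(d <= 0):
        raise ValueError("water depth must be positive (land cell?)")
    z = np.maximum(d - canopy_offset, 0.0)
    out = i0 * np.exp(-k * z)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class LightField:
    """Gridded PFD at canopy height (umol photons m-2 s-1), NaN out of scope."""

    pfd: np.ndarray
    period: tuple[int, ...]


def pfd_predictor_field(
    grid: DepthGrid,
    fields: ScenarioFields,
    years: Sequence[int],
    irradiance_wm2: Sequence[float] = DEFAULT_IRRADIANCE_WM2,
    months: Sequence[int] | None = None,
    secchi_coefficient: float = SECCHI_ATTENUATION_COEFF,
    canopy_offset: float = CANOPY_OFFSET,
    reflection_loss: float = 0.0,
) -> LightField:
    """Slice-mean PFD field at canopy height for a set of years.

    For each year the annual Secchi field gives one ``k`` field; PFD is
    evaluated per month of the irradiance climatology and averaged over the
    selected ``months`` (default: all twelve, equal weights) and over the
    ``years`` of the slice.  Because ``k`` is annual, the month average
    reduces exactly to a single Beer-law evaluation at the month-mean
    surface PFD.  ``reflection_loss`` (e.g. 0.06 for ~6% air-water
    reflection) is off by default.
    """
    years = tuple(int(y) for y in years)
    if not years:
        raise ValueError("at least one year required")
    irradiance = np.asarray(irradiance_wm2, dtype=float)
    if months is None:
        months = range(1, len(irradiance) + 1)
    month_idx = [int(m) - 1 for m in months]
    if not month_idx or min(month_idx) < 0 or max(month_idx) >= irradiance.size:
        raise ValueError("months must be within the irradiance climatology")
    i0 = pfd_surface(irradiance[month_idx].mean()) * (1.0 - reflection_loss)

    scope = grid.in_scope_mask
    depth = grid.depth
    z = np.maximum(depth - canopy_offset, 0.0)
    acc = np.zeros(grid.shape)
    for year in years:
        sd = fields.secchi[fields.year_index(year)]
        k = np.full(grid.shape, np.nan)
        k[scope] = attenuation_from_secchi(sd[scope], secchi_coefficient)
        acc[scope] += i0 * np.exp(-k[scope] * z[scope])
    pfd = np.full(grid.shape, np.nan)
    pfd[scope] = acc[scope] / len(years)
    return LightField(pfd=pfd, period=years)
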