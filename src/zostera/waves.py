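"""Wave-generated orbital velocity at the sea floor.

Hydrodynamic exposure is expressed as the maximum orbital velocity (MOV)
produced at the seabed by the largest expected wave, derived from the sea
state via linear (Airy) wave theory:

* the maximum wave height follows Rayleigh statistics,
  ``H_max = sqrt(ln(N)/2) * H_m0 ~= 1.86 * H_m0`` for N = 1000 waves;
* ``H_max`` is capped at the local water depth (depth-limited breaking,
  ``H_max / d < 1``);
* its period follows the empirical relation ``T_Hmax = 0.83 * H_max + 3.17``;
* the wavelength solves the implicit dispersion relation
  ``L = (g T^2 / 2 pi) * tanh(2 pi d / L)``;
* the near-bed velocity amplitude is ``U = pi H / (T sinh(2 pi d / L))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .domain import DepthGrid, ScenarioFields

GRAVITY = 9.81  # m s-2


def rayleigh_hmax_factor(n_waves: int = 1000) -> float:
    """Expected ratio H_max / H_m0 for the largest of ``n_waves`` Rayleigh waves."""
    if n_waves < 2:
        raise ValueError("n_waves must be at least 2")
    return math.sqrt(math.log(n_waves) / 2.0)


@dataclass(frozen=True)
class WaveConstants:
    """Constants of the sea-state-to-MOV chain."""

    g: float = GRAVITY
    n_waves: int = 1000
    hmax_factor: float = 1.86
    period_slope: float = 0.83  # s per m of H_max
    period_intercept: float = 3.17  # s

    def __post_init__(self) -> None:
        expected = rayleigh_hmax_factor(self.n_waves)
        if abs(self.hmax_factor - expected) > 0.005:
            raise ValueError(
                f"hmax_factor {self.hmax_factor} inconsistent with Rayleigh "
                f"maximum of N={self.n_waves} waves ({expected:.4f})"
            )


DEFAULT_CONSTANTS = WaveConstants()


def hmax_from_hm0(hm0, factor: float = DEFAULT_CONSTANTS.hmax_factor):
    """Maximum wave height from significant wave height (Rayleigh statistics)."""
    hm0 = np.asarray(hm0, dtype=float)
    if np.any(hm0 < 0):
        raise ValueError("significant wave height must be non-negative")
    out = factor * hm0
    return float(out) if out.ndim == 0 else out


def thmax_from_hmax(
    hmax,
    slope: float = DEFAULT_CONSTANTS.period_slope,
    intercept: float = DEFAULT_CONSTANTS.period_intercept,
):
    """Period of the maximum wave from its height (empirical relation)."""
    hmax = np.asarray(hmax, dtype=float)
    if np.any(hmax < 0):
        raise ValueError("maximum wave height must be non-negative")
    out = slope * hmax + intercept
    return float(out) if out.ndim == 0 else out


def cap_breaking(hmax, d):
    """Depth-limited breaking: the maximum wave height cannot exceed the depth."""
    hmax = np.asarray(hmax, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("water depth must be positive")
    out = np.minimum(hmax, d)
    return float(out) if out.ndim == 0 else out


def deep_water_wavelength(t):
    t = np.asarray(t, dtype=float)
    out = GRAVITY * t**2 / (2.0 * math.pi)
    return float(out) if out.ndim == 0 else out


def dispersion_wavelength(t, d, tol: float = 1e-6, max_iter: int = 200):
    """Solve the linear-theory dispersion relation for the wavelength L (m).

    Newton iteration on the wavenumber, started from the deep-water value,
    with a bisection fallback on ``[1e-3, g t^2 / 2 pi]`` for any element
    that fails to converge.  The result satisfies
    ``|L - (g t^2 / 2 pi) tanh(2 pi d / L)| < tol``.
    """
    t = np.asarray(t, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(t <= 0):
        raise ValueError("wave period must be positive")
    if np.any(d <= 0):
        raise ValueError("water depth must be positive")
    t_b, d_b = np.broadcast_arrays(t, d)
    scalar = t_b.ndim == 0
    t_b = np.atleast_1d(t_b).astype(float)
    d_b = np.atleast_1d(d_b).astype(float)

    omega2 = (2.0 * math.pi / t_b) ** 2
    k = omega2 / GRAVITY  # deep-water wavenumber as the starting point
    converged = np.zeros(k.shape, dtype=bool)
    for _ in range(max_iter):
        kd = k * d_b
        th = np.tanh(kd)
        f = GRAVITY * k * th - omega2
        df = GRAVITY * (th + kd * (1.0 - th**2))
        step = f / df
        k = np.maximum(k - step, 1e-12)
        # tolerance on L: |dL| = (2 pi / k^2) |dk|
        converged = np.abs(step) * 2.0 * math.pi / k**2 < 0.1 * tol
        if converged.all():
            break

    if not converged.all():
        bad = ~converged
        k[bad] = _bisect_wavenumber(omega2[bad], d_b[bad], tol, max_iter)

    L = 2.0 * math.pi / k
    residual = np.abs(L - deep_water_wavelength(t_b) * np.tanh(2.0 * math.pi * d_b / L))
    if np.any(residual > tol):
        raise RuntimeError("dispersion solver failed to reach tolerance")
    return float(L[0]) if scalar else L.reshape(np.broadcast_shapes(t.shape, d.shape))


def _bisect_wavenumber(omega2, d, tol, max_iter):
    """Bisection fallback on wavelength in [1e-3, deep-water L]."""
    L_lo = np.full(omega2.shape, 1e-3)
    L_hi = 2.0 * math.pi * GRAVITY / omega2  # deep-water wavelength
    for _ in range(max_iter + 60):
        L_mid = 0.5 * (L_lo + L_hi)
        # g k tanh(kd) - omega^2 is decreasing in L
        k_mid = 2.0 * math.pi / L_mid
        f = GRAVITY * k_mid * np.tanh(k_mid * d) - omega2
        hi = f > 0  # root lies above L_mid
        L_lo = np.where(hi, L_mid, L_lo)
        L_hi = np.where(hi, L_hi, L_mid)
        if np.all(L_hi - L_lo < 0.1 * tol):
            break
    return 2.0 * math.pi / (0.5 * (L_lo + L_hi))


def bottom_orbital_velocity(h, t, d):
    """Near-bed orbital velocity amplitude U = pi h / (t sinh(2 pi d / L))."""
    h = np.asarray(h, dtype=float)
    t = np.asarray(t, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(h < 0):
        raise ValueError("wave height must be non-negative")
    L = dispersion_wavelength(t, d)
    arg = 2.0 * math.pi * d / np.asarray(L)
    with np.errstate(over="ignore"):
        out = math.pi * h / (t * np.sinh(arg))
    out = np.where(np.isfinite(out), out, 0.0)  # sinh overflow => deep water => U -> 0
    return float(out) if out.ndim == 0 else out


def mov_single_state(hm0, d, constants: WaveConstants = DEFAULT_CONSTANTS, tm02=None):
    """MOV for one sea state: Rayleigh H_max, breaking cap, then linear theory.

    The breaking cap is applied before the period relation so the period
    belongs to the physically realisable wave.  When ``tm02`` is given it is
    used as the wave period instead of the empirical T_Hmax (sensitivity
    option).
    """
    hmax = cap_breaking(hmax_from_hm0(hm0, constants.hmax_factor), d)
    if tm02 is None:
        period = thmax_from_hmax(hmax, constants.period_slope, constants.period_intercept)
    else:
        period = np.asarray(tm02, dtype=float)
    return bottom_orbital_velocity(hmax, period, d)


@dataclass(frozen=True)
class MOVField:
    """Gridded maximum orbital velocity (m s-1), NaN out of scope."""

    mov: np.ndarray
    period: tuple[int, ...]


def mov_predictor_field(
    grid: DepthGrid,
    fields: ScenarioFields,
    years: Sequence[int],
    constants: WaveConstants = DEFAULT_CONSTANTS,
    use_tm02: bool = False,
    statistic: str = "mean",
) -> MOVField:
    """Slice-mean MOV field over the given years.

    Per cell and year the full chain H_m0 -> H_max -> (cap) -> T_Hmax -> U is
    evaluated; the slice value is the arithmetic mean across years
    (``statistic="mean"``) or an upper percentile (``"p90"``) for
    storm-weighted sensitivity runs.
    """
    years = tuple(int(y) for y in years)
    if not years:
        raise ValueError("at least one year required")
    scope = grid.in_scope_mask
    depth = grid.depth[scope]
    yearly = np.empty((len(years), depth.size))
    for i, year in enumerate(years):
        j = fields.year_index(year)
        tm02 = fields.tm02[j][scope] if use_tm02 else None
        yearly[i] = mov_single_state(fields.hm0[j][scope], depth, constants, tm02=tm02)
    if statistic == "mean":
        agg = yearly.mean(axis=0)
    elif statistic == "p90":
        agg = np.percentile(yearly, 90, axis=0)
    else:
        raise ValueError(f"unknown slice statistic {statistic!r}")
    mov = np.full(grid.shape, np.nan)
    mov[scope] = agg
    return MOVField(mov=mov, period=years)
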