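import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from zostera import (
    ScenarioFields,
    WaveConstants,
    bottom_orbital_velocity,
    cap_breaking,
    dispersion_wavelength,
    hmax_from_hm0,
    mov_predictor_field,
    rayleigh_hmax_factor,
    thmax_from_hmax,
)
from zostera.waves import GRAVITY, mov_single_state


def oracle_wavelength(t: float, d: float) -> float:
    """Independent dispersion solve: scalar root bracketing on L."""
    deep = GRAVITY * t**2 / (2 * math.pi)
    f = lambda L: L - deep * math.tanh(2 * math.pi * d / L)
    return brentq(f, 1e-6, deep + 1.0, xtol=1e-12)


class TestConstants:
    def test_rayleigh_factor_rounds_to_published_value(self):
        assert round(rayleigh_hmax_factor(1000), 2) == 1.86

    def test_inconsistent_factor_rejected(self):
        with pytest.raises(ValueError, match="Rayleigh"):
            WaveConstants(hmax_factor=1.90)


class TestWaveHeightPeriodChain:
    @pytest.mark.parametrize("hm0,hmax", [(1.0, 1.86), (0.0, 0.0), (2.0, 3.72)])
    def test_hmax_scaling(self, hm0, hmax):
        assert hmax_from_hm0(hm0) == pytest.approx(hmax)

    @pytest.mark.parametrize("hmax,t", [(0.0, 3.17), (1.0, 4.00), (1.86, 4.7138)])
    def test_period_relation(self, hmax, t):
        assert thmax_from_hmax(hmax) == pytest.approx(t)

    def test_negative_heights_rejected(self):
        with pytest.raises(ValueError):
            hmax_from_hm0(-0.1)
        with pytest.raises(ValueError):
            thmax_from_hmax(-0.1)

    @pytest.mark.parametrize(
        "hmax,d,capped", [(3.72, 2.0, 2.0), (0.5, 2.0, 0.5), (2.0, 2.0, 2.0)]
    )
    def test_breaking_cap(self, hmax, d, capped):
        assert cap_breaking(hmax, d) == pytest.approx(capped)

    def test_cap_requires_positive_depth(self):
        with pytest.raises(ValueError):
            cap_breaking(1.0, 0.0)


class TestDispersion:
    def test_deep_water_limit(self):
        L = dispersion_wavelength(10.0, 1000.0)
        deep = GRAVITY * 100.0 / (2 * math.pi)
        assert L == pytest.approx(deep, rel=1e-3)

    def test_shallow_water_limit(self):
        L = dispersion_wavelength(5.0, 0.1)
        shallow = 5.0 * math.sqrt(GRAVITY * 0.1)
        assert L == pytest.approx(shallow, rel=1e-2)

    def test_residual_below_tolerance_on_random_inputs(self):
        rng = np.random.default_rng(42)
        t = rng.uniform(1.0, 15.0, 1000)
        d = rng.uniform(0.05, 200.0, 1000)
        L = dispersion_wavelength(t, d)
        deep = GRAVITY * t**2 / (2 * math.pi)
        residual = np.abs(L - deep * np.tanh(2 * math.pi * d / L))
        assert residual.max() < 1e-6
        assert (L > 0).all() and (L <= deep + 1e-9).all()

    @given(t=st.floats(1.0, 15.0), d=st.floats(0.05, 300.0))
    @settings(max_examples=60, deadline=None)
    def test_agrees_with_bracketing_oracle(self, t, d):
        assert dispersion_wavelength(t, d) == pytest.approx(
            oracle_wavelength(t, d), abs=1e-6
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            dispersion_wavelength(0.0, 5.0)
        with pytest.raises(ValueError):
            dispersion_wavelength(5.0, -1.0)


class TestBottomOrbitalVelocity:
    def test_zero_wave_gives_zero_velocity(self):
        assert bottom_orbital_velocity(0.0, 5.0, 2.0) == 0.0

    def test_hand_computed_intermediate_case(self):
        # L(5 s, 2 m) ~ 20.9 m, then U = pi * 1 / (5 * sinh(2 pi * 2 / L))
        L = oracle_wavelength(5.0, 2.0)
        expected = math.pi / (5.0 * math.sinh(2 * math.pi * 2.0 / L))
        assert bottom_orbital_velocity(1.0, 5.0, 2.0) == pytest.approx(expected)
        assert expected == pytest.approx(0.99, abs=0.01)

    def test_deep_water_velocity_vanishes(self):
        assert bottom_orbital_velocity(1.0, 5.0, 100.0) < 1e-3

    @given(h=st.floats(0.01, 3.0), scale=st.floats(0.1, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_linear_in_wave_height(self, h, scale):
        u1 = bottom_orbital_velocity(h, 4.0, 3.0)
        u2 = bottom_orbital_velocity(scale * h, 4.0, 3.0)
        assert u2 == pytest.approx(scale * u1, rel=1e-9)


def _sea_state(grid, hm0_value, years):
    shape = (len(years),) + grid.shape
    return ScenarioFields(
        years=years,
        nutrient_scenario="BAU",
        wave_realization="A1B_1",
        secchi=np.full(shape, 4.0),
        hm0=np.full(shape, hm0_value),
        tm02=np.full(shape, 4.0),
    )


class TestMovPredictorField:
    def test_flat_sea_gives_zero_field(self, ramp_grid):
        years = (2007, 2008)
        out = mov_predictor_field(ramp_grid, _sea_state(ramp_grid, 0.0, years), years)
        scope = ramp_grid.in_scope_mask
        np.testing.assert_allclose(out.mov[scope], 0.0)
        assert np.isnan(out.mov[~scope]).all()

    def test_identical_years_equal_single_year(self, ramp_grid):
        years = (2007, 2008, 2009)
        fields = _sea_state(ramp_grid, 0.8, years)
        multi = mov_predictor_field(ramp_grid, fields, years)
        single = mov_predictor_field(ramp_grid, fields, years[:1])
        np.testing.assert_allclose(
            multi.mov[ramp_grid.in_scope_mask], single.mov[ramp_grid.in_scope_mask]
        )

    def test_equals_scalar_chain_cell_by_cell(self, ramp_grid):
        years = (2007,)
        fields = _sea_state(ramp_grid, 0.7, years)
        out = mov_predictor_field(ramp_grid, fields, years)
        for idx in zip(*np.nonzero(ramp_grid.in_scope_mask)):
            d = ramp_grid.depth[idx]
            hmax = cap_breaking(hmax_from_hm0(0.7), d)
            expected = bottom_orbital_velocity(hmax, thmax_from_hmax(hmax), d)
            assert out.mov[idx] == pytest.approx(expected)

    def test_decreases_with_depth_beyond_breaking_zone(self, ramp_grid):
        years = (2007,)
        out = mov_predictor_field(ramp_grid, _sea_state(ramp_grid, 0.6, years), years)
        depths = ramp_grid.depth[:, 0]
        profile = out.mov[:, 0]
        free = depths > hmax_from_hm0(0.6)  # breaking cap inactive
        vals = profile[ramp_grid.in_scope_mask[:, 0] & free]
        assert (np.diff(vals) < 0).all()

    def test_tm02_option_changes_the_period_used(self, ramp_grid):
        d = ramp_grid.depth[ramp_grid.in_scope_mask]
        with_thmax = mov_single_state(0.5, d)
        with_tm02 = mov_single_state(0.5, d, tm02=np.full(d.shape, 8.0))
        assert not np.allclose(with_thmax, with_tm02)

    def test_missing_years_rejected(self, ramp_grid):
        fields = _sea_state(ramp_grid, 0.5, (2007,))
        with pytest.raises(KeyError):
            mov_predictor_field(ramp_grid, fields, (2007, 2010))
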