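"""Unit conversions, stress scalars, PET, the soil water balance and the NPP run."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from casafusion import (CasaParams, ClimateInputs, GridSpec, MonthlyStack,
                        Raster, SoilMoistureState, casa_npp_month,
                        daily_to_monthly_precip, lst_dn_to_celsius, month_range,
                        priestley_taylor_pet, run_casa_class, soil_texture,
                        spin_up, temperature_scalar, water_balance_step)


class TestUnitConversions:
    @pytest.mark.parametrize("dn,expected", [
        (13657.5, 0.0), (15157.5, 30.0), (0.0, -273.15)])
    def test_lst_scaling(self, dn, expected):
        assert lst_dn_to_celsius(dn) == pytest.approx(expected, abs=1e-12)

    def test_lst_rejects_negative_dn(self):
        with pytest.raises(ValueError):
            lst_dn_to_celsius(-1.0)

    @pytest.mark.parametrize("daily,year,month,expected", [
        (2.0, 2003, 1, 62.0),   # 31-day month
        (1.0, 2000, 2, 29.0),   # leap February
        (1.0, 2001, 2, 28.0),
        (0.0, 2003, 7, 0.0)])
    def test_precip_monthly_total_leap_aware(self, daily, year, month, expected):
        assert daily_to_monthly_precip(daily, year, month) == expected

    def test_precip_invalid_month(self):
        with pytest.raises(ValueError):
            daily_to_monthly_precip(1.0, 2003, 13)


class TestTemperatureScalar:
    @staticmethod
    def _reference(t, topt):
        t1 = 0.8 + 0.02 * topt - 0.0005 * topt ** 2
        t2 = 1.1814 / ((1 + math.exp(0.2 * (topt - 10 - t)))
                       * (1 + math.exp(0.3 * (-topt - 10 + t))))
        return min(max(t1 * t2, 0.0), 1.0)

    @pytest.mark.parametrize("t,topt", [(20.0, 20.0), (5.0, 20.0),
                                        (35.0, 20.0), (0.0, 10.0), (25.0, 30.0)])
    def test_matches_closed_form(self, t, topt):
        assert temperature_scalar(t, topt) == pytest.approx(
            self._reference(t, topt), abs=1e-12)

    def test_vanishes_in_deep_cold(self):
        assert temperature_scalar(-100.0, 20.0) < 1e-6
        assert temperature_scalar(-1e6, 20.0) < 1e-300

    def test_unimodal_with_peak_near_optimum(self):
        grid = np.linspace(-30.0, 60.0, 1801)
        vals = temperature_scalar(grid, 20.0)
        peak = grid[int(np.argmax(vals))]
        assert abs(peak - 20.0) < 3.0
        # single sign change in the finite difference -> unimodal
        sign = np.sign(np.diff(vals))
        changes = np.count_nonzero(np.diff(sign[sign != 0]) != 0)
        assert changes == 1

    @given(t=st.floats(-80, 80), topt=st.floats(0, 35))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bounded_unit_interval(self, t, topt):
        assert 0.0 <= temperature_scalar(t, topt) <= 1.0


class TestPriestleyTaylorPet:
    def test_zero_radiation_gives_zero_pet(self):
        assert priestley_taylor_pet(15.0, 0.0) == 0.0

    def test_linear_in_radiation(self):
        assert priestley_taylor_pet(15.0, 400.0) == pytest.approx(
            2.0 * priestley_taylor_pet(15.0, 200.0), rel=1e-12)
        assert priestley_taylor_pet(15.0, 400.0) > priestley_taylor_pet(15.0, 300.0)

    def test_matches_closed_form_at_20C(self):
        delta = 4098.0 * 0.6108 * math.exp(17.27 * 20 / (20 + 237.3)) / (20 + 237.3) ** 2
        expected = 1.26 * delta / (delta + 0.066) * 400.0 / 2.45
        assert priestley_taylor_pet(20.0, 400.0) == pytest.approx(expected, abs=1e-9)


class TestSoilTextureConfig:
    def test_yaml_map_with_defaults_and_overrides(self, tmp_path):
        from casafusion import soil_textures_from_yaml
        path = tmp_path / "soil.yaml"
        path.write_text(
            "1: {class: organic}\n"
            "2: {class: lithosol, capacities: [5, 20, 40], rooting_multiplier: 1.8}\n")
        textures = soil_textures_from_yaml(path)
        assert textures[1].layer_capacity == (40.0, 150.0, 300.0)
        assert textures[2].layer_capacity == (5, 20, 40)
        assert textures[2].effective_capacity[2] == pytest.approx(72.0)

    def test_unknown_class_code_rejected(self):
        with pytest.raises(ValueError, match="unknown soil texture"):
            soil_texture("sand")


def fresh_state(soil, fill=0.5):
    return SoilMoistureState(soil.effective_capacity * fill)


class TestWaterBalance:
    def test_no_forcing_is_a_fixed_point(self):
        soil = soil_texture("clay_5_15")
        state = fresh_state(soil)
        new, eet, w, drainage = water_balance_step(state, 0.0, 0.0, soil)
        np.testing.assert_array_equal(new.layers, state.layers)
        assert (eet, drainage, w) == (0.0, 0.0, 1.0)

    def test_saturated_soil_sheds_all_rain_as_drainage(self):
        soil = soil_texture("organic")
        state = SoilMoistureState(soil.effective_capacity.copy())
        new, eet, w, drainage = water_balance_step(state, 50.0, 0.0, soil)
        assert drainage == 50.0
        assert eet == 0.0
        np.testing.assert_array_equal(new.layers, state.layers)

    def test_dry_soil_limits_evapotranspiration(self):
        soil = soil_texture("lithosol")
        state = SoilMoistureState(np.array([1.0, 2.0, 3.0]))
        new, eet, w, drainage = water_balance_step(state, 4.0, 100.0, soil)
        assert eet == pytest.approx(4.0 + 6.0)  # precip + all extractable
        np.testing.assert_allclose(new.layers, 0.0)
        assert w == pytest.approx(0.5 + 0.5 * 10.0 / 100.0)

    def test_extraction_is_top_down(self):
        soil = soil_texture("organic")
        state = SoilMoistureState(np.array([10.0, 10.0, 10.0]))
        new, _, _, _ = water_balance_step(state, 0.0, 12.0, soil)
        np.testing.assert_allclose(new.layers, [0.0, 8.0, 10.0])

    def test_rooting_multiplier_expands_subsoil_store(self):
        base = soil_texture("clay_ge_30")
        deep = soil_texture("clay_ge_30", rooting_multiplier=1.8)
        assert deep.effective_capacity[2] == pytest.approx(1.8 * base.effective_capacity[2])
        assert np.array_equal(deep.effective_capacity[:2], base.effective_capacity[:2])

    @given(st.lists(st.tuples(st.floats(0, 300), st.floats(0, 300)),
                    min_size=1, max_size=36))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_budget_closes_under_random_forcing(self, forcing):
        soil = soil_texture("clay_15_30")
        state = fresh_state(soil)
        for precip, pet in forcing:
            before = state.total
            state, eet, w, drainage = water_balance_step(state, precip, pet, soil)
            assert precip == pytest.approx(
                (state.total - before) + eet + drainage, abs=1e-9)
            assert 0.5 <= w <= 1.0
            assert (state.layers >= -1e-12).all()
            assert (state.layers <= soil.effective_capacity + 1e-12).all()


class TestSpinUp:
    @staticmethod
    def _climate(spec, keys, temp, precip, solar):
        def stack(v):
            return MonthlyStack({k: Raster(spec, np.full(spec.shape, v)) for k in keys})
        return ClimateInputs(stack(temp), stack(precip), stack(solar))

    def test_wet_climate_fills_to_capacity(self):
        spec = GridSpec(0, 1, 0.5, 2, 2)
        keys = month_range((2001, 1), 24)
        soil = soil_texture("lithosol")
        state = spin_up(self._climate(spec, keys, 10.0, 500.0, 100.0), soil)
        np.testing.assert_allclose(state.layers.sum(axis=0),
                                   soil.effective_capacity.sum())

    def test_zero_precip_drains_to_empty(self):
        spec = GridSpec(0, 1, 0.5, 2, 2)
        keys = month_range((2001, 1), 24)
        state = spin_up(self._climate(spec, keys, 20.0, 0.0, 400.0),
                        soil_texture("clay_5_15"))
        np.testing.assert_allclose(state.layers, 0.0, atol=1e-9)

    def test_deterministic(self):
        spec = GridSpec(0, 1, 0.5, 2, 2)
        keys = month_range((2001, 1), 24)
        climate = self._climate(spec, keys, 10.0, 60.0, 300.0)
        a = spin_up(climate, soil_texture("organic"))
        b = spin_up(climate, soil_texture("organic"))
        np.testing.assert_array_equal(a.layers, b.layers)

    def test_too_short_climate_raises(self):
        spec = GridSpec(0, 1, 0.5, 2, 2)
        keys = month_range((2001, 1), 12)
        with pytest.raises(ValueError, match="24"):
            spin_up(self._climate(spec, keys, 10.0, 60.0, 300.0),
                    soil_texture("organic"))


class TestNppMonth:
    def test_multiplicative_structure(self):
        assert casa_npp_month(100.0, 0.0, 0.55, 1.0, 1.0) == 0.0
        assert casa_npp_month(100.0, 1.0, 0.55, 1.0, 1.0) == pytest.approx(55.0)
        base = casa_npp_month(100.0, 0.5, 0.55, 0.8, 0.7)
        assert casa_npp_month(200.0, 0.5, 0.55, 0.8, 0.7) == pytest.approx(2 * base)

    def test_negative_ivi_floored_when_nonnegative(self):
        assert casa_npp_month(100.0, -0.1, 0.55, 1.0, 1.0) == 0.0
        assert casa_npp_month(100.0, -0.1, 0.55, 1.0, 1.0,
                              npp_nonnegative=False) < 0.0

    def test_monotone_in_each_factor(self, rng):
        sr, ivi, t, w = 300.0, 0.5, 0.7, 0.8
        base = casa_npp_month(sr, ivi, 0.55, t, w)
        assert casa_npp_month(sr + 50, ivi, 0.55, t, w) >= base
        assert casa_npp_month(sr, ivi + 0.1, 0.55, t, w) >= base
        assert casa_npp_month(sr, ivi, 0.55, t + 0.1, w) >= base
        assert casa_npp_month(sr, ivi, 0.55, t, w + 0.1) >= base


def _uniform_climate(spec, keys, temp=15.0, precip=80.0, solar=400.0):
    def stack(v):
        return MonthlyStack({k: Raster(spec, np.full(spec.shape, v)) for k in keys})
    return ClimateInputs(stack(temp), stack(precip), stack(solar))


class TestRunCasaClass:
    SPEC = GridSpec(-111.0, 45.0, 0.004, 5, 5)

    def _run(self, ivi_value=0.5, **kw):
        keys = month_range((2003, 1), 12)
        climate_keys = month_range((2001, 1), 36)
        climate = _uniform_climate(self.SPEC, climate_keys, **kw)
        ivi = MonthlyStack({k: Raster(self.SPEC, np.full(self.SPEC.shape, ivi_value))
                            for k in keys})
        return run_casa_class(ivi, climate, soil_texture("clay_5_15"),
                              CasaParams(topt=20.0))

    def test_uniform_inputs_give_uniform_npp(self):
        npp, _ = self._run()
        for key in npp.keys():
            vals = npp[key].values
            assert np.ptp(vals) == 0.0

    def test_zero_ivi_zero_npp_but_water_still_moves(self):
        npp, diag = self._run(ivi_value=0.0, precip=300.0)
        for key in npp.keys():
            np.testing.assert_array_equal(npp[key].values, 0.0)
        total_drainage = sum(float(diag["drainage"][k].values[0, 0])
                             for k in diag["drainage"].keys())
        assert total_drainage > 0.0

    def test_grid_run_equals_scalar_composition(self):
        """A pixel of the gridded run must equal the hand-chained scalar ops."""
        npp, diag = self._run()
        soil = soil_texture("clay_5_15")
        state = SoilMoistureState(soil.effective_capacity / 2.0)
        pet = priestley_taylor_pet(15.0, 400.0)
        for _ in range(24):  # spin-up months, identical uniform forcing
            state, _, _, _ = water_balance_step(state, 80.0, pet, soil)
        ts = temperature_scalar(15.0, 20.0)
        for key in npp.keys():
            state, eet, w, drainage = water_balance_step(state, 80.0, pet, soil)
            expected = casa_npp_month(400.0, 0.5, 0.55, ts, w)
            assert npp[key].values[2, 3] == pytest.approx(expected, abs=1e-9)
            assert diag["w_scalar"][key].values[2, 3] == pytest.approx(w, abs=1e-12)

    def test_warm_wet_limit_reaches_closed_form(self):
        """Saturating moisture and optimal temperature reduce NPP to
        Sr * IVI * e_max * T(topt, topt)."""
        npp, _ = self._run(temp=20.0, precip=10000.0)
        expected = 400.0 * 0.5 * 0.55 * temperature_scalar(20.0, 20.0) * 1.0
        last = npp.keys()[-1]
        assert npp[last].values[0, 0] == pytest.approx(expected, abs=1e-9)

    def test_misaligned_grids_raise(self):
        keys = month_range((2003, 1), 12)
        climate = _uniform_climate(self.SPEC, month_range((2001, 1), 36))
        other = GridSpec(0.0, 1.0, 0.004, 5, 5)
        ivi = MonthlyStack({k: Raster(other, np.full((5, 5), 0.5)) for k in keys})
        with pytest.raises(ValueError, match="aligned"):
            run_casa_class(ivi, climate, soil_texture("organic"))

    def test_scalar_stacks_within_bounds(self):
        _, diag = self._run()
        for key in diag["t_scalar"].keys():
            t = diag["t_scalar"][key].values
            w = diag["w_scalar"][key].values
            assert ((t >= 0) & (t <= 1)).all()
            assert ((w >= 0.5) & (w <= 1)).all()
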