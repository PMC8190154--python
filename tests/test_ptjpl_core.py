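import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest

from fieldet import ptjpl_core as pt
from fieldet import synthetic_data as sd
from fieldet.forcing_io import daytime_mask
from fieldet.ptjpl_core import PTJPLParams

PARAMS = PTJPLParams()


class TestMetDerivatives:
    def test_saturation_gives_zero_vpd(self):
        md = pt.met_derivatives(20.0, 1.0)
        assert md["vpd"] == pytest.approx(0.0, abs=1e-12)

    def test_delta_at_20c(self):
        # direct evaluation of the Magnus/FAO-56 forms
        e_sat = 0.6108 * math.exp(17.27 * 20 / (20 + 237.3))
        expected = 4098 * e_sat / (20 + 237.3) ** 2
        md = pt.met_derivatives(20.0, 0.5)
        assert md["delta"] == pytest.approx(expected, rel=1e-12)
        assert md["delta"] == pytest.approx(0.1448, abs=2e-4)

    def test_esat_vpd_at_25c(self):
        md = pt.met_derivatives(25.0, 0.5)
        assert md["e_sat"] == pytest.approx(3.168, abs=2e-3)
        assert md["vpd"] == pytest.approx(1.584, abs=1e-3)

    def test_out_of_range_ta_rejected(self):
        with pytest.raises(ValueError):
            pt.met_derivatives(70.0, 0.5)


class TestVegetationIndices:
    def test_fipar_offset_boundary(self):
        veg = pt.vegetation_indices(0.05, PARAMS)
        assert veg["f_ipar"] == 0.0

    def test_ndvi_08_reference_values(self):
        veg = pt.vegetation_indices(0.8, PARAMS)
        assert veg["savi"] == pytest.approx(0.492, rel=1e-12)
        assert veg["f_apar"] == pytest.approx(1.3632 * 0.492 - 0.048, rel=1e-12)
        assert veg["f_apar"] == pytest.approx(0.6227, abs=1e-4)
        assert veg["f_ipar"] == pytest.approx(0.75, rel=1e-12)
        assert veg["lai"] == pytest.approx(-math.log(0.25) / 0.5, rel=1e-12)
        assert veg["lai"] == pytest.approx(2.7726, abs=1e-4)

    def test_bare_or_water_clips_to_zero(self):
        veg = pt.vegetation_indices(-0.3, PARAMS)
        assert veg["f_apar"] == 0.0
        assert veg["f_ipar"] == 0.0
        assert veg["lai"] == 0.0


class TestConstraints:
    def _cons(self, ta, rh, ndvi=0.8, topt=25.0, f_apar_max=0.7):
        params = PARAMS.with_topt(topt)
        md = pt.met_derivatives(ta, rh)
        veg = pt.vegetation_indices(ndvi, params)
        return pt.constraints(md, veg, params, f_apar_max, ta=ta, rh=rh)

    def test_fwet_is_rh_fourth(self):
        assert self._cons(20.0, 0.5).f_wet == pytest.approx(0.0625, rel=1e-12)

    def test_ft_is_one_at_topt(self):
        assert self._cons(25.0, 0.5, topt=25.0).f_t == pytest.approx(1.0, rel=1e-12)

    def test_fsm_is_one_when_vpd_zero(self):
        assert self._cons(20.0, 1.0).f_sm == pytest.approx(1.0)

    def test_fg_zero_when_fipar_zero(self):
        cons = self._cons(20.0, 0.5, ndvi=0.05)
        assert cons.f_g == 0.0

    def test_invalid_topt_rejected(self):
        with pytest.raises(ValueError):
            PARAMS.with_topt(-1.0)


class TestEstimateTopt:
    @staticmethod
    def _met(ta, rh, rn, start="2019-06-01"):
        index = pd.date_range(start, periods=len(ta), freq="h")
        return pd.DataFrame(
            {"Ta": ta, "RH": rh, "Rn": rn, "G": 0.0, "H": 0.0, "LE": 0.0, "P": 0.0},
            index=index,
        )

    def test_singleton(self):
        met = self._met([22.0], [0.5], [500.0])
        ndvi = pd.Series([0.7], index=pd.Index([dt.date(2019, 6, 1)]))
        assert pt.estimate_topt(met, ndvi) == 22.0

    def test_argmax_of_two(self):
        # same NDVI/RH; score ~ Rn*Ta/VPD; make the 28-degree hour win
        met = self._met([18.0, 28.0], [0.5, 0.5], [200.0, 900.0])
        ndvi = pd.Series([0.7], index=pd.Index([dt.date(2019, 6, 1)]))
        assert pt.estimate_topt(met, ndvi) == 28.0

    def test_fallback_without_daytime(self):
        met = self._met([20.0], [0.5], [0.0])
        ndvi = pd.Series([0.7], index=pd.Index([dt.date(2019, 6, 1)]))
        assert pt.estimate_topt(met, ndvi) == 25.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            pt.estimate_topt(self._met([], [], []), pd.Series(dtype=float))

    def test_matches_exhaustive_scan(self, small_scene):
        cfg, stack, met, _, _, _ = small_scene
        r, c = sd.tower_pixel(cfg)
        ndvi = sd.ndvi_series_at(stack, r, c)
        # brute force: loop every hour, recompute the score independently
        best, best_ta = -np.inf, 25.0
        for ts, row in met.iterrows():
            if row["Rn"] <= 0:
                continue
            e_sat = 0.6108 * math.exp(17.27 * row["Ta"] / (row["Ta"] + 237.3))
            vpd = e_sat * (1 - row["RH"])
            if vpd <= 0:
                continue
            savi = 0.45 * ndvi[ts.date()] + 0.132
            f_apar = min(max(1.3632 * savi - 0.048, 0.0), 1.0)
            score = f_apar * row["Rn"] * row["Ta"] / vpd
            if score > best:
                best, best_ta = score, row["Ta"]
        assert pt.estimate_topt(met, ndvi) == pytest.approx(best_ta, rel=1e-12)


class TestRadiationPartition:
    def test_bare_soil(self):
        part = pt.radiation_partition(500.0, 0.0, PARAMS)
        assert part["rn_s"] == 500.0
        assert part["rn_c"] == 0.0

    def test_reference_lai(self):
        part = pt.radiation_partition(1.0, 2.7726, PARAMS)
        assert part["rn_s"] == pytest.approx(math.exp(-0.6 * 2.7726), rel=1e-12)
        assert part["rn_s"] == pytest.approx(0.1895, abs=2e-4)

    def test_closure(self):
        rng = np.random.default_rng(3)
        rn = rng.uniform(0, 800, 100)
        lai = rng.uniform(0, 6, 100)
        part = pt.radiation_partition(rn, lai, PARAMS)
        np.testing.assert_allclose(part["rn_s"] + part["rn_c"], rn, rtol=1e-12)


class TestSoilHeatFlux:
    def test_cosine_argument_zero(self):
        g = pt.soil_heat_flux(400.0, -10800.0, PARAMS)
        assert g == pytest.approx(PARAMS.g_amplitude * 400.0, rel=1e-12)

    def test_zero_crossing(self):
        # cos(2*pi*(t + 10800)/74000) = 0 at t = 74000/4 - 10800 = 7700
        assert pt.soil_heat_flux(400.0, 7700.0, PARAMS) == pytest.approx(0.0, abs=1e-9)

    def test_zero_soil_radiation(self):
        assert pt.soil_heat_flux(0.0, 0.0, PARAMS) == 0.0

    def test_never_negative(self):
        t = np.linspace(-43200, 43200, 1000)
        g = pt.soil_heat_flux(300.0, t, PARAMS)
        assert (g >= 0).all()


class TestComputeFluxes:
    def test_unconstrained_priestley_taylor_limit(self):
        md = pt.met_derivatives(25.0, 0.6)
        cons = pt.Constraints(
            f_g=np.array(1.0), f_wet=np.array(0.0), f_t=np.array(1.0),
            f_m=np.array(1.0), f_sm=np.array(1.0),
        )
        rn, g = 600.0, 40.0
        rn_s, rn_c = 250.0, 350.0
        fluxes = pt.compute_fluxes(md, cons, rn_c, rn_s, g, PARAMS)
        expected = PARAMS.alpha * md["delta"] / (md["delta"] + PARAMS.gamma) * (rn - g)
        assert fluxes.le_total == pytest.approx(expected, rel=1e-12)

    def test_all_constraints_zero(self):
        md = pt.met_derivatives(25.0, 0.6)
        cons = pt.Constraints(*(np.array(0.0) for _ in range(5)))
        fluxes = pt.compute_fluxes(md, cons, 350.0, 250.0, 40.0, PARAMS)
        assert fluxes.le_total == 0.0

    def test_spreadsheet_oracle(self):
        """Step-by-step independent evaluation, Ta=25, RH=0.6, Rn=600,
        NDVI=0.8, Topt=25, solar noon."""
        ta, rh, rn, ndvi = 25.0, 0.6, 600.0, 0.8
        params = PARAMS.with_topt(25.0)

        # psychrometrics
        e_sat = 0.6108 * math.exp(17.27 * ta / (ta + 237.3))
        vpd = e_sat * (1 - rh)
        delta = 4098 * e_sat / (ta + 237.3) ** 2
        # vegetation
        savi = 0.45 * ndvi + 0.132
        f_apar = 1.3632 * savi - 0.048
        f_ipar = ndvi - 0.05
        lai = -math.log(1 - f_ipar) / 0.5
        f_apar_max = 0.7
        # constraints
        f_wet = rh**4
        f_g = f_apar / f_ipar if f_apar / f_ipar < 1 else 1.0
        f_t = math.exp(-(((ta - 25.0) / 25.0) ** 2))
        f_m = f_apar / f_apar_max
        f_sm = rh ** (vpd / 1.0)
        # radiation and soil heat flux at solar noon
        rn_s = rn * math.exp(-0.6 * lai)
        rn_c = rn - rn_s
        g = max(0.31 * math.cos(2 * math.pi * (0.0 + 10800) / 74000) * rn_s, 0.0)
        pt_term = 1.26 * delta / (delta + 0.066)
        le_c = (1 - f_wet) * f_g * f_t * f_m * pt_term * rn_c
        le_s = (f_wet + f_sm * (1 - f_wet)) * pt_term * max(rn_s - g, 0.0)
        le_i = f_wet * pt_term * rn_c

        md = pt.met_derivatives(ta, rh)
        veg = pt.vegetation_indices(ndvi, params)
        cons = pt.constraints(md, veg, params, f_apar_max, ta=ta, rh=rh)
        part = pt.radiation_partition(rn, veg["lai"], params)
        g_mod = pt.soil_heat_flux(part["rn_s"], 0.0, params)
        fluxes = pt.compute_fluxes(md, cons, part["rn_c"], part["rn_s"], g_mod, params)

        assert float(g_mod) == pytest.approx(g, abs=1e-9)
        assert float(fluxes.le_c) == pytest.approx(le_c, abs=1e-9)
        assert float(fluxes.le_s) == pytest.approx(le_s, abs=1e-9)
        assert float(fluxes.le_i) == pytest.approx(le_i, abs=1e-9)
        assert float(fluxes.le_total) == pytest.approx(le_s + le_c + le_i, abs=1e-9)


class TestRunScene:
    def test_uniform_grid_gives_uniform_rasters(self, small_scene):
        cfg, stack, met, _, _, _ = small_scene
        date = stack.dates[len(stack.dates) // 2]
        met_day = met[pd.Index([t.date() for t in met.index]) == date]
        f_apar_max = pt.f_apar_max_from_stack(stack)
        _, fluxes = pt.run_scene(
            stack, date, met_day, PARAMS.with_topt(20.0), f_apar_max,
            cfg.longitude, cfg.timezone,
        )
        for hour_slice in fluxes.le_total:
            assert np.ptp(hour_slice) == 0.0

    def test_pointwise_oracle(self, small_scene):
        cfg, stack, met, _, _, _ = small_scene
        date = stack.dates[40]
        met_day = met[pd.Index([t.date() for t in met.index]) == date]
        params = PARAMS.with_topt(20.0)
        f_apar_max = pt.f_apar_max_from_stack(stack, params)
        hours, fluxes = pt.run_scene(
            stack, date, met_day, params, f_apar_max, cfg.longitude, cfg.timezone
        )
        r, c = 3, 11
        day = met_day[daytime_mask(met_day)]
        for k, (ts, row) in enumerate(day.iterrows()):
            md = pt.met_derivatives(row["Ta"], row["RH"])
            veg = pt.vegetation_indices(stack.grid_for(date)[r, c], params)
            cons = pt.constraints(md, veg, params, f_apar_max[r, c], ta=row["Ta"], rh=row["RH"])
            part = pt.radiation_partition(row["Rn"], veg["lai"], params)
            t_solar = pt.solar_seconds(pd.DatetimeIndex([ts]), cfg.longitude, cfg.timezone)
            g = pt.soil_heat_flux(part["rn_s"], t_solar[0], params)
            fx = pt.compute_fluxes(md, cons, part["rn_c"], part["rn_s"], g, params)
            assert float(fx.le_total) == pytest.approx(fluxes.le_total[k, r, c], rel=1e-12)

    def test_nighttime_excluded(self, small_scene):
        cfg, stack, met, _, _, _ = small_scene
        date = stack.dates[10]
        met_day = met[pd.Index([t.date() for t in met.index]) == date]
        hours, fluxes = pt.run_scene(
            stack, date, met_day, PARAMS.with_topt(20.0),
            pt.f_apar_max_from_stack(stack), cfg.longitude, cfg.timezone,
        )
        n_day = int(daytime_mask(met_day).sum())
        assert fluxes.le_total.shape[0] == len(hours) == n_day

    def test_missing_date_errors(self, small_scene):
        cfg, stack, met, _, _, _ = small_scene
        with pytest.raises(KeyError):
            stack.grid_for(dt.date(2030, 1, 1))
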