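"""Soil water bucket, limited growth, sward ageing and the nitrogen cycle."""

import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cowcalf.climate import DailyWeather, synthesize_weather
from cowcalf.pasture import (
    NFluxes,
    SoilParams,
    SoilState,
    SpeciesParams,
    SwardState,
    WaterFluxes,
    age_and_senesce,
    daily_growth,
    me_from_digestibility,
    nitrogen_cycle,
    temperature_factor,
    update_soil_water,
    wfps,
)

DAY = dt.date(2000, 3, 1)


def _species(**kw):
    base = dict(pathway="C3", rue=0.7, t_base=3.5, t_opt=17.0, t_max=33.0,
                max_growth=60.0, senescence_rate=0.02, digestibility_new=73.0,
                digestibility_floor=52.0, quality_decay=0.1,
                legume_fraction=0.2, fixation_coeff=0.04)
    base.update(kw)
    return SpeciesParams(**base)


def _weather(tmin=10.0, tmax=20.0, rain=0.0, rad=20.0):
    return DailyWeather(DAY, tmin, tmax, rain, rad, 1.0)


class TestSoilWater:
    def test_empty_bucket_stays_empty_without_rain(self):
        soil = SoilState(water=0.0, mineral_n=5.0, organic_n=100.0)
        out, fx = update_soil_water(soil, _weather(), SoilParams(capacity=80.0))
        assert out.water == 0.0
        assert fx.et == 0.0
        assert fx.drainage == 0.0

    def test_full_bucket_overflows_rainfall(self):
        sp = SoilParams(capacity=80.0)
        soil = SoilState(water=80.0, mineral_n=5.0, organic_n=100.0)
        out, fx = update_soil_water(soil, _weather(rain=100.0), sp)
        assert out.water == pytest.approx(80.0)
        assert fx.drainage == pytest.approx(100.0 - fx.et)

    def test_annual_water_balance_closes_below_point1_mm(self, sites):
        sp = sites["dookie"].soil
        met = synthesize_weather(sites["dookie"].climate, 1, seed=2)
        soil = SoilState(water=0.5 * sp.capacity, mineral_n=10.0, organic_n=300.0)
        start = soil.water
        rain = et = drain = 0.0
        for row in met.itertuples(index=False):
            w = DailyWeather(row.date, row.tmin_c, row.tmax_c, row.rain_mm,
                             row.rad_mj_m2, row.vp_kpa)
            soil, fx = update_soil_water(soil, w, sp)
            rain += fx.rain
            et += fx.et
            drain += fx.drainage
        assert abs(rain - et - drain - (soil.water - start)) < 0.1


class TestGrowth:
    def test_dry_soil_stops_growth(self):
        sward = SwardState(2.0, 0.5, 70.0, 60.0, 10.0)
        soil = SoilState(water=0.0, mineral_n=50.0, organic_n=300.0)
        assert daily_growth(sward, soil, _weather(), _species(), SoilParams(80.0)) == 0.0

    def test_unconstrained_growth_is_rue_radiation_capped(self):
        sp = _species(max_growth=500.0, cover_scale=1e-9)  # full light interception
        soil_p = SoilParams(capacity=80.0, )
        soil = SoilState(water=80.0, mineral_n=1e6, organic_n=300.0)
        sward = SwardState(3.0, 0.0, 70.0, 90.0, 0.0)
        w = _weather(tmin=17.0, tmax=17.0, rad=20.0)  # tmean at t_opt
        g = daily_growth(sward, soil, w, sp, soil_p)
        assert g == pytest.approx(sp.rue * 20.0 * 10.0, rel=1e-4)
        sp_capped = _species(max_growth=60.0, cover_scale=1e-9)
        assert daily_growth(sward, soil, w, sp_capped, soil_p) == 60.0

    @settings(max_examples=60, deadline=None)
    @given(water=st.floats(0.0, 80.0), mineral=st.floats(0.0, 60.0),
           rad=st.floats(0.0, 35.0), bump=st.floats(0.0, 20.0))
    def test_growth_monotone_in_water_nitrogen_radiation(self, water, mineral, rad, bump):
        sp = _species()
        soil_p = SoilParams(capacity=80.0)
        sward = SwardState(1.5, 0.5, 68.0, 45.0, 8.0)

        def g(wat, minn, radiation):
            soil = SoilState(water=wat, mineral_n=minn, organic_n=200.0)
            return daily_growth(sward, soil, _weather(rad=radiation), sp, soil_p)

        base = g(water, mineral, rad)
        assert g(min(80.0, water + bump), mineral, rad) >= base
        assert g(water, mineral + bump, rad) >= base
        assert g(water, mineral, rad + bump) >= base

    def test_c4_temperature_optimum_above_c3(self, sites):
        c4 = sites["albany"].species
        c3 = sites["dookie"].species
        temps = [t / 2.0 for t in range(0, 90)]
        assert max(temps, key=lambda t: temperature_factor(t, c4)) > \
            max(temps, key=lambda t: temperature_factor(t, c3))


class TestSwardAgeing:
    def test_quality_decays_to_floor_without_growth(self):
        sp = _species()
        sward = SwardState(1.0, 0.2, sp.digestibility_new, 30.0, 4.0)
        for _ in range(400):
            sward, _, _ = age_and_senesce(sward, 0.0, sp)
        assert sward.green_digestibility == pytest.approx(sp.digestibility_floor)

    def test_all_new_sward_has_new_growth_quality(self):
        sp = _species()
        sward = SwardState(0.0, 0.0, sp.digestibility_new, 0.0, 0.0)
        sward, _, _ = age_and_senesce(sward, 30.0, sp)
        assert sward.green_digestibility == pytest.approx(sp.digestibility_new)

    def test_digestibility_me_map_hits_calibration_pairs(self):
        sp = _species()
        assert me_from_digestibility(60.0, sp) == pytest.approx(9.7, abs=0.01)
        assert me_from_digestibility(63.0, sp) == pytest.approx(10.2, abs=0.01)


class TestNitrogen:
    def _soil_p(self, **kw):
        base = dict(capacity=80.0, k_denit=0.01, wfps_anaerobic=0.6,
                    wfps_at_capacity=1.0, leach_eff=0.3)
        base.update(kw)
        return SoilParams(**base)

    def test_no_denitrification_below_anaerobic_threshold(self):
        sp = self._soil_p()
        soil = SoilState(water=0.5 * 80.0, mineral_n=30.0, organic_n=200.0)
        assert wfps(soil, sp) < sp.wfps_anaerobic
        _, nf = nitrogen_cycle(soil, 0.0, WaterFluxes(0, 0, 0), _weather(),
                               _species(), sp)
        assert nf.denit_n == 0.0

    def test_no_leaching_without_drainage(self):
        sp = self._soil_p()
        soil = SoilState(water=40.0, mineral_n=30.0, organic_n=200.0)
        _, nf = nitrogen_cycle(soil, 0.0, WaterFluxes(5.0, 5.0, 0.0), _weather(),
                               _species(), sp)
        assert nf.leach_n == 0.0

    def test_denitrification_monotone_in_wfps_above_threshold(self):
        sp = self._soil_p()
        w = _weather(tmin=15.0, tmax=25.0)
        prev = 0.0
        for fill in (0.61, 0.7, 0.8, 0.9, 1.0):
            soil = SoilState(water=fill * 80.0, mineral_n=30.0, organic_n=200.0)
            _, nf = nitrogen_cycle(soil, 0.0, WaterFluxes(0, 0, 0), w, _species(), sp)
            assert nf.denit_n > prev
            prev = nf.denit_n

    def test_fixation_proportional_to_legume_growth(self):
        sp = self._soil_p()
        species = _species(legume_fraction=0.25, fixation_coeff=0.04)
        soil = SoilState(water=40.0, mineral_n=10.0, organic_n=200.0)
        _, nf = nitrogen_cycle(soil, 50.0, WaterFluxes(0, 0, 0), _weather(),
                               species, sp)
        assert nf.fixation == pytest.approx(0.25 * 50.0 * 0.04)

    def test_albany_supplemented_fixation_in_calibration_window(self, system_runs):
        summaries, _ = system_runs[("albany", True)]
        mean_fix = sum(s.fixation_n for s in summaries) / len(summaries)
        assert 58.0 <= mean_fix <= 65.0

    def test_kikuyu_diet_poorer_than_phalaris_sites(self, system_runs):
        def mean_d(name):
            vals = [s.diet_digestibility
                    for mode in (False, True)
                    for s in system_runs[(name, mode)][0]]
            return sum(vals) / len(vals)

        albany = mean_d("albany")
        for other in ("dookie", "vasey", "wagga"):
            assert albany < mean_d(other)
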