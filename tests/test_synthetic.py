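"""Generators: solar geometry, snow fields, light chains, Chl-a, incubations."""

import datetime as dt
import math

import numpy as np
import pytest

from icebloom.config import LeadEvent, ScenarioConfig
from icebloom.productivity import net_npp, split_event
from icebloom.snow_optics import SnowOpticsModel, snow_transmissivity
from icebloom import synthetic as syn

UTC = dt.timezone.utc


# -- independent solar-position oracle (NOAA-style, different algorithm) -----

def noaa_solar_elevation(lat_deg, when):
    """Solar elevation from the NOAA general solar position equations."""
    doy = when.timetuple().tm_yday
    frac_hour = when.hour + when.minute / 60
    gamma = 2 * math.pi / 365 * (doy - 1 + (frac_hour - 12) / 24)
    eqtime = 229.18 * (0.000075 + 0.001868 * math.cos(gamma)
                       - 0.032077 * math.sin(gamma)
                       - 0.014615 * math.cos(2 * gamma)
                       - 0.040849 * math.sin(2 * gamma))
    decl = (0.006918 - 0.399912 * math.cos(gamma) + 0.070257 * math.sin(gamma)
            - 0.006758 * math.cos(2 * gamma) + 0.000907 * math.sin(2 * gamma)
            - 0.002697 * math.cos(3 * gamma) + 0.00148 * math.sin(3 * gamma))
    tst = frac_hour * 60 + eqtime  # longitude 0
    ha = math.radians(tst / 4 - 180)
    lat = math.radians(lat_deg)
    cos_zen = (math.sin(lat) * math.sin(decl)
               + math.cos(lat) * math.cos(decl) * math.cos(ha))
    return 90 - math.degrees(math.acos(max(-1, min(1, cos_zen))))


class TestSurfacePar:
    def test_polar_night_is_all_dark(self):
        sp = syn.gen_surface_par(88.0, dt.date(2020, 1, 15), dt.date(2020, 1, 16))
        assert max(sp.par) == 0.0

    def test_equatorial_equinox_midday_reaches_scale(self):
        sp = syn.gen_surface_par(0.0, dt.date(2020, 3, 20), dt.date(2020, 3, 21),
                                 step_minutes=10, scale=2000.0)
        assert max(sp.par) == pytest.approx(2000.0, rel=0.01)

    def test_early_spring_high_arctic_day_night_cycle(self):
        sp = syn.gen_surface_par(84.0, dt.date(2020, 3, 28), dt.date(2020, 3, 29),
                                 step_minutes=60)
        par = dict(zip(sp.timestamps, sp.par))
        assert par[dt.datetime(2020, 3, 28, 12, tzinfo=UTC)] > 0
        assert par[dt.datetime(2020, 3, 28, 0, tzinfo=UTC)] == 0.0

    def test_elevation_agrees_with_independent_noaa_formula(self):
        for lat, when in [(84.0, dt.datetime(2020, 3, 28, 12, tzinfo=UTC)),
                          (84.0, dt.datetime(2020, 3, 28, 6, tzinfo=UTC)),
                          (0.0, dt.datetime(2020, 3, 20, 12, tzinfo=UTC)),
                          (-60.0, dt.datetime(2020, 2, 10, 15, tzinfo=UTC))]:
            ours = syn.solar_elevation(lat, when)
            noaa = noaa_solar_elevation(lat, when)
            # compare the irradiance-relevant quantity; near-zenith angles
            # are numerically touchy in degrees
            assert math.sin(math.radians(ours)) == pytest.approx(
                math.sin(math.radians(noaa)), abs=0.03)

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_surface_par(84.0, dt.date(2020, 3, 1), dt.date(2020, 3, 1))


class TestSnowField:
    def test_single_sample_keeps_requested_class(self):
        field = syn.gen_snow_field(1, class_mix={"rubble": 1.0}, seed=4)
        assert len(field) == 1 and field[0].surface_class == "rubble"

    def test_defaults_reproduce_transect_mean_range(self):
        field = syn.gen_snow_field(3000, seed=0)
        overall = np.mean([s.depth for s in field])
        assert 0.25 <= overall <= 0.30

    def test_per_class_means_within_three_standard_errors(self):
        field = syn.gen_snow_field(3000, seed=1)
        for cls, (mu, sd) in syn.SNOW_CLASS_PARAMS.items():
            depths = np.array([s.depth for s in field if s.surface_class == cls])
            se = sd / math.sqrt(depths.size)
            # truncation at 0.03 m shifts the level/rubble means negligibly
            assert abs(depths.mean() - mu) < 3 * se + 0.01

    def test_mean_transmissivity_exceeds_transmissivity_at_mean_depth(self):
        field = syn.gen_snow_field(2000, seed=2)
        depths = np.array([s.depth for s in field])
        model = SnowOpticsModel(kappa_snow=14.1)
        assert (snow_transmissivity(depths, model).mean()
                > snow_transmissivity(float(depths.mean()), model))

    def test_reproducible_and_param_validation(self):
        a = syn.gen_snow_field(50, seed=9)
        b = syn.gen_snow_field(50, seed=9)
        assert [(s.surface_class, s.depth) for s in a] == \
               [(s.surface_class, s.depth) for s in b]
        with pytest.raises(ValueError):
            syn.gen_snow_field(10, class_params={"level": (-0.1, 0.03),
                                                 "rubble": (0.28, 0.06),
                                                 "deformed": (0.33, 0.10)})


class TestLightChain:
    def _surface(self, scenario):
        return syn.gen_surface_par(scenario.latitude, dt.date(2020, 3, 28),
                                   dt.date(2020, 3, 29), step_minutes=240,
                                   scale=scenario.surface_scale)

    def test_noiseless_unshaded_profile_is_exact_exponential(self):
        sc = ScenarioConfig(sigma_log=0.0, shading_s=0.0, kappa_w=0.05)
        profiles = syn.gen_light_chain("hh", sc, self._surface(sc), 0.20)
        lit = [p for p in profiles if p.par[0] > 0]
        z = np.array(lit[0].depths)
        slope = np.polyfit(z, np.log(np.array(lit[0].par)), 1)[0]
        assert slope == pytest.approx(-0.05, abs=1e-12)

    def test_top_sensor_shading_deficit_matches_closed_form(self):
        sc = ScenarioConfig(sigma_log=0.0, shading_s=0.5, shading_ell=3.0)
        profiles = [p for p in syn.gen_light_chain("hh", sc, self._surface(sc), 0.20)
                    if p.par[0] > 0]
        p = profiles[0]
        unshaded = (p.par[1] / (1 - 0.5 * math.exp(-2 / 3.0))
                    * math.exp(sc.kappa_w * (p.depths[1] - p.depths[0])))
        assert p.par[0] / unshaded == pytest.approx(1 - 0.5 * math.exp(-1 / 3.0),
                                                    rel=1e-10)

    def test_lead_event_amplifies_by_configured_factor(self):
        lead = LeadEvent(site="hh", start=dt.date(2020, 3, 28), duration_days=3,
                         amplification=10.0)
        sc0 = ScenarioConfig(sigma_log=0.0)
        sc1 = ScenarioConfig(sigma_log=0.0, lead_events=(lead,))
        surf = self._surface(sc0)
        base = syn.gen_light_chain("hh", sc0, surf, 0.20)
        amp = syn.gen_light_chain("hh", sc1, surf, 0.20)
        for p0, p1 in zip(base, amp):
            lit = np.array(p0.par) > 0
            assert np.allclose(np.array(p1.par)[lit] / np.array(p0.par)[lit], 10.0)

    def test_nonpositive_ice_thickness_rejected(self):
        sc = ScenarioConfig()
        with pytest.raises(ValueError):
            syn.gen_light_chain("hh", sc, self._surface(sc), 0.20, ice_thickness=0.0)


class TestChlSeries:
    def test_noiseless_value_twenty_days_after_onset(self):
        sc = ScenarioConfig(sigma_log=0.0, baseline_chl=0.015, r_post=0.06)
        day = sc.onset_day + dt.timedelta(days=20)
        assert syn.chl_expectation(day, sc) == pytest.approx(0.015 * math.exp(1.2))
        # consistent with ~0.05 ug/L reached a few weeks after onset
        assert 0.045 < syn.chl_expectation(day, sc) < 0.055

    def test_zero_growth_rate_stays_at_baseline(self):
        sc = ScenarioConfig(sigma_log=0.15, r_post=0.0, seed=5)
        series = syn.gen_chl_series(sc.start, sc.end, sc).daily_average()
        vals = np.array(series.concentrations)
        assert abs(np.log(vals / sc.baseline_chl).mean()) < 0.05

    def test_fixed_seed_reproduces_series_exactly(self):
        sc = ScenarioConfig(sigma_log=0.2, seed=11)
        a = syn.gen_chl_series(sc.start, sc.end, sc)
        b = syn.gen_chl_series(sc.start, sc.end, sc)
        assert a.concentrations == b.concentrations

    def test_all_values_positive_and_onset_must_be_inside_range(self):
        sc = ScenarioConfig(sigma_log=0.3, seed=3)
        series = syn.gen_chl_series(sc.start, sc.end, sc)
        assert min(series.concentrations) > 0
        with pytest.raises(ValueError):
            syn.gen_chl_series(sc.onset_day + dt.timedelta(days=1), sc.end, sc)
        with pytest.raises(ValueError):
            ScenarioConfig(baseline_chl=0.0)


class TestIncubations:
    def test_zero_npp_sample_counts_equal_blank(self):
        event = syn.gen_incubations([0.0], seed=0)[0]
        light = [r for r in event if r.light]
        assert all(r.dpm_sample == pytest.approx(r.dpm_blank) for r in light)

    def test_round_trip_recovers_injected_net_rate(self):
        for truth in (1.0, 5.0):
            event = syn.gen_incubations([truth], dark_rate=0.3, seed=0)[0]
            res = net_npp(*split_event(event))
            assert res.net == pytest.approx(truth, rel=1e-10)

    def test_blank_is_configured_fraction_of_sample_counts(self):
        rec = syn.gen_incubations([1.0], blank_fraction=0.25, seed=0)[0][0]
        assert rec.dpm_blank == pytest.approx(0.25 * rec.dpm_sample)
        # the printed field average: a 500 DPM sample carries a 125 DPM blank
        assert 0.25 * 500 == 125

    def test_invalid_blank_fraction_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_incubations([1.0], blank_fraction=1.0)
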