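"""Sun path, clear-sky beam, mask sampling and dose accumulation."""

import datetime as dt
import warnings

import numpy as np
import pytest
from scipy.integrate import IntegrationWarning, quad

from canopylux.hemi_image import FisheyeGeometry, SkyMask, fov_valid_mask
from canopylux.solar import (
    MeteoDay,
    RadiationConfig,
    SolarPosition,
    accumulate_radiation,
    beam_transmission,
    clear_sky_day_total,
    clear_sky_direct,
    mean_daily_dose,
    solar_elevation_azimuth,
    sun_position,
)
from canopylux.synthetic import default_geometry, gen_met_series

from ._ephemeris import almanac_sun
from .conftest import HARVEST, OAKVILLE, RIPENING_START


def all_sky_mask(size=121, max_zenith=75.0) -> SkyMask:
    c = (size - 1) / 2
    geom = FisheyeGeometry(c, c, c, max_zenith=max_zenith)
    valid = fov_valid_mask((size, size), geom)
    return SkyMask(np.ones((size, size), bool), valid, geom)


class TestSunPosition:
    def test_equinox_noon_elevation(self, oak_config):
        pos = sun_position(dt.datetime(2017, 3, 20, 12, 17), oak_config)
        assert pos.elevation == pytest.approx(90 - 38.428, abs=0.5)

    def test_midnight_sun_below_horizon(self, oak_config):
        assert sun_position(dt.datetime(2017, 7, 24, 0, 0), oak_config).elevation < 0

    def test_summer_solar_noon_azimuth_south(self, oak_config):
        els, azs = solar_elevation_azimuth(
            [dt.datetime(2017, 6, 21, 12, m) for m in range(0, 60, 5)], oak_config
        )
        az_at_peak = azs[np.argmax(els)]
        assert az_at_peak == pytest.approx(180.0, abs=2.0)

    def test_against_almanac_ephemeris(self, oak_config):
        for local in [
            dt.datetime(2017, 3, 20, 9, 0),
            dt.datetime(2017, 6, 21, 15, 30),
            dt.datetime(2017, 12, 21, 11, 0),
            dt.datetime(2023, 8, 5, 14, 0),
        ]:
            el, az = solar_elevation_azimuth([local], oak_config)
            el2, az2 = almanac_sun(
                local - dt.timedelta(hours=oak_config.utc_offset),
                oak_config.latitude,
                oak_config.longitude,
            )
            assert abs(el[0] - el2) < 0.5
            assert abs(((az[0] - az2 + 180) % 360) - 180) < 0.5

    def test_era_bounds(self, oak_config):
        with pytest.raises(ValueError, match="era"):
            sun_position(dt.datetime(1900, 1, 1, 12), oak_config)


class TestClearSky:
    def test_below_horizon_is_zero(self, oak_config):
        assert clear_sky_direct(-5.0, oak_config) == 0.0

    def test_overhead_sun_close_to_air_mass_one(self, oak_config):
        # Kasten-Young air mass at 90 deg is 0.9997, not exactly 1
        assert clear_sky_direct(90.0, oak_config) == pytest.approx(
            1367 * 0.70, rel=1e-3
        )

    def test_strictly_increasing_with_elevation(self, oak_config):
        vals = clear_sky_direct(np.arange(1.0, 90.5, 0.5), oak_config)
        assert (np.diff(vals) > 0).all()


class TestBeamTransmission:
    def test_open_sky_transmits_fully(self, oak_config):
        mask = all_sky_mask()
        pos = SolarPosition(dt.datetime(2017, 8, 1, 12), elevation=60.0, azimuth=180.0)
        assert beam_transmission(mask, pos, oak_config) == 1.0

    def test_omission_ring_blocked(self, oak_config):
        # elevation 10 deg -> zenith 80 deg, beyond the 150-degree lens
        mask = all_sky_mask()
        pos = SolarPosition(dt.datetime(2017, 8, 1, 7), elevation=10.0, azimuth=90.0)
        assert beam_transmission(mask, pos, oak_config) == 0.0

    def test_below_horizon_blocked(self, oak_config):
        pos = SolarPosition(dt.datetime(2017, 8, 1, 22), elevation=-3.0, azimuth=300.0)
        assert beam_transmission(all_sky_mask(), pos, oak_config) == 0.0

    def test_half_covered_disc_on_boundary(self, oak_config):
        # sky for azimuth < 180 (east half), canopy west; sun disc on the edge
        size = 401
        c = (size - 1) / 2
        geom = FisheyeGeometry(c, c, c)
        valid = fov_valid_mask((size, size), geom)
        cols = np.arange(size)[None, :].repeat(size, axis=0)
        grid = (cols >= c) & valid  # image right half = azimuth in (0, 180)
        mask = SkyMask(grid, valid, geom)
        pos = SolarPosition(dt.datetime(2017, 8, 1, 12), elevation=50.0, azimuth=180.0)
        cfg = RadiationConfig(**OAKVILLE, beam_sampling_radius=6.0)
        assert beam_transmission(mask, pos, cfg) == pytest.approx(0.5, abs=0.05)


class TestAccumulation:
    def window_met(self, config, factor=1.0):
        return [
            MeteoDay(d, clear_sky_day_total(d, config) * factor)
            for d in (RIPENING_START + dt.timedelta(days=i) for i in range(47))
        ]

    def test_all_canopy_mask_receives_nothing(self, oak_config):
        mask = all_sky_mask()
        mask.grid[:] = False
        s = accumulate_radiation(mask, oak_config, self.window_met(oak_config),
                                 RIPENING_START, HARVEST)
        assert s.total_MJ == 0.0 and s.direct_MJ == 0.0 and s.diffuse_MJ == 0.0

    def test_open_site_matches_continuous_quadrature(self, oak_config):
        """c_d = 1 open-site dose equals the integral of the clear-sky model."""
        mask = all_sky_mask(max_zenith=90.0)  # full hemisphere: no blocked ring
        start, end = dt.date(2017, 8, 1), dt.date(2017, 8, 4)
        met = [MeteoDay(start + dt.timedelta(days=i),
                        clear_sky_day_total(start + dt.timedelta(days=i), oak_config))
               for i in range(3)]
        s = accumulate_radiation(mask, oak_config, met, start, end)

        def wm2(hours, day):
            t = dt.datetime.combine(day, dt.time()) + dt.timedelta(hours=hours)
            el, _ = solar_elevation_azimuth([t], oak_config)
            return clear_sky_direct(float(el[0]), oak_config)

        oracle = 0.0
        # the horizon kink limits adaptive subdivision; accuracy is checked
        # by the 1% agreement itself
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", IntegrationWarning)
            for i in range(3):
                day = start + dt.timedelta(days=i)
                direct_J = sum(
                    quad(wm2, a, b, args=(day,), limit=100)[0]
                    for a, b in ((0.0, 6.5), (6.5, 19.0), (19.0, 24.0))
                )
                oracle += direct_J * 3600 / 1e6 * (1 + oak_config.diffuse_fraction)
        assert s.total_MJ == pytest.approx(oracle, rel=0.01)

    def test_occlusion_monotonicity_for_nested_masks(self, oak_config, rng):
        start, end = dt.date(2017, 8, 1), dt.date(2017, 8, 3)
        met = [MeteoDay(start + dt.timedelta(days=i), 25.0) for i in range(2)]
        big = all_sky_mask()
        sub = SkyMask(big.grid & (rng.random(big.shape) < 0.6), big.valid,
                      big.geometry)
        t_big = accumulate_radiation(big, oak_config, met, start, end).total_MJ
        t_sub = accumulate_radiation(sub, oak_config, met, start, end).total_MJ
        assert t_sub <= t_big

    def test_met_correction_scales_direct_only(self, oak_config):
        """Cloudy day: direct share follows measured global; diffuse stays clear."""
        mask = all_sky_mask(max_zenith=90.0)
        start, end = dt.date(2017, 8, 1), dt.date(2017, 8, 2)
        clear = clear_sky_day_total(start, oak_config)
        s = accumulate_radiation(mask, oak_config,
                                 [MeteoDay(start, 0.5 * clear)], start, end)
        f = oak_config.diffuse_fraction
        direct_share = 1 / (1 + f)
        assert s.direct_MJ == pytest.approx(0.5 * clear * direct_share, rel=5e-3)
        assert s.diffuse_MJ == pytest.approx(clear * f / (1 + f), rel=5e-3)

    def test_cd_capped_against_unit_errors(self, oak_config):
        mask = all_sky_mask(max_zenith=90.0)
        start, end = dt.date(2017, 8, 1), dt.date(2017, 8, 2)
        clear = clear_sky_day_total(start, oak_config)
        s = accumulate_radiation(mask, oak_config,
                                 [MeteoDay(start, 10 * clear)], start, end)
        assert s.per_day["c_d"].iloc[0] == oak_config.cd_cap
        assert s.per_day["c_d_capped"].iloc[0]

    def test_timestep_halving_changes_total_under_one_percent(self):
        mask = all_sky_mask(max_zenith=90.0)
        start, end = dt.date(2017, 8, 1), dt.date(2017, 8, 2)
        totals = []
        for step in (10.0, 20.0):
            cfg = RadiationConfig(**OAKVILLE, timestep_min=step)
            met = [MeteoDay(start, clear_sky_day_total(start, cfg))]
            totals.append(accumulate_radiation(mask, cfg, met, start, end).total_MJ)
        assert abs(totals[1] - totals[0]) / totals[0] < 0.01

    def test_rotation_invariance_of_dose(self, oak_config, rng):
        """Rotating mask content and azimuth_offset together leaves dose fixed."""
        size = 121
        c = (size - 1) / 2
        geom0 = FisheyeGeometry(c, c, c)
        valid = fov_valid_mask((size, size), geom0)
        grid = (rng.random((size, size)) < 0.5) & valid
        # 90-degree image rotation == compass rotation by -90 for "up"
        grid_rot = np.rot90(grid, k=-1)
        geom_rot = FisheyeGeometry(c, c, c, azimuth_offset=270.0)
        start, end = dt.date(2017, 8, 1), dt.date(2017, 8, 3)
        met = [MeteoDay(start + dt.timedelta(days=i), 25.0) for i in range(2)]
        t0 = accumulate_radiation(SkyMask(grid, valid, geom0), oak_config,
                                  met, start, end).total_MJ
        t1 = accumulate_radiation(SkyMask(grid_rot, np.rot90(valid, k=-1), geom_rot),
                                  oak_config, met, start, end).total_MJ
        assert t1 == pytest.approx(t0, rel=1e-6)

    def test_missing_met_day_is_an_error(self, oak_config):
        with pytest.raises(ValueError, match="missing"):
            accumulate_radiation(all_sky_mask(), oak_config, [],
                                 dt.date(2017, 8, 1), dt.date(2017, 8, 2))

    def test_reversed_window_is_an_error(self, oak_config):
        with pytest.raises(ValueError, match="after"):
            accumulate_radiation(all_sky_mask(), oak_config, [],
                                 dt.date(2017, 8, 2), dt.date(2017, 8, 1))


class TestMeanDailyDose:
    def test_ripening_window_mean(self):
        assert mean_daily_dose(550.0, RIPENING_START, HARVEST) == pytest.approx(
            11.7, abs=0.05
        )

    def test_zero_dose(self):
        assert mean_daily_dose(0.0, RIPENING_START, HARVEST) == 0.0

    def test_simple_division(self):
        assert mean_daily_dose(100.0, dt.date(2017, 8, 1), dt.date(2017, 8, 11)) == 10.0

    def test_zero_length_period(self):
        with pytest.raises(ValueError, match="zero-length"):
            mean_daily_dose(5.0, HARVEST, HARVEST)


def test_gen_met_series_bounded_by_clear_sky(oak_config):
    days = gen_met_series(dt.date(2017, 8, 1), dt.date(2017, 8, 10), oak_config,
                          seed=3)
    for d in days:
        assert 0 < d.measured_global <= clear_sky_day_total(d.date, oak_config)
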