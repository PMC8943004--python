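"""Twilight detection, threshold positioning, calibration and MCMC refinement."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from nocmig import geolocation as geo, solar, synthetic as syn
from nocmig.gpsmetrics import great_circle_km
from nocmig.rasters import Raster

from conftest import make_twilight_frame


def _series(light, start="2018-09-01", freq="5min"):
    t = pd.date_range(start, periods=len(light), freq=freq)
    return pd.DataFrame({"timestamp": t, "light": light})


class TestDetectTwilights:
    def test_square_wave_crossings(self):
        day = [1.0] * 84 + [1000.0] * 120 + [1.0] * 84
        light = day * 3
        tw = geo.detect_twilights(_series(light), 10.0)
        assert len(tw) == 6
        assert list(tw["type"][:2]) == ["sunrise", "sunset"]
        # crossing within one 5-min interval of the true switch
        first_up = pd.Timestamp("2018-09-01") + pd.Timedelta(minutes=84 * 5)
        assert abs((tw["time"].iloc[0] - first_up).total_seconds()) <= 300

    def test_midday_dip_suppressed(self):
        day = [1.0] * 84 + [1000.0] * 57 + [2.0] * 6 + [1000.0] * 57 + [1.0] * 84
        tw = geo.detect_twilights(_series(day * 2), 10.0)
        assert (tw.groupby("date").size() <= 2).all()
        assert len(tw) == 4

    def test_constant_light_warns_and_empty(self):
        with pytest.warns(UserWarning, match="no twilight crossing"):
            tw = geo.detect_twilights(_series([5.0] * 1000), 10.0)
        assert len(tw) == 0

    def test_interpolated_crossing_time(self):
        light = [1.0, 1.0, 7.0, 19.0, 100.0]
        tw = geo.detect_twilights(_series(light), 10.0)
        # linear interpolation between samples 2 (7) and 3 (19): 1/4 of the way
        expect = pd.Timestamp("2018-09-01 00:10:00") + pd.Timedelta(minutes=1.25)
        assert abs((tw["time"].iloc[0] - expect).total_seconds()) < 1


class TestThresholdPositions:
    def test_forward_inverse_stationary(self):
        tw = make_twilight_frame(15.0, 0.0, date(2018, 11, 1), 10, solar.SUNRISE_SUNSET_ZENITH)
        pos = geo.threshold_positions(tw, solar.SUNRISE_SUNSET_ZENITH, lat_hint=0.0)
        assert np.nanmax(np.abs(pos["lon"] - 15.0)) < 1.5
        assert np.nanmax(np.abs(pos["lat"] - 0.0)) < 2.0

    def test_prime_meridian_longitude(self):
        tw = make_twilight_frame(0.0, 40.0, date(2018, 11, 1), 6, solar.SUNRISE_SUNSET_ZENITH)
        pos = geo.threshold_positions(tw, solar.SUNRISE_SUNSET_ZENITH, lat_hint=40.0)
        assert np.nanmax(np.abs(pos["lon"])) < 1.5

    def test_equinox_latitude_flagged(self):
        tw = make_twilight_frame(10.0, 35.0, date(2018, 3, 18), 5, solar.SUNRISE_SUNSET_ZENITH)
        # force an unsolvable day length: 12 h exactly at a deep zenith
        pos = geo.threshold_positions(tw, 98.0, lat_hint=35.0)
        assert pos["lat_indeterminate"].any()

    def test_non_alternating_events_rejected(self):
        tw = make_twilight_frame(10.0, 35.0, date(2018, 11, 1), 3, solar.SUNRISE_SUNSET_ZENITH)
        bad = pd.concat([tw, tw.iloc[[0]]]).sort_values("time").reset_index(drop=True)
        with pytest.raises(ValueError, match="non-alternating"):
            geo.threshold_positions(bad, solar.SUNRISE_SUNSET_ZENITH)


class TestHillEkstrom:
    def test_noiseless_zenith_recovery(self):
        tw = make_twilight_frame(25.0, -20.0, date(2019, 1, 1), 40, 96.0)
        cal = geo.hill_ekstrom_calibrate(tw, lat_hint=-20.0)
        assert cal.zenith_effective_deg == pytest.approx(96.0, abs=0.25)
        assert cal.zenith_deg == pytest.approx(96.0, abs=0.3)

    def test_lognormal_delay_mean_recovered(self):
        rng = np.random.default_rng(23)
        tw = make_twilight_frame(
            25.0, -20.0, date(2019, 1, 1), 80, 96.0,
            delay_fn=lambda: rng.lognormal(np.log(5.0), 0.5),
        )
        cal = geo.hill_ekstrom_calibrate(tw, lat_hint=-20.0)
        truth = 5.0 * np.exp(0.5**2 / 2)
        assert abs(cal.mean_min - truth) / truth < 0.30

    def test_short_window_rejected(self):
        tw = make_twilight_frame(25.0, -20.0, date(2019, 1, 1), 10, 96.0)
        with pytest.raises(ValueError, match="shorter"):
            geo.hill_ekstrom_calibrate(tw)

    def test_calibration_model_invariants(self):
        with pytest.raises(ValueError):
            geo.CalibrationModel(zenith_deg=89.0)
        with pytest.raises(ValueError):
            geo.CalibrationModel(zenith_deg=96.0, shape=-1.0)


class TestCredibleInterval:
    def test_normal_samples_quantile_halfwidth(self):
        rng = np.random.default_rng(2)
        s = rng.normal(0.0, 1.0, size=(100_000, 2))
        ci = geo.credible_interval(s)
        # 1.25% / 98.75% normal quantiles: +/- 2.2414 sigma
        assert ci["lon_hi"] == pytest.approx(2.2414, abs=0.03)
        assert ci["lat_lo"] == pytest.approx(-2.2414, abs=0.03)

    def test_constant_samples_zero_width(self):
        s = np.full((200, 2), 3.5)
        ci = geo.credible_interval(s)
        assert ci["lon_hi"] - ci["lon_lo"] == 0.0

    def test_level_monotonicity(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=(5000, 2))
        wide = geo.credible_interval(s, level=0.975)
        narrow = geo.credible_interval(s, level=0.5)
        assert narrow["lon_hi"] - narrow["lon_lo"] < wide["lon_hi"] - wide["lon_lo"]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="100"):
            geo.credible_interval(np.zeros((50, 2)))


class TestPriors:
    def test_speed_prior_mean(self):
        cal = geo.CalibrationModel(zenith_deg=96.0)
        pr = geo.EstellePriors(deployment=(5.5, 51.1), twilight_error=cal)
        assert pr.prior_mean_speed_kmh == pytest.approx(2.2 / 0.08)
        # sampling the prior reproduces the analytic mean shape/rate
        rng = np.random.default_rng(0)
        draws = rng.gamma(2.2, 1 / 0.08, 200_000)
        assert draws.mean() == pytest.approx(27.5, rel=0.01)

    def test_deployment_on_water_rejected(self):
        cal = geo.CalibrationModel(zenith_deg=96.0)
        sea = Raster(np.zeros((10, 10)), 0.0, 40.0, 1.0)
        with pytest.raises(ValueError, match="water"):
            geo.EstellePriors(deployment=(5.0, 45.0), twilight_error=cal, land_mask=sea)


class TestMcmcRefinement:
    def _stationary_setup(self, rng_seed=1):
        rng = np.random.default_rng(rng_seed)
        lon0, lat0 = 15.0, 45.0
        cal = geo.CalibrationModel(zenith_deg=96.0, shape=0.6, scale_min=3.5)
        tw = make_twilight_frame(
            lon0, lat0, date(2018, 8, 1), 25, 96.0,
            delay_fn=lambda: rng.lognormal(np.log(3.5), 0.6),
        )
        pos = geo.threshold_positions(tw, 96.0, lat_hint=lat0)
        return lon0, lat0, cal, tw, pos

    def test_refinement_tightens_stationary_positions(self):
        lon0, lat0, cal, tw, pos = self._stationary_setup()
        mask = Raster(np.ones((40, 40)), 0.0, 30.0, 1.0)
        priors = geo.EstellePriors(deployment=(lon0, lat0), twilight_error=cal, land_mask=mask)
        sched = geo.McmcSchedule(burn_in=100, tuning_runs=2, tuning_iters=150, final_iters=800)
        ref, samples = geo.refine_positions_mcmc(pos, priors, tw, schedule=sched, rng=5)
        truth = np.c_[[lon0] * len(ref), [lat0] * len(ref)]
        err1 = great_circle_km(np.c_[ref["lon_mean"], ref["lat_mean"]], truth)
        err0 = great_circle_km(
            np.c_[pos["lon"], pos["lat"]], np.c_[[lon0] * len(pos), [lat0] * len(pos)]
        )
        assert np.median(err1) < np.median(err0)
        inbox = (
            (lon0 >= ref["lon_lo"]) & (lon0 <= ref["lon_hi"])
            & (lat0 >= ref["lat_lo"]) & (lat0 <= ref["lat_hi"])
        )
        assert inbox.mean() > 0.85

    def test_stationary_group_respects_land_mask(self):
        lon0, lat0, cal, tw, pos = self._stationary_setup()
        # water everywhere except a land band around the true longitude
        vals = np.zeros((40, 40))
        vals[:, 10:20] = 1.0  # land lons 10..20
        mask = Raster(vals, 0.0, 30.0, 1.0)
        priors = geo.EstellePriors(deployment=(lon0, lat0), twilight_error=cal, land_mask=mask)
        groups = np.zeros(len(tw), dtype=int)  # fully stationary: one location
        groups[0] = 0
        sched = geo.McmcSchedule(burn_in=50, tuning_runs=1, tuning_iters=100, final_iters=400)
        ref, samples = geo.refine_positions_mcmc(
            pos, priors, tw, group_ids=groups, schedule=sched, rng=6
        )
        land = mask.sample(samples[:, :, 0].ravel(), samples[:, :, 1].ravel())
        assert np.all(land >= 0.5)

    def test_mask_violation_at_anchor_reported(self):
        lon0, lat0, cal, tw, pos = self._stationary_setup()
        vals = np.ones((40, 40))
        vals[:, 14:17] = 0.0  # water at the deployment longitude band
        mask = Raster(vals, 0.0, 30.0, 1.0)
        with pytest.raises(ValueError, match="water"):
            geo.EstellePriors(deployment=(lon0, lat0), twilight_error=cal, land_mask=mask)

    def test_day_roost_groups_pair_sunrise_with_sunset(self):
        tw = make_twilight_frame(15.0, 45.0, date(2018, 8, 1), 3, 96.0)
        g = geo.day_roost_groups(tw)
        # events: sr ss sr ss sr ss -> groups 0 0 1 1 2 2
        assert list(g) == [0, 0, 1, 1, 2, 2]

    def test_deterministic_given_rng_seed(self):
        lon0, lat0, cal, tw, pos = self._stationary_setup()
        mask = Raster(np.ones((40, 40)), 0.0, 30.0, 1.0)
        priors = geo.EstellePriors(deployment=(lon0, lat0), twilight_error=cal, land_mask=mask)
        sched = geo.McmcSchedule(burn_in=20, tuning_runs=1, tuning_iters=50, final_iters=200)
        a, _ = geo.refine_positions_mcmc(pos, priors, tw, schedule=sched, rng=9)
        b, _ = geo.refine_positions_mcmc(pos, priors, tw, schedule=sched, rng=9)
        pd.testing.assert_frame_equal(a, b)
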