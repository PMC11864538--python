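"""Climatology, annual detection, solar elevation and the day:night ratio."""

import numpy as np
import pandas as pd
import pytest

from whalesong.call_metrics import PresenceSeries
from whalesong.phenology import (
    AnalysisYear,
    DielBins,
    annual_detection,
    day_night_ratio,
    detection_ratio,
    monthly_climatology,
    whole_period_detection,
)
from whalesong.series import SampleSeries
from whalesong.solar import solar_elevation


def _presence(dates, flags):
    return PresenceSeries(pd.DatetimeIndex(dates), np.asarray(flags, bool), 1.01)


class TestAnalysisYear:
    def test_spans_july_through_june(self):
        y = AnalysisYear(2018)
        assert y.start == pd.Timestamp("2018-07-01")
        assert y.end == pd.Timestamp("2019-06-30")

    def test_years_tile_without_overlap(self):
        a, b = AnalysisYear(2018), AnalysisYear(2019)
        assert b.start - a.end == pd.Timedelta(days=1)


class TestClimatologyAndAnnual:
    def test_all_present_gives_hundred_everywhere(self):
        dates = pd.date_range("2018-07-01", "2020-06-30")
        clim = monthly_climatology(_presence(dates, np.ones(len(dates))))
        assert np.allclose(clim.values, 100.0)

    def test_single_month_presence(self):
        dates = pd.date_range("2018-07-01", "2019-06-30")
        flags = dates.month == 11
        clim = monthly_climatology(_presence(dates, flags))
        assert clim[11] == 100.0
        assert clim.drop(11).sum() == 0.0

    def test_unsampled_month_is_missing(self):
        dates = pd.date_range("2018-01-01", "2018-01-31")
        clim = monthly_climatology(_presence(dates, np.ones(31)))
        assert clim[1] == 100.0
        assert clim.drop(1).isna().all()

    def test_no_presence_gives_zero_annual(self):
        dates = pd.date_range("2018-07-01", "2019-06-30")
        pres = _presence(dates, np.zeros(len(dates)))
        assert annual_detection(pres, AnalysisYear(2018)) == 0.0

    def test_order_invariance(self, rng):
        dates = pd.date_range("2018-07-01", "2019-06-30")
        flags = rng.random(len(dates)) < 0.4
        perm = rng.permutation(len(dates))
        a = annual_detection(_presence(dates, flags), AnalysisYear(2018))
        b = annual_detection(_presence(dates[perm], flags[perm]), AnalysisYear(2018))
        assert a == pytest.approx(b)

    def test_annual_values_conserve_whole_period_detection(self, rng):
        dates = pd.date_range("2018-07-01", "2020-06-30")
        flags = rng.random(len(dates)) < 0.4
        pres = _presence(dates, flags)
        total = 0.0
        weight = 0
        for yr in (2018, 2019):
            y = AnalysisYear(yr)
            n = int(y.mask(pres.dates).sum())
            total += annual_detection(pres, y) * n
            weight += n
        assert total / weight == pytest.approx(whole_period_detection(pres))

    def test_empty_year_rejected(self):
        dates = pd.date_range("2018-07-01", periods=10)
        with pytest.raises(ValueError, match="no retained days"):
            annual_detection(_presence(dates, np.ones(10)), AnalysisYear(2021))

    def test_detection_ratio_arithmetic(self):
        assert detection_ratio(34.0, 76.0) == pytest.approx(76 / 34)
        with pytest.raises(ValueError):
            detection_ratio(0.0, 50.0)


def _psa_elevation(unix, lat, lon):
    """Independent oracle: PSA solar-position algorithm (geometric)."""
    jd = unix / 86400.0 + 2440587.5
    n = jd - 2451545.0
    omega = 2.1429 - 0.0010394594 * n
    mean_lon = 4.8950630 + 0.017202791698 * n
    mean_anom = 6.2400600 + 0.0172019699 * n
    ecl_lon = (mean_lon + 0.03341607 * np.sin(mean_anom)
               + 0.00034894 * np.sin(2 * mean_anom)
               - 0.0001134 - 0.0000203 * np.sin(omega))
    ep = 0.4090928 - 6.2140e-9 * n + 0.0000396 * np.cos(omega)
    ra = np.arctan2(np.cos(ep) * np.sin(ecl_lon), np.cos(ecl_lon)) % (2 * np.pi)
    dec = np.arcsin(np.sin(ep) * np.sin(ecl_lon))
    gmst = 6.6974243242 + 0.0657098283 * n + (unix % 86400) / 3600.0
    lmst = (gmst * 15 + lon) * np.pi / 180
    ha = lmst - ra
    latr = np.deg2rad(lat)
    zen = np.arccos(np.cos(latr) * np.cos(ha) * np.cos(dec)
                    + np.sin(dec) * np.sin(latr))
    zen += 6371.01 / 149597890 * np.sin(zen)  # parallax
    return 90 - np.rad2deg(zen)


class TestSolarElevation:
    def test_equator_equinox_noon_near_zenith(self):
        se = solar_elevation(np.datetime64("2021-03-20T12:07:00"), 0.0, 0.0)
        assert se > 89.0

    def test_midlatitude_solar_midnight_is_deep_night(self):
        # local solar midnight at 122 W is ~08:09 UTC
        se = solar_elevation(np.datetime64("2021-06-21T08:09:00"),
                             36.713, -122.186)
        assert se < -12.0

    def test_agrees_with_independent_psa_algorithm(self):
        rng = np.random.default_rng(0)
        lo = pd.Timestamp("2016-01-01").timestamp()
        hi = pd.Timestamp("2023-01-01").timestamp()
        unix = rng.uniform(lo, hi, 10)
        ours = solar_elevation(unix, 36.713, -122.186)
        oracle = _psa_elevation(unix, 36.713, -122.186)
        assert np.max(np.abs(ours - oracle)) <= 0.5

    def test_invalid_coordinates_rejected(self):
        with pytest.raises(ValueError, match="coordinates"):
            solar_elevation(np.datetime64("2021-01-01T00:00:00"), 100.0, 0.0)


def _stream_over(days, values):
    return SampleSeries(np.datetime64(f"{days[0]}T00:00:00"), 60.0, values)


class TestDayNightRatio:
    def _uniform_positives(self, rate, seed, days=60):
        rng = np.random.default_rng(seed)
        n = days * 1440  # one sample per minute
        stream = SampleSeries(np.datetime64("2021-01-01T00:00:00"), 60.0,
                              np.zeros(n, dtype=np.float32))
        return stream, rng.random(n) < rate

    def test_uniform_singing_gives_unit_ratio(self):
        stream, positive = self._uniform_positives(0.3, 1)
        ratio = day_night_ratio(stream, positive)
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_day_only_positives_give_zero_when_night_active(self):
        stream, _ = self._uniform_positives(0.0, 0)
        se = solar_elevation(stream.unix_seconds())
        cls = DielBins().classify(se)
        positive = cls != 0  # everything positive except twilight
        # coarse solar grid may re-bin a handful of twilight-edge samples
        assert day_night_ratio(stream, positive) == pytest.approx(1.0, abs=0.01)
        only_night = cls == -1
        assert day_night_ratio(stream, only_night) == 0.0

    def test_no_night_positives_is_undefined_not_infinite(self):
        stream, _ = self._uniform_positives(0.0, 0)
        se = solar_elevation(stream.unix_seconds())
        only_day = DielBins().classify(se) == 1
        assert np.isnan(day_night_ratio(stream, only_day))

    def test_thinning_invariance(self):
        stream, positive = self._uniform_positives(0.3, 2, days=120)
        full = day_night_ratio(stream, positive)
        thinned = day_night_ratio(stream.thin(3), positive[::3])
        assert thinned == pytest.approx(full, abs=0.1)

    def test_year_restriction_drops_outside_samples(self):
        stream, positive = self._uniform_positives(0.3, 3, days=400)
        r = day_night_ratio(stream, positive, year=AnalysisYear(2020))
        assert np.isfinite(r)
        with pytest.raises(ValueError, match="no samples"):
            day_night_ratio(stream, positive, year=AnalysisYear(2030))
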