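"""Ground-truth bookkeeping and statistical structure of the generators."""

import numpy as np
import pandas as pd
import pytest

from whalesong.call_metrics import BLUE_BAND
from whalesong.synthetic import (
    IsotopeScenario,
    NoiseModel,
    PopulationScenario,
    SongScenario,
    generate_beuti,
    generate_isotopes,
    generate_photo_id,
    generate_score_series,
    generate_spectral_frames,
    simulate_ci_experiment,
)


class TestSpectralFrames:
    def test_reproducible_for_fixed_seed(self, always_singing, quiet_noise, week):
        f1, t1 = generate_spectral_frames(always_singing, quiet_noise,
                                          BLUE_BAND, week, 7,
                                          freqs=np.arange(38, 48))
        f2, t2 = generate_spectral_frames(always_singing, quiet_noise,
                                          BLUE_BAND, week, 7,
                                          freqs=np.arange(38, 48))
        assert np.array_equal(f1.psd, f2.psd)
        assert np.array_equal(t1.sample_song, t2.sample_song)

    def test_daily_presence_iff_any_song_frame(self, quiet_noise, week):
        scenario = SongScenario(season_start_doy=1, season_end_doy=366,
                                daily_presence_prob=0.5)
        _, truth = generate_spectral_frames(scenario, quiet_noise, BLUE_BAND,
                                            week, 3, freqs=np.arange(38, 48))
        per_day = truth.sample_song.reshape(len(week), -1)
        assert np.array_equal(truth.daily_presence.values, per_day.any(axis=1))

    def test_presence_every_day_when_certain(self, always_singing, quiet_noise,
                                             week):
        _, truth = generate_spectral_frames(always_singing, quiet_noise,
                                            BLUE_BAND, week, 1,
                                            freqs=np.arange(38, 48))
        assert truth.daily_presence.all()

    def test_injected_elevation_matches_configuration(self, always_singing,
                                                      quiet_noise, week):
        frames, truth = generate_spectral_frames(
            always_singing, quiet_noise, BLUE_BAND, week, 11,
            freqs=np.arange(38, 48))
        song = truth.sample_song
        peak = frames.band_columns(BLUE_BAND.peak_bins).astype(float)
        back = frames.band_columns(BLUE_BAND.background_bins).astype(float)
        elevation = peak.mean(axis=1) - back.mean(axis=1)
        # mean peak-minus-background difference on song vs silent frames
        realized = elevation[song].mean() - elevation[~song].mean()
        mc_err = 3 * 0.5 / np.sqrt(min(song.sum(), (~song).sum()))
        assert realized == pytest.approx(always_singing.call_energy_db,
                                         abs=4 * mc_err + 0.05)

    def test_zero_energy_injection_leaves_spectra_pure_noise(self, quiet_noise,
                                                             week):
        silent = SongScenario(season_start_doy=1, season_end_doy=366,
                              call_energy_db=0.0)
        frames, truth = generate_spectral_frames(silent, quiet_noise,
                                                 BLUE_BAND, week, 5,
                                                 freqs=np.arange(38, 48))
        assert truth.sample_song.any()  # flags still recorded
        peak = frames.band_columns(BLUE_BAND.peak_bins).astype(float).mean(axis=1)
        song = truth.sample_song
        diff = peak[song].mean() - peak[~song].mean()
        assert abs(diff) < 4 * 0.5 / np.sqrt(min(song.sum(), (~song).sum()))

    def test_background_bins_unaffected_by_injection(self, quiet_noise, week):
        base = dict(season_start_doy=1, season_end_doy=366)
        loud = SongScenario(call_energy_db=12.0, **base)
        f_loud, _ = generate_spectral_frames(loud, quiet_noise, BLUE_BAND,
                                             week, 21, freqs=np.arange(38, 48))
        back = f_loud.band_columns(BLUE_BAND.background_bins).astype(float)
        assert back.mean() == pytest.approx(95.0, abs=0.05)

    def test_streaming_simulation_matches_direct_generation(
            self, always_singing, quiet_noise, week):
        frames, t_direct = generate_spectral_frames(
            always_singing, quiet_noise, BLUE_BAND, week, 9,
            freqs=np.arange(38, 48))
        from whalesong.call_metrics import call_index_frames
        from whalesong.spectra import frames_to_daily

        daily, stream, t_stream = simulate_ci_experiment(
            always_singing, quiet_noise, BLUE_BAND, week, 9,
            freqs=np.arange(38, 48))
        assert np.array_equal(t_direct.sample_song, t_stream.sample_song)
        assert np.allclose(frames_to_daily(frames).mean_psd, daily.mean_psd)
        assert np.allclose(call_index_frames(frames, BLUE_BAND).values,
                           stream.values)


class TestScoreSeries:
    def test_no_song_no_confusers_has_zero_fractions(self, week):
        silent = SongScenario(season_start_doy=100, season_end_doy=110)
        stream, truth = generate_score_series(silent, 0.0, week, 3)
        assert not (stream.values > 0.7).any()
        assert truth.daily_song_seconds.sum() == 0

    def test_confusers_stay_below_threshold(self, week):
        silent = SongScenario(season_start_doy=100, season_end_doy=110)
        stream, _ = generate_score_series(silent, 50.0, week, 4)
        assert (stream.values >= 0.3).sum() > 0
        assert not (stream.values > 0.7).any()

    def test_certain_exceedance_recovers_daily_fraction(self):
        days = pd.date_range("2021-06-21", periods=1)
        scenario = SongScenario(season_start_doy=1, season_end_doy=366,
                                day_song_fraction=0.1, bout_length_s=600)
        stream, truth = generate_score_series(scenario, 0.0, days, 8,
                                              score_exceed_prob=1.0)
        from whalesong.call_metrics import daily_song_fraction

        frac = daily_song_fraction(stream.values)
        realized = 100 * truth.daily_song_seconds.iloc[0] / 86400
        assert frac == pytest.approx(realized)
        assert frac == pytest.approx(10.0, abs=100 * 2 * 600 / 86400)

    def test_negative_confuser_rate_rejected(self, week):
        with pytest.raises(ValueError, match="confuser_rate"):
            generate_score_series(SongScenario(), -1.0, week, 0)


class TestPhotoId:
    def test_zero_detection_probability_yields_no_records(self):
        pop = PopulationScenario(detect_prob=0.0)
        records, _ = generate_photo_id(pop, [2021], 0)
        assert records.empty

    def test_perfect_survey_of_one_resident_gives_uid_one_daily(self):
        pop = PopulationScenario(n_individuals=1, resident_fraction=1.0,
                                 effort_prob_by_month=(1.0,) * 12,
                                 detect_prob=1.0)
        records, _ = generate_photo_id(pop, [2021], 0)
        from whalesong.photo_id import uid_per_day

        uid = uid_per_day(records)
        assert len(uid) == 365
        assert (uid == 1).all()

    def test_median_arrival_recovers_scenario_mean(self):
        pop = PopulationScenario(n_individuals=50, arrival_mean_doy=105,
                                 arrival_sd_days=6, resident_fraction=0.0)
        meds = []
        for rep in range(20):
            _, truth = generate_photo_id(pop, [2021], 300 + rep)
            meds.append(truth.arrivals["arrival_doy"].median())
        # sampling-distribution check: median of n=50 draws stays within
        # a few days of the configured mean
        assert np.median(meds) == pytest.approx(105, abs=3)
        assert all(abs(m - 105) < 6 for m in meds)

    def test_truth_records_one_row_per_individual_per_year(self):
        pop = PopulationScenario(n_individuals=10)
        _, truth = generate_photo_id(pop, [2020, 2021], 1)
        assert len(truth.arrivals) == 20


class TestIsotopes:
    def test_zero_covariance_collapses_to_group_mean(self):
        sc = IsotopeScenario(14.0, -17.0, np.zeros((2, 2)), 5)
        samples = generate_isotopes({("humpback", 2017): sc}, 0)
        assert np.allclose(samples["d15n"], 14.0)
        assert np.allclose(samples["d13c"], -17.0)

    def test_large_sample_means_match_scenario(self):
        sc = IsotopeScenario(14.0, -17.0, [[0.5, 0.1], [0.1, 0.4]], 10_000)
        samples = generate_isotopes({("blue", 2019): sc}, 1)
        se_n = np.sqrt(0.4 / 10_000)
        se_c = np.sqrt(0.5 / 10_000)
        assert samples["d15n"].mean() == pytest.approx(14.0, abs=3 * se_n)
        assert samples["d13c"].mean() == pytest.approx(-17.0, abs=3 * se_c)

    def test_non_psd_covariance_rejected(self):
        with pytest.raises(ValueError, match="positive semi-definite"):
            IsotopeScenario(14.0, -17.0, [[1.0, 2.0], [2.0, 1.0]], 5)

    def test_disjoint_groups_have_zero_ellipse_overlap(self):
        near = IsotopeScenario(10.0, -20.0, 0.01 * np.eye(2), 50)
        far = IsotopeScenario(20.0, -10.0, 0.01 * np.eye(2), 50)
        samples = generate_isotopes({("a", 1): near, ("b", 1): far}, 2)
        from whalesong.isotopes import ellipse_overlap, p_ellipse, standard_ellipse

        ellipses = []
        for _, grp in samples.groupby("species"):
            se = standard_ellipse(grp["d13c"], grp["d15n"])
            ellipses.append(p_ellipse(se.center, se.cov, 0.95))
        assert ellipse_overlap(*ellipses) == 0.0


class TestBeuti:
    def test_reproducible_and_daily(self):
        days = pd.date_range("2021-01-01", periods=365)
        a = generate_beuti(days, 7)
        b = generate_beuti(days, 7)
        assert a.equals(b)
        assert (a.index == days).all()
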