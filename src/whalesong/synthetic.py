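"""Synthetic pipeline inputs with known ground truth.

Every input the analysis consumes can be generated here with the statistical
structure the methods assume, so that each stage of the pipeline can be
validated against truth: PSD frames with call energy injected into the
analysis band during scheduled song bouts; a 1-second classifier-score
stream with a high-score song regime and moderate-score confuser events;
photo-identification records from a population with per-individual arrival
and departure dates under imperfect survey effort and detection; and
bivariate-normal isotope samples per (species, year) group.

All randomness flows from a single seeded numpy Generator passed explicitly;
identical seed and configuration reproduce identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .call_metrics import CallBand, call_index_frames
from .phenology import DielBins
from .series import SampleSeries
from .solar import MARS_LAT, MARS_LON, solar_elevation
from .spectra import DailySpectra, FrameSet, frames_to_daily

__all__ = [
    "SongScenario",
    "NoiseModel",
    "PopulationScenario",
    "IsotopeScenario",
    "SyntheticTruth",
    "generate_spectral_frames",
    "simulate_ci_experiment",
    "generate_score_series",
    "generate_photo_id",
    "generate_isotopes",
]

SECONDS_PER_DAY = 86400


@dataclass
class SongScenario:
    """Seasonal and diel structure of one species' singing.

    ``night_sing_fraction`` (rho) is the nocturnal preference on a
    per-unit-time basis: the share of singing that would occur in the night
    solar-elevation bin if the day and night bins had equal duration.  Bout
    allocation weights rho by the actual bin durations so that the singing
    *rate* ratio night:day is rho:(1-rho) at any latitude and season.
    ``day_song_fraction`` is the singing duty cycle on a song day.
    """

    species: str = "blue"
    season_start_doy: int = 182
    season_end_doy: int = 60
    daily_presence_prob: float = 1.0
    night_sing_fraction: float = 0.5
    call_energy_db: float = 6.0
    bout_length_s: float = 600.0
    day_song_fraction: float = 0.5

    def __post_init__(self) -> None:
        for p in (self.daily_presence_prob, self.night_sing_fraction,
                  self.day_song_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities/fractions must lie in [0, 1]")
        if self.call_energy_db < 0:
            raise ValueError("call_energy_db must be >= 0")
        for d in (self.season_start_doy, self.season_end_doy):
            if not 1 <= d <= 366:
                raise ValueError("season days must lie in [1, 366]")
        if self.bout_length_s <= 0:
            raise ValueError("bout_length_s must be positive")

    def in_season(self, doy: np.ndarray) -> np.ndarray:
        """Season membership, handling wrap across the year boundary."""
        doy = np.asarray(doy)
        if self.season_start_doy <= self.season_end_doy:
            return (doy >= self.season_start_doy) & (doy <= self.season_end_doy)
        return (doy >= self.season_start_doy) | (doy <= self.season_end_doy)


@dataclass
class NoiseModel:
    """Background PSD model: base spectrum + AR(1) day offset + frame jitter.

    ``base_psd_db`` maps frequency (Hz) to the long-term mean spectrum level
    (a scalar means a flat spectrum).  The day-level offset, common to all
    bins within a day, follows a stationary AR(1) with the given lag-1
    coefficient and marginal SD; per-frame, per-bin Gaussian jitter is
    independent.
    """

    base_psd_db: object = 95.0  # scalar or callable f(Hz)->dB
    daily_ar1_coeff: float = 0.6
    daily_sd_db: float = 1.5
    frame_sd_db: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.daily_ar1_coeff < 1.0:
            raise ValueError("daily_ar1_coeff must lie in [0, 1)")
        if self.daily_sd_db < 0 or self.frame_sd_db < 0:
            raise ValueError("noise SDs must be >= 0")

    def base(self, freqs: np.ndarray) -> np.ndarray:
        if callable(self.base_psd_db):
            out = np.asarray([float(self.base_psd_db(f)) for f in freqs])
        else:
            out = np.full(len(freqs), float(self.base_psd_db))
        if not np.all(np.isfinite(out)):
            raise ValueError("base PSD must be finite on the frequency grid")
        return out

    def day_offsets(self, n_days: int, rng: np.random.Generator) -> np.ndarray:
        """Stationary AR(1) day-level dB offsets."""
        a, sd = self.daily_ar1_coeff, self.daily_sd_db
        out = np.empty(n_days)
        x = rng.normal(0.0, sd) if sd > 0 else 0.0
        innov_sd = sd * np.sqrt(1.0 - a * a)
        for i in range(n_days):
            out[i] = x
            x = a * x + (rng.normal(0.0, innov_sd) if sd > 0 else 0.0)
        return out


@dataclass
class PopulationScenario:
    """Per-year phenology and observation process of a photo-ID'd population.

    A small ``resident_fraction`` of individuals remains in the study area
    year-round (overwintering animals are a documented feature of coastal
    humpback aggregations); they supply the low-UID winter sighting days
    that anchor the lower third of the daily UID distribution, which is
    what the 33rd-percentile migration-timing threshold separates.
    """

    n_individuals: int = 50
    arrival_mean_doy: float = 105.0
    arrival_sd_days: float = 6.0
    departure_mean_doy: float = 320.0
    departure_sd_days: float = 10.0
    effort_prob_by_month: tuple = (0.6,) * 12
    detect_prob: float = 0.5
    resident_fraction: float = 0.08

    def __post_init__(self) -> None:
        if len(self.effort_prob_by_month) != 12:
            raise ValueError("effort_prob_by_month needs 12 entries")
        probs = (*self.effort_prob_by_month, self.detect_prob,
                 self.resident_fraction)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        # modulo year wrap: arrival before departure within one cycle
        span = (self.departure_mean_doy - self.arrival_mean_doy) % 365
        if span == 0:
            raise ValueError("departure must follow arrival (modulo year wrap)")


@dataclass
class IsotopeScenario:
    """Bivariate-normal (d13C, d15N) structure of one (species, year) group."""

    mean_d15n: float
    mean_d13c: float
    cov: np.ndarray
    n_samples: int = 5

    def __post_init__(self) -> None:
        self.cov = np.asarray(self.cov, dtype=float)
        if self.cov.shape != (2, 2):
            raise ValueError("cov must be 2x2")
        if not np.allclose(self.cov, self.cov.T):
            raise ValueError("cov must be symmetric")
        if np.any(np.linalg.eigvalsh(self.cov) < -1e-12):
            raise ValueError("cov must be positive semi-definite")
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")


@dataclass
class SyntheticTruth:
    """Generator bookkeeping for downstream validation."""

    sample_song: np.ndarray | None = None  # per-frame/second song flags
    daily_presence: pd.Series | None = None  # >=1 song-flagged sample that day
    daily_song_seconds: pd.Series | None = None
    night_sing_fraction: float | None = None
    injected_db: float | None = None
    arrivals: pd.DataFrame | None = None  # individual, year, arrival/departure doy


# ---------------------------------------------------------------------------
# bout scheduling


def _schedule_day_flags(
    n_samples: int,
    step_s: float,
    day_start: np.datetime64,
    scenario: SongScenario,
    rng: np.random.Generator,
    lat: float,
    lon: float,
    bins: DielBins,
    solar_resolution_s: float = 60.0,
) -> np.ndarray:
    """Boolean song flags for one day's samples, placed in diel bins.

    Singing time is split between the day and night solar-elevation bins in
    proportion rho*T_night : (1-rho)*T_day normalized (so the singing rate
    ratio is rho:(1-rho)); bouts occupy non-overlapping blocks of
    ``bout_length`` samples chosen uniformly within each bin.
    """
    flags = np.zeros(n_samples, dtype=bool)
    target = int(round(scenario.day_song_fraction * n_samples))
    if target == 0:
        return flags
    t0 = day_start.astype("datetime64[s]").astype("int64")
    unix = t0 + step_s * np.arange(n_samples)
    blocks = np.floor(unix / solar_resolution_s).astype("int64")
    uniq, inverse = np.unique(blocks, return_inverse=True)
    se = solar_elevation((uniq + 0.5) * solar_resolution_s, lat, lon)[inverse]
    cls = bins.classify(se)

    rho = scenario.night_sing_fraction
    t_day = int(np.sum(cls == 1))
    t_night = int(np.sum(cls == -1))
    w_night = rho * t_night
    w_day = (1.0 - rho) * t_day
    if w_night + w_day == 0:
        return flags
    night_target = int(round(target * w_night / (w_night + w_day)))
    day_target = target - night_target

    k = max(1, int(round(scenario.bout_length_s / step_s)))
    for bin_code, bin_target in ((1, day_target), (-1, night_target)):
        idx = np.flatnonzero(cls == bin_code)
        if idx.size == 0 or bin_target == 0:
            continue
        n_blocks = idx.size // k
        if n_blocks == 0:
            flags[idx[: min(bin_target, idx.size)]] = True
            continue
        want = min(n_blocks, max(1, int(round(bin_target / k))))
        chosen = rng.choice(n_blocks, size=want, replace=False)
        for c in chosen:
            flags[idx[c * k:(c + 1) * k]] = True
    return flags


# ---------------------------------------------------------------------------
# spectral frames


def _day_frame_block(
    day: np.datetime64,
    freqs: np.ndarray,
    base: np.ndarray,
    day_offset: float,
    song_flags: np.ndarray,
    scenario: SongScenario,
    band: CallBand,
    noise: NoiseModel,
    rng: np.random.Generator,
    frame_seconds: float,
) -> np.ndarray:
    n = song_flags.size
    psd = rng.standard_normal((n, freqs.size), dtype=np.float32)
    psd *= np.float32(noise.frame_sd_db)
    psd += (base + day_offset).astype(np.float32)
    if scenario.call_energy_db > 0 and song_flags.any():
        peak_idx = np.searchsorted(freqs, sorted(band.peak_bins))
        psd[np.ix_(song_flags, peak_idx)] += np.float32(scenario.call_energy_db)
    return psd


def _daily_song_schedule(dates: pd.DatetimeIndex, scenario: SongScenario,
                         rng: np.random.Generator) -> np.ndarray:
    doy = dates.dayofyear.to_numpy()
    in_season = scenario.in_season(doy)
    draws = rng.random(len(dates)) < scenario.daily_presence_prob
    return in_season & draws


def generate_spectral_frames(
    scenario: SongScenario,
    noise: NoiseModel,
    band: CallBand,
    dates,
    seed: int | np.random.Generator,
    freqs: np.ndarray | None = None,
    frame_seconds: float = 5.0,
    lat: float = MARS_LAT,
    lon: float = MARS_LON,
    bins: DielBins = DielBins(),
) -> tuple[FrameSet, SyntheticTruth]:
    """PSD frames over whole days, with call energy injected during bouts.

    ``dates`` is a sequence of calendar days (each contributes a full day of
    frames at the 5-s cadence).  Peak-band bins of song-flagged frames are
    elevated by ``call_energy_db`` above the realized background; background
    bins are untouched by injection.

    Holds all frames in memory: intended for spans up to a few months.  For
    year-scale experiments use :func:`simulate_ci_experiment`, which reduces
    each day's frames on the fly with the identical random stream.
    """
    rng = np.random.default_rng(seed)
    dates = pd.DatetimeIndex(dates).normalize()
    if len(dates) == 0:
        raise ValueError("date_range must be non-empty")
    if freqs is None:
        freqs = np.arange(10, 101)
    freqs = np.asarray(freqs, dtype=int)
    missing = [b for b in band.all_bins if b not in set(freqs.tolist())]
    if missing:
        raise ValueError(f"band bins {missing} outside the frequency grid")

    per_day = int(round(SECONDS_PER_DAY / frame_seconds))
    base = noise.base(freqs)
    offsets = noise.day_offsets(len(dates), rng)
    song_days = _daily_song_schedule(dates, scenario, rng)

    all_psd, all_times, all_flags = [], [], []
    for i, day in enumerate(dates):
        d64 = np.datetime64(day, "s")
        flags = (
            _schedule_day_flags(per_day, frame_seconds, d64, scenario, rng,
                                lat, lon, bins)
            if song_days[i] else np.zeros(per_day, dtype=bool)
        )
        psd = _day_frame_block(d64, freqs, base, offsets[i], flags, scenario,
                               band, noise, rng, frame_seconds)
        all_psd.append(psd)
        all_flags.append(flags)
        all_times.append(d64 + (frame_seconds * np.arange(per_day)).astype("timedelta64[s]"))

    flags = np.concatenate(all_flags)
    frames = FrameSet(np.concatenate(all_times), freqs, np.vstack(all_psd),
                      frame_seconds)
    truth = _song_truth(dates, flags, per_day, frame_seconds, scenario)
    return frames, truth


def _song_truth(dates, flags, per_day, step_s, scenario) -> SyntheticTruth:
    by_day = flags.reshape(len(dates), per_day)
    return SyntheticTruth(
        sample_song=flags,
        daily_presence=pd.Series(by_day.any(axis=1), index=dates),
        daily_song_seconds=pd.Series(by_day.sum(axis=1) * step_s, index=dates),
        night_sing_fraction=scenario.night_sing_fraction,
        injected_db=scenario.call_energy_db,
    )


def simulate_ci_experiment(
    scenario: SongScenario,
    noise: NoiseModel,
    band: CallBand,
    dates,
    seed: int | np.random.Generator,
    freqs: np.ndarray | None = None,
    frame_seconds: float = 5.0,
    lat: float = MARS_LAT,
    lon: float = MARS_LON,
    bins: DielBins = DielBins(),
    domain: str = "linear",
) -> tuple[DailySpectra, SampleSeries, SyntheticTruth]:
    """Year-scale streaming simulation: daily mean spectra + per-frame CI.

    Generates each day's frames with the same random stream as
    :func:`generate_spectral_frames`, reduces them immediately to the daily
    mean spectrum and the per-frame CI, and discards the frames, keeping
    memory flat over arbitrarily long periods.
    """
    rng = np.random.default_rng(seed)
    dates = pd.DatetimeIndex(dates).normalize()
    if len(dates) == 0:
        raise ValueError("date_range must be non-empty")
    if freqs is None:
        freqs = np.arange(10, 101)
    freqs = np.asarray(freqs, dtype=int)

    per_day = int(round(SECONDS_PER_DAY / frame_seconds))
    base = noise.base(freqs)
    offsets = noise.day_offsets(len(dates), rng)
    song_days = _daily_song_schedule(dates, scenario, rng)

    mean_psd = np.empty((len(dates), freqs.size))
    ci_stream = np.empty(len(dates) * per_day)
    flags_all = np.zeros(len(dates) * per_day, dtype=bool)
    for i, day in enumerate(dates):
        d64 = np.datetime64(day, "s")
        flags = (
            _schedule_day_flags(per_day, frame_seconds, d64, scenario, rng,
                                lat, lon, bins)
            if song_days[i] else np.zeros(per_day, dtype=bool)
        )
        psd = _day_frame_block(d64, freqs, base, offsets[i], flags, scenario,
                               band, noise, rng, frame_seconds)
        fs = FrameSet(
            d64 + (frame_seconds * np.arange(per_day)).astype("timedelta64[s]"),
            freqs, psd, frame_seconds,
        )
        mean_psd[i] = frames_to_daily(fs, domain=domain).mean_psd[0]
        ci_stream[i * per_day:(i + 1) * per_day] = call_index_frames(fs, band).values
        flags_all[i * per_day:(i + 1) * per_day] = flags

    if not (np.diff(dates.values.astype("datetime64[D]")).astype(int) == 1).all():
        raise ValueError("streaming simulation requires contiguous dates")
    daily = DailySpectra(dates, freqs, mean_psd, np.ones(len(dates)))
    stream = SampleSeries(np.datetime64(dates[0], "s"), frame_seconds, ci_stream)
    truth = _song_truth(dates, flags_all, per_day, frame_seconds, scenario)
    return daily, stream, truth


# ---------------------------------------------------------------------------
# classifier-score stream


def generate_score_series(
    scenario: SongScenario,
    confuser_rate: float,
    dates,
    seed: int | np.random.Generator,
    score_exceed_prob: float = 0.9,
    confuser_length_s: float = 300.0,
    lat: float = MARS_LAT,
    lon: float = MARS_LON,
    bins: DielBins = DielBins(),
) -> tuple[SampleSeries, SyntheticTruth]:
    """1-second classifier-score stream with song, background and confusers.

    Song seconds draw from a high-score regime — above 0.7 with probability
    ``score_exceed_prob``, otherwise in [0.4, 0.7) — background seconds from
    a low regime (Beta(1.5, 25), essentially always < 0.3), and confuser
    events (other biological sources) arrive at ``confuser_rate`` per day
    with scores uniform in [0.3, 0.6], below the 0.7 threshold by
    construction.
    """
    if confuser_rate < 0:
        raise ValueError("confuser_rate must be >= 0")
    if not 0.0 <= score_exceed_prob <= 1.0:
        raise ValueError("score_exceed_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    dates = pd.DatetimeIndex(dates).normalize()
    if len(dates) == 0:
        raise ValueError("date_range must be non-empty")

    n_total = len(dates) * SECONDS_PER_DAY
    scores = rng.beta(1.5, 25.0, size=n_total).astype(np.float32)
    song_days = _daily_song_schedule(dates, scenario, rng)
    flags_all = np.zeros(n_total, dtype=bool)

    for i, day in enumerate(dates):
        lo = i * SECONDS_PER_DAY
        d64 = np.datetime64(day, "s")
        # confuser events: moderately elevated scores, never above threshold
        n_conf = rng.poisson(confuser_rate)
        for _ in range(n_conf):
            start = rng.integers(0, SECONDS_PER_DAY)
            length = max(1, int(rng.exponential(confuser_length_s)))
            stop = min(SECONDS_PER_DAY, start + length)
            seg = slice(lo + start, lo + stop)
            scores[seg] = rng.uniform(0.3, 0.6, size=stop - start)
        if song_days[i]:
            flags = _schedule_day_flags(SECONDS_PER_DAY, 1.0, d64, scenario,
                                        rng, lat, lon, bins)
            idx = np.flatnonzero(flags)
            high = rng.random(idx.size) < score_exceed_prob
            vals = np.where(high,
                            rng.uniform(0.7, 1.0, size=idx.size),
                            rng.uniform(0.4, 0.7, size=idx.size))
            scores[lo + idx] = vals.astype(np.float32)
            flags_all[lo + idx] = True

    # guard against float32 round-up past the closed unit interval
    np.clip(scores, 0.0, 1.0, out=scores)
    stream = SampleSeries(np.datetime64(dates[0], "s"), 1.0, scores)
    truth = _song_truth(dates, flags_all, SECONDS_PER_DAY, 1.0, scenario)
    return stream, truth


# ---------------------------------------------------------------------------
# photo identification


def generate_photo_id(
    pop: PopulationScenario,
    years,
    seed: int | np.random.Generator,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Identification records over calendar years, with arrival/departure truth.

    Each individual is present between its sampled arrival and departure
    day-of-year; records are emitted only on surveyed days (monthly effort
    probability) for individuals passing the per-day detection draw.
    """
    rng = np.random.default_rng(seed)
    years = list(years)
    if not years:
        raise ValueError("years must be non-empty")

    rows, truth_rows = [], []
    for year in years:
        days = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        doy = days.dayofyear.to_numpy()
        arr = rng.normal(pop.arrival_mean_doy, pop.arrival_sd_days,
                         size=pop.n_individuals)
        dep = rng.normal(pop.departure_mean_doy, pop.departure_sd_days,
                         size=pop.n_individuals)
        n_res = int(round(pop.resident_fraction * pop.n_individuals))
        if n_res > 0:  # residents (last indices) are present year-round
            arr[pop.n_individuals - n_res:] = 1.0
            dep[pop.n_individuals - n_res:] = 366.0
        effort_p = np.asarray(pop.effort_prob_by_month)[days.month - 1]
        surveyed = rng.random(len(days)) < effort_p
        # presence matrix individuals x days, with modulo-year wrap
        wrap = dep < arr
        present = (doy[None, :] >= arr[:, None]) & (doy[None, :] <= dep[:, None])
        if wrap.any():
            w = wrap[:, None]
            present = np.where(
                w, (doy[None, :] >= arr[:, None]) | (doy[None, :] <= dep[:, None]),
                present,
            )
        detected = present & (rng.random(present.shape) < pop.detect_prob)
        detected &= surveyed[None, :]
        ind_idx, day_idx = np.nonzero(detected)
        for ii, dd in zip(ind_idx, day_idx):
            rows.append((f"ind{ii:04d}", days[dd]))
        for ii in range(pop.n_individuals):
            truth_rows.append((f"ind{ii:04d}", year, arr[ii], dep[ii]))

    records = pd.DataFrame(rows, columns=["individual_id", "date"])
    truth = SyntheticTruth(
        arrivals=pd.DataFrame(
            truth_rows,
            columns=["individual_id", "year", "arrival_doy", "departure_doy"],
        )
    )
    return records, truth


# ---------------------------------------------------------------------------
# upwelling index


def generate_beuti(
    dates,
    seed: int | np.random.Generator,
    mean: float = 0.5,
    seasonal_amplitude: float = 1.5,
    peak_doy: int = 135,
    noise_sd: float = 0.6,
    ar1: float = 0.8,
) -> pd.Series:
    """Synthetic daily BEUTI (kmol m^-1 d^-1): seasonal cycle + AR(1) noise.

    Upwelling peaks in late spring (``peak_doy``) and turns negative
    (downwelling) in winter when the seasonal cycle dips below zero.
    """
    rng = np.random.default_rng(seed)
    dates = pd.DatetimeIndex(dates).normalize()
    doy = dates.dayofyear.to_numpy()
    seasonal = mean + seasonal_amplitude * np.cos(2 * np.pi * (doy - peak_doy) / 365.25)
    noise = np.empty(len(dates))
    x = rng.normal(0.0, noise_sd)
    innov = noise_sd * np.sqrt(1 - ar1 * ar1)
    for i in range(len(dates)):
        noise[i] = x
        x = ar1 * x + rng.normal(0.0, innov)
    return pd.Series(seasonal + noise, index=dates, name="beuti")


# ---------------------------------------------------------------------------
# isotopes


def generate_isotopes(
    scenarios: dict,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Bivariate-normal samples per (species, year) group.

    ``scenarios`` maps (species, year) -> IsotopeScenario.  Sample order
    follows sorted group keys for reproducibility.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for (species, year) in sorted(scenarios, key=lambda k: (str(k[0]), str(k[1]))):
        sc = scenarios[(species, year)]
        mean = np.array([sc.mean_d13c, sc.mean_d15n])
        draws = rng.multivariate_normal(mean, sc.cov, size=sc.n_samples,
                                        method="cholesky" if _is_pd(sc.cov) else "svd")
        for d13c, d15n in draws:
            rows.append((species, year, d13c, d15n))
    return pd.DataFrame(rows, columns=["species", "year", "d13c", "d15n"])


def _is_pd(cov: np.ndarray) -> bool:
    return bool(np.all(np.linalg.eigvalsh(cov) > 1e-12))
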