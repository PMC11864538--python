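"""Call index, daily song fraction, smoothing and presence thresholds.

The call index (CI) for blue and fin whale song is the ratio of the peak
spectrum level (dB) within the call's frequency band to the mean spectrum
level (dB) in the adjacent background bands; CI = 1.0 means no call energy,
and daily maxima reach roughly 1.2.  Humpback song is quantified instead as
the percent of recording time with a classifier score above 0.7.  Daily
series of either metric are smoothed with a centered 5-day running mean
before a presence threshold (CI >= 1.01, or fraction >= 3 %) is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series import SampleSeries
from .spectra import DailySpectra, FrameSet

__all__ = [
    "CallBand",
    "FIN_BAND",
    "BLUE_BAND",
    "PresenceSeries",
    "call_index",
    "call_index_daily",
    "call_index_frames",
    "daily_song_fraction",
    "song_fraction_series",
    "smooth_5day",
    "presence",
    "detection_performance",
    "CI_PRESENCE_THRESHOLD",
    "SCORE_THRESHOLD",
    "FRACTION_PRESENCE_THRESHOLD",
]

CI_PRESENCE_THRESHOLD = 1.01  # minimum daily CI defining blue/fin song presence
SCORE_THRESHOLD = 0.7  # classifier score above which a second counts as song
FRACTION_PRESENCE_THRESHOLD = 3.0  # % of day above score threshold => presence


@dataclass(frozen=True)
class CallBand:
    """Peak and flanking-background 1-Hz bins for one species' song unit."""

    species: str
    peak_bins: tuple
    background_bins: tuple

    def __post_init__(self) -> None:
        if set(self.peak_bins) & set(self.background_bins):
            raise ValueError("peak and background bins must be disjoint")

    @property
    def all_bins(self) -> tuple:
        return tuple(sorted(set(self.peak_bins) | set(self.background_bins)))


# Fin whale 20 Hz pulse; blue whale B call analyzed at its third harmonic.
FIN_BAND = CallBand("fin", peak_bins=(20, 21), background_bins=(19, 22))
BLUE_BAND = CallBand("blue", peak_bins=(42, 43), background_bins=(41, 44))


@dataclass
class PresenceSeries:
    """Daily song presence booleans on coverage-retained days."""

    dates: pd.DatetimeIndex
    present: np.ndarray
    threshold: float
    species: str = ""

    def __post_init__(self) -> None:
        self.present = np.asarray(self.present, dtype=bool)
        if self.present.size != len(self.dates):
            raise ValueError("present flags must match dates")

    def __len__(self) -> int:
        return len(self.dates)

    def to_series(self) -> pd.Series:
        return pd.Series(self.present, index=self.dates, name="present")


def _ci_from_levels(peak: np.ndarray, background: np.ndarray) -> np.ndarray:
    """CI = max(peak-bin dB) / mean(background-bin dB)."""
    num = np.max(peak, axis=-1)
    den = np.mean(background, axis=-1)
    if np.any(den <= 0):
        raise ValueError(
            "non-positive mean background spectrum level; CI is defined for "
            "positive dB levels (dB re 1 uPa^2/Hz at realistic ocean levels)"
        )
    return num / den


def call_index(spectrum: np.ndarray, freqs: np.ndarray, band: CallBand) -> float:
    """Call index of a single dB spectrum on an integer 1-Hz grid."""
    spectrum = np.asarray(spectrum, dtype=float)
    freqs = np.asarray(freqs, dtype=int)
    idx = {int(f): i for i, f in enumerate(freqs)}
    try:
        peak = spectrum[..., [idx[b] for b in band.peak_bins]]
        back = spectrum[..., [idx[b] for b in band.background_bins]]
    except KeyError as e:
        raise ValueError(f"band bin {e} missing from spectrum grid") from None
    return float(_ci_from_levels(peak, back))


def call_index_daily(daily: DailySpectra, band: CallBand) -> pd.Series:
    """Daily CI series from daily mean spectra."""
    peak = daily.band_columns(band.peak_bins)
    back = daily.band_columns(band.background_bins)
    ci = _ci_from_levels(peak.astype(float), back.astype(float))
    return pd.Series(ci, index=daily.dates, name=f"ci_{band.species}")


def call_index_frames(frames: FrameSet, band: CallBand) -> SampleSeries:
    """Per-frame (5-s) CI stream, for diel analyses."""
    peak = frames.band_columns(band.peak_bins)
    back = frames.band_columns(band.background_bins)
    ci = _ci_from_levels(peak.astype(float), back.astype(float))
    if len(frames) > 1:
        steps = np.diff(frames.times.astype("int64"))
        if not np.all(steps == steps[0]):
            raise ValueError("frame CI stream requires a regular frame cadence")
        step = float(steps[0])
    else:
        step = frames.frame_seconds
    return SampleSeries(frames.times[0], step, ci)


def daily_song_fraction(scores: np.ndarray, score_threshold: float = SCORE_THRESHOLD) -> float:
    """Percent of recorded seconds in one day with score strictly above threshold."""
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("empty day: song fraction undefined")
    if np.any(s < 0) or np.any(s > 1):
        raise ValueError("scores must lie in [0, 1]")
    return 100.0 * float(np.count_nonzero(s > score_threshold)) / s.size

def song_fraction_series(scores: SampleSeries,
                         score_threshold: float = SCORE_THRESHOLD) -> pd.Series:
    """Daily percent-of-recording-time song fraction from a 1-s score stream."""
    days = scores.day_index()
    uniq, inverse, counts = np.unique(days, return_inverse=True, return_counts=True)
    above = np.zeros(uniq.size)
    np.add.at(above, inverse, (scores.values > score_threshold).astype(float))
    frac = 100.0 * above / counts
    return pd.Series(frac, index=pd.DatetimeIndex(uniq), name="song_fraction")


def smooth_5day(series: pd.Series, window: int = 5) -> pd.Series:
    """Centered running mean over calendar days.

    The series is re-indexed to a contiguous daily grid so the window is
    defined in calendar days; at the edges and adjacent to gaps the mean is
    taken over the days available in the window.  Only originally-present
    days are returned.
    """
    if series.empty:
        return series.copy()
    full = pd.date_range(series.index.min(), series.index.max(), freq="D")
    on_grid = series.reindex(full)
    sm = on_grid.rolling(window, center=True, min_periods=1).mean()
    return sm.loc[series.index]


def presence(series: pd.Series, threshold: float, species: str = "",
             inclusive: bool = True) -> PresenceSeries:
    """Threshold a (smoothed) daily metric series into daily presence.

    A "minimum value applied to define presence" reads as >= at equality
    (inclusive=True, the default); set inclusive=False for strict >.
    """
    vals = series.to_numpy(dtype=float)
    flags = vals >= threshold if inclusive else vals > threshold
    return PresenceSeries(series.index, flags, threshold, species)


def detection_performance(pres: PresenceSeries, truth: pd.Series) -> tuple[float, float]:
    """Precision and recall of daily presence against ground-truth daily flags.

    ``truth`` is a boolean Series indexed by date.  Precision is NaN when
    nothing is flagged present.
    """
    truth = truth.reindex(pres.dates)
    if truth.isna().any():
        raise ValueError("presence and truth must share the same date domain")
    t = truth.to_numpy(dtype=bool)
    p = pres.present
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    precision = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    recall = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    return precision, recall
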