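"""Phenology and diel structure of song detection.

Seasonal structure is summarized as a monthly climatology (percent of
recorded days with detection, pooled by month across years) and as the
percent of days with detection in each analysis year.  Because song emerges
annually between July and August in all three species, an analysis year runs
July 1 through June 30.  Diel structure is the day:night ratio of
song-positive sample fractions, with day defined by solar elevation
SE > 0 deg and night by SE < -12 deg; twilight samples are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .call_metrics import PresenceSeries
from .series import SampleSeries
from .solar import MARS_LAT, MARS_LON, solar_elevation

__all__ = [
    "AnalysisYear",
    "DielBins",
    "monthly_climatology",
    "annual_detection",
    "whole_period_detection",
    "detection_ratio",
    "day_night_ratio",
]


@dataclass(frozen=True)
class AnalysisYear:
    """July 1 of ``start_year`` through June 30 of the following year."""

    start_year: int
    label: str = ""

    @property
    def start(self) -> pd.Timestamp:
        return pd.Timestamp(self.start_year, 7, 1)

    @property
    def end(self) -> pd.Timestamp:
        return pd.Timestamp(self.start_year + 1, 6, 30)

    def mask(self, dates: pd.DatetimeIndex) -> np.ndarray:
        return (dates >= self.start) & (dates <= self.end)

    def __str__(self) -> str:
        return self.label or f"{self.start_year}-{self.start_year + 1}"


@dataclass(frozen=True)
class DielBins:
    """Solar-elevation bins: day SE > day_min; night SE < night_max.

    The band between them (twilight) belongs to neither bin.
    """

    day_min_deg: float = 0.0
    night_max_deg: float = -12.0

    def classify(self, elevation: np.ndarray) -> np.ndarray:
        """+1 day, -1 night, 0 twilight."""
        e = np.asarray(elevation)
        return np.where(e > self.day_min_deg, 1, np.where(e < self.night_max_deg, -1, 0))


def monthly_climatology(pres: PresenceSeries) -> pd.Series:
    """Percent of recorded days with detection, per month pooled across years.

    Months with zero retained days are NaN.
    """
    s = pres.to_series()
    by_month = s.groupby(s.index.month).mean() * 100.0
    return by_month.reindex(range(1, 13))


def annual_detection(pres: PresenceSeries, year: AnalysisYear) -> float:
    """Percent of retained days with detection within one July-June year."""
    m = year.mask(pres.dates)
    if not m.any():
        raise ValueError(f"no retained days within analysis year {year}")
    return 100.0 * float(np.mean(pres.present[m]))


def whole_period_detection(pres: PresenceSeries) -> float:
    """Percent of retained days with detection over the entire record."""
    if len(pres) == 0:
        raise ValueError("empty presence series")
    return 100.0 * float(np.mean(pres.present))


def detection_ratio(pct_early: float, pct_late: float) -> float:
    """Factor of change between two annual detection percentages."""
    if pct_early <= 0:
        raise ValueError("early-year detection percent must be positive")
    return pct_late / pct_early


def day_night_ratio(
    stream: SampleSeries,
    positive: np.ndarray,
    lat: float = MARS_LAT,
    lon: float = MARS_LON,
    bins: DielBins = DielBins(),
    year: AnalysisYear | None = None,
    solar_resolution_s: float = 60.0,
    method: str = "pooled",
) -> float:
    """Day:night ratio of song-positive sample fractions.

    ratio = (fraction of day-bin samples positive) / (fraction of night-bin
    samples positive).  Twilight samples are excluded.  NaN when the night
    bin has no positive samples (undefined, not infinite); 0.0 when only the
    day bin lacks positives.

    ``positive`` is a boolean array aligned with ``stream`` (e.g. score > 0.7
    for humpback, frame CI >= 1.01 for blue/fin).  Solar elevation is
    evaluated on a coarse grid (default 60 s) and nearest-interpolated to
    sample times; the sun moves < 0.25 deg/min, so the binning error is far
    below the 12-deg band structure.

    ``method="pooled"`` (default) pools all samples across the period;
    ``method="daily"`` averages the per-day positivity fractions within each
    bin first, then forms the ratio of those means.
    """
    positive = np.asarray(positive, dtype=bool)
    if positive.size != len(stream):
        raise ValueError("positive flags must align with the sample stream")

    unix = stream.unix_seconds()
    if year is not None:
        t0 = np.datetime64(year.start, "s").astype("int64")
        t1 = np.datetime64(year.end + pd.Timedelta(days=1), "s").astype("int64")
        sel = (unix >= t0) & (unix < t1)
        unix, positive = unix[sel], positive[sel]
    if unix.size == 0:
        raise ValueError("no samples in the requested period")

    se = _solar_elevation_coarse(unix, lat, lon, solar_resolution_s)
    cls = bins.classify(se)

    if method == "pooled":
        day_frac = _bin_fraction(positive, cls == 1)
        night_frac = _bin_fraction(positive, cls == -1)
    elif method == "daily":
        day_frac = _mean_daily_fraction(unix, positive, cls == 1)
        night_frac = _mean_daily_fraction(unix, positive, cls == -1)
    else:
        raise ValueError("method must be 'pooled' or 'daily'")

    if night_frac is None or day_frac is None:
        raise ValueError("a diel bin contains no samples in the period")
    if night_frac == 0.0:
        return float("nan")
    return day_frac / night_frac


def _bin_fraction(positive: np.ndarray, in_bin: np.ndarray) -> float | None:
    n = int(in_bin.sum())
    if n == 0:
        return None
    return float(np.count_nonzero(positive & in_bin)) / n


def _mean_daily_fraction(unix, positive, in_bin) -> float | None:
    if not in_bin.any():
        return None
    days = (unix[in_bin] // 86400).astype(int)
    pos = positive[in_bin].astype(float)
    frame = pd.DataFrame({"day": days, "pos": pos})
    return float(frame.groupby("day")["pos"].mean().mean())


def _solar_elevation_coarse(unix: np.ndarray, lat: float, lon: float,
                            resolution_s: float) -> np.ndarray:
    """Solar elevation at block centers of a coarse time grid, broadcast back."""
    if resolution_s <= 0:
        return solar_elevation(unix, lat, lon)
    blocks = np.floor(unix / resolution_s).astype("int64")
    uniq, inverse = np.unique(blocks, return_inverse=True)
    centers = (uniq + 0.5) * resolution_s
    return solar_elevation(centers, lat, lon)[inverse]
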