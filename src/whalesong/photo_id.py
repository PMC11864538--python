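"""Visual-detection metrics from photo-identification records.

Photo-ID archives yield, per surveyed day, the number of unique individuals
identified (UID/day).  Three derived metrics track population-level change:
local abundance (distributions of UID/day pooled by year), migration timing
(first month whose median UID/day rises and remains above — or falls and
remains below — a threshold set at the 33rd percentile of all daily values),
and site fidelity (per-individual counts of distinct identification days
within a year, screened at 1-4 minimum days).  Distributions are compared
with Wilcoxon rank-sum tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .phenology import AnalysisYear

__all__ = [
    "read_photo_id_csv",
    "uid_per_day",
    "percentile_threshold",
    "MigrationTiming",
    "migration_timing",
    "site_fidelity",
    "rank_sum_compare",
]

UID_PERCENTILE = 33  # separates the lower third of daily UID values


def read_photo_id_csv(path) -> pd.DataFrame:
    """Read identification records: individual_id, date (ISO-8601), lat, lon.

    Coordinates are optional and unused by the metrics; records lacking them
    are retained.
    """
    df = pd.read_csv(path, dtype={"individual_id": str})
    if not {"individual_id", "date"} <= set(df.columns):
        raise ValueError("photo-ID CSV requires columns individual_id, date")
    df["date"] = pd.to_datetime(df["date"])
    return df


def uid_per_day(records: pd.DataFrame) -> pd.Series:
    """Unique individuals identified per day, on days having photo data.

    Days without identifications are absent from the result, not zero.
    """
    if records.empty:
        return pd.Series(dtype=int, name="uid")
    days = records["date"].dt.normalize()
    out = records.groupby(days)["individual_id"].nunique()
    out.name = "uid"
    out.index.name = "date"
    return out


def percentile_threshold(uid: pd.Series, q: float = UID_PERCENTILE,
                         method: str = "linear") -> float:
    """q-th percentile of daily UID values pooled across all years."""
    if uid.empty:
        raise ValueError("empty UID series")
    return float(np.percentile(uid.to_numpy(dtype=float), q, method=method))


@dataclass
class MigrationTiming:
    """Threshold-crossing summary of one analysis year's UID/day progression."""

    year: AnalysisYear
    threshold: float
    arrival_month: int | None  # calendar month number, or None if not found
    departure_month: int | None
    months_above: int


def _monthly_medians(uid: pd.Series) -> pd.Series:
    """Median UID/day per calendar month, on surveyed days only."""
    periods = uid.index.to_period("M")
    return uid.groupby(periods).median()


def migration_timing(
    uid: pd.Series,
    threshold: float,
    year: AnalysisYear,
    spring_months: tuple = (2, 3, 4, 5, 6),
    winter_months: tuple = (10, 11, 12, 1, 2),
    arrival_horizon_month: int = 9,
    departure_horizon_month: int = 2,
) -> MigrationTiming:
    """Arrival/departure months from the monthly-median UID/day progression.

    Arrival: first month in the spring window (Feb-Jun of the year's ending
    calendar year) whose median rises above the threshold with every
    subsequent monthly median through the persistence horizon (September)
    also above.  Departure is symmetric over the winter window (Oct-Feb)
    with medians falling below the threshold, persistence checked through
    February — the month of the annual minimum.  A month without survey
    data counts as below threshold.  ``months_above`` counts months of the
    analysis year whose median exceeds the threshold.
    """
    med = _monthly_medians(uid)

    def median_at(ts: pd.Timestamp) -> float:
        p = ts.to_period("M")
        return float(med[p]) if p in med.index else float("nan")

    # months_above over the 12 months of the July-June analysis year
    months = pd.period_range(year.start, year.end, freq="M")
    months_above = sum(
        1 for p in months if p in med.index and float(med[p]) > threshold
    )

    spring_year = year.start_year + 1  # Feb-Jun fall in the ending calendar year
    arrival = _first_persistent(
        med, [pd.Timestamp(spring_year, m, 1) for m in spring_months],
        pd.Timestamp(spring_year, arrival_horizon_month, 1),
        threshold, above=True,
    )
    winter_ts = [
        pd.Timestamp(year.start_year if m >= 7 else spring_year, m, 1)
        for m in winter_months
    ]
    departure = _first_persistent(
        med, winter_ts,
        pd.Timestamp(spring_year, departure_horizon_month, 1),
        threshold, above=False,
    )
    return MigrationTiming(year, threshold, arrival, departure, months_above)


def _first_persistent(med: pd.Series, window: list, horizon: pd.Timestamp,
                      threshold: float, above: bool) -> int | None:
    if med.empty:
        return None
    # persistence cannot be checked past the end of the record
    last = med.index.max()
    for start in window:
        p_start = start.to_period("M")
        p_end = min(horizon.to_period("M"), last)
        if p_start > p_end:
            continue
        span = pd.period_range(p_start, p_end, freq="M")
        ok = True
        for p in span:
            v = float(med[p]) if p in med.index else float("nan")
            crossed = (v > threshold) if above else not (v > threshold)
            if np.isnan(v):
                crossed = not above  # no data reads as below threshold
            if not crossed:
                ok = False
                break
        if ok:
            return start.month
    return None


def site_fidelity(records: pd.DataFrame, year: AnalysisYear,
                  min_days_screen: int = 1) -> pd.Series:
    """Distinct identification days per individual within one analysis year.

    Individuals identified on fewer than ``min_days_screen`` days are
    excluded (screening from 1 to 4 days probes sensitivity to transients).
    """
    if not 1 <= min_days_screen <= 4:
        raise ValueError("min_days_screen must be in 1..4")
    if records.empty:
        return pd.Series(dtype=int, name="days_identified")
    dates = records["date"].dt.normalize()
    in_year = (dates >= year.start) & (dates <= year.end)
    sub = records.loc[in_year]
    counts = sub.groupby("individual_id")["date"].apply(
        lambda d: d.dt.normalize().nunique()
    )
    counts.name = "days_identified"
    return counts[counts >= min_days_screen]


def rank_sum_compare(sample_a, sample_b, alternative: str = "two-sided"
                     ) -> tuple[float, int]:
    """Wilcoxon rank-sum (Mann-Whitney) comparison of two samples.

    ``alternative`` refers to sample_a relative to sample_b ('two-sided',
    'less', 'greater').  Exact enumeration is used when the smaller sample
    has <= 8 values and there are no ties; otherwise the normal
    approximation with tie and continuity corrections.  Returns (p, dir)
    where dir is the sign of median(a) - median(b).

    Two samples with all values identical carry no ordering information:
    p = 1 by convention.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    direction = int(np.sign(np.median(a) - np.median(b)))
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0, 0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.pvalue), direction
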