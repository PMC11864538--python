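"""Spectral reduction: frames, daily mean spectra, and coverage accounting.

The long-term monitoring pipeline works from power-spectral-density "frames":
5-second spectra on an integer 1-Hz frequency grid, in dB re 1 uPa^2/Hz.
Frames are averaged into daily mean spectra (in linear power by default),
and only days with sufficient recording coverage enter downstream analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "FrameSet",
    "DailySpectra",
    "CoverageAccounting",
    "Spectrogram",
    "spectrogram",
    "frames_to_daily",
    "coverage_filter",
]

FRAME_SECONDS = 5.0
SECONDS_PER_DAY = 86400.0


@dataclass
class FrameSet:
    """A sequence of PSD frames: times (UTC), 1-Hz frequency grid, dB levels.

    ``psd`` has shape (n_frames, n_freqs); float32 is accepted to keep long
    simulations compact.
    """

    times: np.ndarray  # datetime64[s], shape (n,)
    freqs: np.ndarray  # int Hz, shape (m,), strictly increasing, 1-Hz spaced
    psd: np.ndarray  # dB, shape (n, m)
    frame_seconds: float = FRAME_SECONDS

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[s]")
        self.freqs = np.asarray(self.freqs, dtype=int)
        self.psd = np.atleast_2d(np.asarray(self.psd))
        if self.psd.shape != (self.times.size, self.freqs.size):
            raise ValueError("psd shape does not match times x freqs")
        if self.freqs.size > 1 and not np.all(np.diff(self.freqs) == 1):
            raise ValueError("frequency grid must be 1-Hz spaced and increasing")
        if not np.all(np.isfinite(self.psd)):
            raise ValueError("non-finite PSD values")

    def __len__(self) -> int:
        return self.times.size

    def band_columns(self, bins) -> np.ndarray:
        """dB levels at the requested integer-Hz bins, shape (n, len(bins))."""
        idx = np.searchsorted(self.freqs, np.asarray(sorted(bins)))
        if np.any(idx >= self.freqs.size) or np.any(
            self.freqs[idx] != np.asarray(sorted(bins))
        ):
            raise ValueError(f"bins {sorted(bins)} not all on the frequency grid")
        return self.psd[:, idx]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.psd, index=pd.DatetimeIndex(self.times, name="timestamp"),
                          columns=self.freqs)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, frame_seconds: float = FRAME_SECONDS) -> "FrameSet":
        freqs = np.asarray([int(c) for c in df.columns])
        return cls(df.index.values, freqs, df.to_numpy(), frame_seconds)


@dataclass
class DailySpectra:
    """Daily mean spectra with per-day recording coverage."""

    dates: pd.DatetimeIndex  # normalized to midnight, one entry per day with data
    freqs: np.ndarray
    mean_psd: np.ndarray  # dB, shape (n_days, n_freqs)
    coverage: np.ndarray  # fraction of the day with frames, shape (n_days,)

    def __post_init__(self) -> None:
        self.coverage = np.asarray(self.coverage, dtype=float)
        if np.any(self.coverage < 0) or np.any(self.coverage > 1 + 1e-9):
            raise ValueError("coverage must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.dates)

    def band_columns(self, bins) -> np.ndarray:
        idx = np.searchsorted(self.freqs, np.asarray(sorted(bins)))
        if np.any(idx >= self.freqs.size) or np.any(
            self.freqs[idx] != np.asarray(sorted(bins))
        ):
            raise ValueError(f"bins {sorted(bins)} not all on the frequency grid")
        return self.mean_psd[:, idx]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.mean_psd, index=self.dates, columns=self.freqs)
        df["coverage"] = self.coverage
        return df

    def select(self, mask: np.ndarray) -> "DailySpectra":
        return DailySpectra(self.dates[mask], self.freqs,
                            self.mean_psd[mask], self.coverage[mask])


@dataclass
class CoverageAccounting:
    """Day accounting for a monitoring period.

    ``pct_sampled`` is relative to the full period; ``pct_retained`` and
    ``pct_complete`` are relative to sampled days.
    """

    period_days: int
    sampled_days: int
    retained_days: int
    complete_days: int

    @property
    def rejected_days(self) -> int:
        return self.sampled_days - self.retained_days

    @property
    def pct_sampled(self) -> int:
        return round(100.0 * self.sampled_days / self.period_days)

    @property
    def pct_retained(self) -> int:
        return round(100.0 * self.retained_days / self.sampled_days)

    @property
    def pct_complete(self) -> int:
        return round(100.0 * self.complete_days / self.sampled_days)


@dataclass
class Spectrogram:
    """Time-frequency matrix in dB, 1-Hz frequency resolution."""

    freqs: np.ndarray
    times: np.ndarray  # seconds from start of audio
    psd_db: np.ndarray  # shape (n_freqs, n_times)

    def background_subtracted(self, percentile: float = 1.0) -> np.ndarray:
        """Subtract, per frequency bin, the given percentile over time."""
        floor = np.percentile(self.psd_db, percentile, axis=1, keepdims=True)
        return self.psd_db - floor


def spectrogram(audio: np.ndarray, fs: float = 16000.0, nfft: int = 16000,
                overlap: float = 0.5, calibration_db: float = 0.0) -> Spectrogram:
    """Hann-window spectrogram at 1-Hz resolution (nfft = sample rate).

    Parameters mirror the standard long-term-monitoring recipe: 16 kHz audio,
    nfft 16000 (1 Hz bins), Hann window, 50 % overlap. ``calibration_db`` is
    added to convert to absolute spectrum level for a calibrated hydrophone;
    synthetic work uses the identity calibration (0 dB).
    """
    x = np.asarray(audio, dtype=float)
    if x.size < nfft:
        raise ValueError(f"audio shorter than one window ({x.size} < {nfft} samples)")
    noverlap = int(round(nfft * overlap))
    f, t, sxx = signal.spectrogram(
        x, fs=fs, window="hann", nperseg=nfft, noverlap=noverlap,
        scaling="density", mode="psd",
    )
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(sxx) + calibration_db
    return Spectrogram(f, t, db)


def frames_to_daily(frames: FrameSet, domain: str = "linear") -> DailySpectra:
    """Average PSD frames into one mean spectrum per UTC calendar day.

    domain="linear" (default) averages in linear power then converts back to
    dB — the physically meaningful energy average. domain="db" averages the
    dB values directly, for sensitivity checks.
    """
    if domain not in ("linear", "db"):
        raise ValueError("domain must be 'linear' or 'db'")
    if len(frames) == 0:
        return DailySpectra(pd.DatetimeIndex([]), frames.freqs,
                            np.empty((0, frames.freqs.size)), np.empty(0))
    days = frames.times.astype("datetime64[D]")
    uniq, inverse, counts = np.unique(days, return_inverse=True, return_counts=True)
    n_days, n_freq = uniq.size, frames.freqs.size
    acc = np.zeros((n_days, n_freq))
    if domain == "linear":
        np.add.at(acc, inverse, np.power(10.0, frames.psd.astype(float) / 10.0))
        mean = 10.0 * np.log10(acc / counts[:, None])
    else:
        np.add.at(acc, inverse, frames.psd.astype(float))
        mean = acc / counts[:, None]
    coverage = np.minimum(counts * frames.frame_seconds / SECONDS_PER_DAY, 1.0)
    return DailySpectra(pd.DatetimeIndex(uniq), frames.freqs, mean, coverage)


def coverage_filter(
    daily: DailySpectra,
    min_coverage: float = 0.75,
    period: tuple | None = None,
    complete_coverage: float = 0.999,
) -> tuple[DailySpectra, CoverageAccounting]:
    """Retain days with coverage >= min_coverage, with day accounting.

    ``period`` optionally gives (start_date, end_date) of the full monitoring
    period; otherwise the span of the sampled days is used.
    """
    if period is not None:
        start, end = (np.datetime64(p, "D") for p in period)
        period_days = int((end - start) / np.timedelta64(1, "D")) + 1
    elif len(daily) > 0:
        period_days = int(
            (daily.dates[-1] - daily.dates[0]) / pd.Timedelta(days=1)
        ) + 1
    else:
        period_days = 0
    mask = daily.coverage >= min_coverage
    acct = CoverageAccounting(
        period_days=period_days,
        sampled_days=len(daily),
        retained_days=int(mask.sum()),
        complete_days=int(np.sum(daily.coverage >= complete_coverage)),
    )
    return daily.select(mask), acct
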