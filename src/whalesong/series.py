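"""Regularly-sampled metric streams (1-s song scores, 5-s frame call indices)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SampleSeries"]


@dataclass
class SampleSeries:
    """A regular stream of metric samples starting at a UTC instant.

    Stored as (start, step_s, values) rather than an explicit timestamp per
    sample so that year-long 1-second streams stay compact.
    """

    start: np.datetime64
    step_s: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.start = np.datetime64(self.start, "s")
        self.values = np.asarray(self.values)
        if self.step_s <= 0:
            raise ValueError("step_s must be positive")

    def __len__(self) -> int:
        return self.values.size

    def unix_seconds(self) -> np.ndarray:
        t0 = self.start.astype("int64")
        return t0 + self.step_s * np.arange(self.values.size)

    def timestamps(self) -> np.ndarray:
        return self.start + (self.step_s * np.arange(self.values.size)).astype(
            "timedelta64[s]"
        )

    def day_index(self) -> np.ndarray:
        """Calendar day (datetime64[D]) of every sample."""
        return (self.start + (self.step_s * np.arange(self.values.size)).astype(
            "timedelta64[s]"
        )).astype("datetime64[D]")

    def thin(self, factor: int) -> "SampleSeries":
        if factor < 1:
            raise ValueError("thinning factor must be >= 1")
        return SampleSeries(self.start, self.step_s * factor, self.values[::factor])
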