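"""Suprathreshold excursion ("avalanche") extraction from continuous series.

An event starts when the series rises strictly above a threshold (by default
the median of the entire series) and ends when it returns to or below it.
Its size is the area between the curve and the threshold over the excursion
(rectangle rule, units of value x seconds); its duration is the excursion
length in seconds.  This continuous-excursion definition is the appropriate
avalanche definition for large, densely active populations where empty time
bins never occur.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import TimeSeries

__all__ = ["EventSet", "extract_events"]


@dataclass(frozen=True)
class EventSet:
    """Non-overlapping, time-ordered suprathreshold events of one series.

    ``start`` is the index of the first sample above threshold; ``end`` is
    exclusive (first index at or below threshold again).  ``size`` is
    dt * sum(value - threshold) over the run; ``duration`` is dt * run length.
    """

    start: np.ndarray
    end: np.ndarray
    size: np.ndarray
    duration: np.ndarray
    threshold: float
    dt: float
    source_label: str = ""

    def __post_init__(self) -> None:
        start = np.asarray(self.start, dtype=int)
        end = np.asarray(self.end, dtype=int)
        size = np.asarray(self.size, dtype=float)
        duration = np.asarray(self.duration, dtype=float)
        n = start.size
        if not (end.size == size.size == duration.size == n):
            raise ValueError("event fields must have equal length")
        if n:
            if np.any(end <= start):
                raise ValueError("events must satisfy start < end")
            if np.any(start[1:] < end[:-1]):
                raise ValueError("events must be non-overlapping and time-ordered")
            if np.any(size <= 0) or np.any(duration <= 0):
                raise ValueError("event sizes and durations must be positive")
        for name, arr in [("start", start), ("end", end), ("size", size), ("duration", duration)]:
            object.__setattr__(self, name, arr)

    def __len__(self) -> int:
        return self.start.size

    @property
    def sizes(self) -> np.ndarray:
        return self.size

    @property
    def durations(self) -> np.ndarray:
        return self.duration

    def select(self, mask: np.ndarray) -> "EventSet":
        """Subset of events (boolean mask or index array), order preserved."""
        return EventSet(
            self.start[mask],
            self.end[mask],
            self.size[mask],
            self.duration[mask],
            threshold=self.threshold,
            dt=self.dt,
            source_label=self.source_label,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start_s": self.start * self.dt,
                "end_s": self.end * self.dt,
                "size": self.size,
                "duration": self.duration,
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def extract_events(ts: TimeSeries, threshold: float | str = "median") -> EventSet:
    """Extract maximal runs of samples strictly above a threshold.

    Samples equal to the threshold terminate events ("exceeded" read as
    strict).  Runs touching either boundary of the recording are kept.
    Degenerate events whose area is numerically zero are dropped.  A series
    that never exceeds the threshold yields an empty EventSet.
    """
    v = ts.values
    if isinstance(threshold, str):
        if threshold != "median":
            raise ValueError(f"unknown threshold rule {threshold!r}")
        thr = float(np.median(v))
    else:
        thr = float(threshold)

    above = v > thr
    # run boundaries of the boolean mask
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate(([0], starts))
    if above[-1]:
        ends = np.concatenate((ends, [v.size]))

    excess = np.concatenate(([0.0], np.cumsum(np.where(above, v - thr, 0.0))))
    sizes = ts.dt * (excess[ends] - excess[starts])
    durations = ts.dt * (ends - starts)

    keep = sizes > 0  # drop numerically-zero areas
    return EventSet(
        starts[keep],
        ends[keep],
        sizes[keep],
        durations[keep],
        threshold=thr,
        dt=ts.dt,
        source_label=ts.label,
    )
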