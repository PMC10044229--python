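"""Hourly/daily presence statistics for labeled noise events and calls.

Events are half-open intervals ``[start, end)`` in seconds from the start
of their recording day (recorder-local clock; no timezone conversion).
Events crossing hour boundaries are split at the boundaries before
aggregation, and overlapping intervals are merged (union semantics), which
makes the hourly × days total equal the daily totals exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

__all__ = [
    "NoiseEvent",
    "hourly_presence",
    "daily_totals",
    "calls_per_hour",
    "merge_intervals",
]

DAY_S = 86400.0
QUIET_THRESHOLD_H = 12.0


@dataclass(frozen=True)
class NoiseEvent:
    """A labeled noise interval within one recording day."""

    day: date
    start: float   # s from day start
    end: float
    source: str = "boat"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"non-positive event length: {self}")
        if self.start < 0 or self.end > DAY_S:
            raise ValueError(f"event outside its 24 h day span: {self}")


def merge_intervals(intervals: list[tuple[float, float]]
                    ) -> list[tuple[float, float]]:
    """Union of half-open intervals as a sorted disjoint list."""
    if not intervals:
        return []
    out = []
    for start, end in sorted(intervals):
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


def _split_by_hour(start: float, end: float):
    """Yield (hour, start, end) pieces clipped to hour boundaries."""
    t = start
    while t < end:
        hour = int(t // 3600.0)
        boundary = min((hour + 1) * 3600.0, end)
        yield hour, t, boundary
        t = boundary


def hourly_presence(events: list[NoiseEvent], n_days: int) -> np.ndarray:
    """Mean noise hours per clock hour: a 24-vector with entries in [0, 1].

    Per day and clock hour the union of event intervals is summed, then
    averaged over ``n_days``.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    buckets: dict[tuple[date, int], list[tuple[float, float]]] = {}
    for ev in events:
        for hour, s, e in _split_by_hour(ev.start, ev.end):
            buckets.setdefault((ev.day, hour), []).append((s, e))
    out = np.zeros(24)
    for (_, hour), intervals in buckets.items():
        out[hour] += sum(e - s for s, e in merge_intervals(intervals)) / 3600.0
    return out / n_days


def daily_totals(events: list[NoiseEvent],
                 quiet_threshold_h: float = QUIET_THRESHOLD_H) -> pd.DataFrame:
    """Merged-interval noise hours per day, with a quiet-day flag.

    Returns a frame with columns ``date``, ``total_hours`` and ``quiet``
    (set when the total is below ``quiet_threshold_h``).
    """
    per_day: dict[date, list[tuple[float, float]]] = {}
    for ev in events:
        per_day.setdefault(ev.day, []).append((ev.start, ev.end))
    rows = []
    for day in sorted(per_day):
        total = sum(e - s for s, e in merge_intervals(per_day[day])) / 3600.0
        rows.append({"date": day, "total_hours": total,
                     "quiet": total < quiet_threshold_h})
    return pd.DataFrame(rows, columns=["date", "total_hours", "quiet"])


def calls_per_hour(call_times: list[tuple[date, float]],
                   n_days: int | None = None) -> np.ndarray:
    """Call counts per clock hour, cumulated across days (24-vector)."""
    out = np.zeros(24, dtype=np.int64)
    for _, t in call_times:
        if not 0 <= t < DAY_S:
            raise ValueError(f"call time {t} s outside day span")
        out[int(t // 3600.0)] += 1
    return out
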