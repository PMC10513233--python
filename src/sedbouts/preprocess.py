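"""Missing-epoch imputation and daytime windowing.

Missing activity counts (typically ~1% of epochs) are filled with a moving
median over a centered window; the recording is then carved into per-day
daytime segments of exactly 840 one-minute epochs (08:00-21:59 wall clock).
Imputation runs on the full recording before carving so that epochs near
the window edges can borrow neighbours from outside the daytime window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date as date_type
from datetime import datetime, time, timedelta

import numpy as np
import pandas as pd

from sedbouts.actigraphy_io import EpochSeries

logger = logging.getLogger(__name__)

MINUTES_PER_DAY = 840  # 14 h daytime window at 1-min epochs


class ImputationError(ValueError):
    """Series cannot be imputed (e.g. no observed values at all)."""


@dataclass
class DaytimeDay:
    """One complete daytime window: 840 per-minute counts for one date."""

    subject_id: str
    date: date_type
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.counts) != MINUTES_PER_DAY:
            raise ValueError(
                f"a daytime day has exactly {MINUTES_PER_DAY} epochs, "
                f"got {len(self.counts)}"
            )
        if np.any(np.isnan(self.counts)):
            raise ValueError("daytime day must have no missing values")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def day_type(self) -> str:
        # ISO weekday: Saturday=6, Sunday=7
        return "weekend" if self.date.isoweekday() >= 6 else "weekday"


def impute_moving_median(
    series: EpochSeries, window_minutes: int = 30
) -> EpochSeries:
    """Fill missing epochs with the median of a centered moving window.

    Each missing epoch at index ``i`` is replaced by the median of the
    observed values inside the window ``[i - w//2, i + (w-1)//2]``
    (truncated at the series edges).  Observed values are never altered.
    If every neighbour in the window is itself missing, the nearest
    observed value is used instead (earlier one on ties), which keeps the
    operation total at realistic missingness levels.
    """
    if window_minutes < 1:
        raise ValueError("window_minutes must be >= 1")
    counts = series.counts.copy()
    missing = np.flatnonzero(np.isnan(counts))
    if missing.size == 0:
        return EpochSeries(series.subject_id, series.group, series.start_times, counts)
    observed_idx = np.flatnonzero(~np.isnan(counts))
    if observed_idx.size == 0:
        raise ImputationError(
            f"{series.subject_id}: cannot impute an all-missing series"
        )
    n = len(counts)
    half_lo = window_minutes // 2
    half_hi = (window_minutes - 1) // 2
    original = series.counts  # medians use observed values only, not fills
    for i in missing:
        lo = max(0, i - half_lo)
        hi = min(n, i + half_hi + 1)
        window = original[lo:hi]
        window = window[~np.isnan(window)]
        if window.size:
            counts[i] = float(np.median(window))
        else:
            nearest = observed_idx[np.argmin(np.abs(observed_idx - i))]
            counts[i] = original[nearest]
    return EpochSeries(series.subject_id, series.group, series.start_times, counts)


def carve_daytime_days(
    series: EpochSeries,
    start: time = time(8, 0),
    end: time = time(22, 0),
) -> list[DaytimeDay]:
    """Cut an imputed series into complete daytime days.

    The window is half-open ``[start, end)`` in wall-clock time, which at
    the defaults gives exactly 840 one-minute epochs per calendar day.
    Dates whose window is only partially covered are dropped and logged.
    """
    if np.any(series.missing_mask):
        raise ValueError("carve_daytime_days expects an imputed series")
    start_dt = datetime.combine(datetime.min.date(), start)
    end_dt = datetime.combine(datetime.min.date(), end)
    window_minutes = int((end_dt - start_dt).total_seconds() // 60)
    if window_minutes <= 0:
        raise ValueError("window end must be after window start")

    index = series.start_times
    first = index[0]
    days: list[DaytimeDay] = []
    for day in sorted(set(index.date)):
        win_start = datetime.combine(day, start)
        pos = int((win_start - first.to_pydatetime()).total_seconds() // 60)
        if pos < 0 or pos + window_minutes > len(series):
            logger.info(
                "%s: dropping partial day %s (window not fully covered)",
                series.subject_id,
                day,
            )
            continue
        if index[pos].to_pydatetime() != win_start:
            logger.info(
                "%s: dropping day %s (window start not on the epoch grid)",
                series.subject_id,
                day,
            )
            continue
        days.append(
            DaytimeDay(
                subject_id=series.subject_id,
                date=day,
                counts=series.counts[pos : pos + window_minutes],
            )
        )
    return days
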