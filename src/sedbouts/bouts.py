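"""Sedentary/active classification, bout extraction, binning and features.

An epoch is sedentary when its activity count is strictly below the
threshold (default 100 cpm, the Freedson cut-point); ``wake_total`` counts
epochs at or above it.  A bout is a maximal run of consecutive same-state
epochs; sedentary bouts are binned by duration into the five classes
1-3, 4-5, 6-30, 31-60 and >60 minutes (inclusive integer edges).  Bouts
truncated by the day boundary keep their observed duration so that the
bin decomposition always sums to the total sedentary time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from sedbouts.preprocess import MINUTES_PER_DAY, DaytimeDay

SEDENTARY_THRESHOLD_CPM = 100.0
N_TWO_HOUR_SLOTS = 7
SLOT_MINUTES = MINUTES_PER_DAY // N_TWO_HOUR_SLOTS

DAY_SUBSETS = ("all7", "weekday", "weekend")


@dataclass(frozen=True)
class Bout:
    """Maximal run of same-state epochs within one daytime day."""

    start_index: int
    duration: int
    state: str  # "sedentary" | "active"

    def __post_init__(self) -> None:
        if self.duration < 1 or self.start_index < 0:
            raise ValueError("bouts have start_index >= 0 and duration >= 1")
        if self.state not in ("sedentary", "active"):
            raise ValueError(f"unknown bout state {self.state!r}")


@dataclass(frozen=True)
class BinScheme:
    """Contiguous inclusive duration bins partitioning the positive integers.

    ``edges`` are (lower, upper) pairs in minutes; the last upper bound of
    ``None`` means open-ended.
    """

    edges: tuple[tuple[int, int | None], ...] = (
        (1, 3),
        (4, 5),
        (6, 30),
        (31, 60),
        (61, None),
    )
    labels: tuple[str, ...] = (
        "sed_bouts_1_3",
        "sed_bouts_4_5",
        "sed_bouts_6_30",
        "sed_bouts_31_60",
        "sed_bouts_gt60",
    )

    def __post_init__(self) -> None:
        if len(self.edges) != len(self.labels):
            raise ValueError("one label per bin required")
        prev_hi = 0
        for i, (lo, hi) in enumerate(self.edges):
            if lo != prev_hi + 1:
                raise ValueError("bins must tile the positive integers contiguously")
            if hi is None:
                if i != len(self.edges) - 1:
                    raise ValueError("only the last bin may be open-ended")
                break
            if hi < lo:
                raise ValueError("bin upper bound below lower bound")
            prev_hi = hi
        if self.edges[-1][1] is not None:
            raise ValueError("last bin must be open-ended")

    def index_of(self, duration: int) -> int:
        for i, (lo, hi) in enumerate(self.edges):
            if duration >= lo and (hi is None or duration <= hi):
                return i
        raise ValueError(f"duration {duration} not covered by scheme")

    def __len__(self) -> int:
        return len(self.edges)


DEFAULT_BIN_SCHEME = BinScheme()


@dataclass
class DailySummary:
    """Per subject-day sedentary/active accounting."""

    subject_id: str
    date: object
    day_type: str
    sed_bout_time: np.ndarray  # minutes per bin
    sed_bout_count: np.ndarray  # bouts per bin
    sed_total: float  # minutes
    wake_total: float  # minutes
    two_hour_sed_mean: np.ndarray  # mean cpm of sedentary epochs, nan if none
    two_hour_sed_time: np.ndarray  # sedentary minutes per 2-h slot
    two_hour_act_mean: np.ndarray
    two_hour_act_time: np.ndarray


@dataclass
class SubjectFeatures:
    """Per-subject per-day averages over a day subset; the unit of all
    group statistics."""

    subject_id: str
    group: str
    day_subset: str
    n_days: int
    sed_bout_time: np.ndarray  # minutes/day per bin
    sed_total: float
    wake_total: float
    count_mean: float
    count_sd: float
    count_mean_sed: float  # over epochs with cpm < threshold
    count_sd_sed: float
    count_mean_act: float  # over epochs with cpm >= threshold
    count_sd_act: float


def classify_sedentary(
    counts: np.ndarray, threshold: float = SEDENTARY_THRESHOLD_CPM
) -> np.ndarray:
    """True where the activity count is strictly below the threshold."""
    counts = np.asarray(counts, dtype=float)
    if np.any(np.isnan(counts)):
        raise ValueError("counts must have no missing values")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    return counts < threshold


def extract_bouts(mask: np.ndarray) -> list[Bout]:
    """Run-length encode a sedentary mask into maximal bouts.

    Durations cover the whole day; bouts cut by the day boundary are
    reported at their observed (truncated) length.
    """
    mask = np.asarray(mask, dtype=bool)
    n = len(mask)
    if n == 0:
        return []
    change = np.flatnonzero(mask[1:] != mask[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [n]])
    return [
        Bout(
            start_index=int(s),
            duration=int(e - s),
            state="sedentary" if mask[s] else "active",
        )
        for s, e in zip(starts, ends)
    ]


def bin_sedentary_time(
    bouts: Iterable[Bout], scheme: BinScheme = DEFAULT_BIN_SCHEME
) -> tuple[np.ndarray, np.ndarray]:
    """Minutes and bout counts per duration bin (active bouts ignored)."""
    time = np.zeros(len(scheme))
    count = np.zeros(len(scheme), dtype=int)
    for bout in bouts:
        if bout.state != "sedentary":
            continue
        k = scheme.index_of(bout.duration)
        time[k] += bout.duration
        count[k] += 1
    return time, count


def summarize_day(
    day: DaytimeDay,
    threshold: float = SEDENTARY_THRESHOLD_CPM,
    scheme: BinScheme = DEFAULT_BIN_SCHEME,
) -> DailySummary:
    """Full sedentary/active accounting for one complete daytime day."""
    counts = day.counts
    sed_mask = classify_sedentary(counts, threshold)
    bouts = extract_bouts(sed_mask)
    bin_time, bin_count = bin_sedentary_time(bouts, scheme)
    sed_total = float(sed_mask.sum())
    wake_total = float(len(counts) - sed_total)

    slot_counts = counts.reshape(N_TWO_HOUR_SLOTS, SLOT_MINUTES)
    slot_mask = sed_mask.reshape(N_TWO_HOUR_SLOTS, SLOT_MINUTES)
    sed_time = slot_mask.sum(axis=1).astype(float)
    act_time = SLOT_MINUTES - sed_time
    with np.errstate(invalid="ignore"):
        sed_sum = np.where(slot_mask, slot_counts, 0.0).sum(axis=1)
        act_sum = np.where(~slot_mask, slot_counts, 0.0).sum(axis=1)
        sed_mean = np.where(sed_time > 0, sed_sum / np.maximum(sed_time, 1), np.nan)
        act_mean = np.where(act_time > 0, act_sum / np.maximum(act_time, 1), np.nan)

    return DailySummary(
        subject_id=day.subject_id,
        date=day.date,
        day_type=day.day_type,
        sed_bout_time=bin_time,
        sed_bout_count=bin_count,
        sed_total=sed_total,
        wake_total=wake_total,
        two_hour_sed_mean=sed_mean,
        two_hour_sed_time=sed_time,
        two_hour_act_mean=act_mean,
        two_hour_act_time=act_time,
    )


def _select_subset(day_types: Sequence[str], subset: str) -> np.ndarray:
    if subset not in DAY_SUBSETS:
        raise ValueError(f"day_subset must be one of {DAY_SUBSETS}, got {subset!r}")
    if subset == "all7":
        return np.ones(len(day_types), dtype=bool)
    return np.array([t == subset for t in day_types])


def average_features(
    days: Sequence[DailySummary],
    raw_days: Sequence[DaytimeDay],
    subset: str = "all7",
    group: str = "HC",
    threshold: float = SEDENTARY_THRESHOLD_CPM,
) -> SubjectFeatures:
    """Per-day averages of the daily summaries over a day subset.

    Bout-time features are arithmetic means over the selected days;
    the descriptive count statistics (overall / sedentary / active mean
    and sd) are pooled over every epoch of the selected days.
    """
    if len(days) != len(raw_days):
        raise ValueError("days and raw_days must be parallel sequences")
    keep = _select_subset([d.day_type for d in days], subset)
    if not keep.any():
        raise ValueError(f"no days in subset {subset!r}")
    selected = [d for d, k in zip(days, keep) if k]
    pooled = np.concatenate([rd.counts for rd, k in zip(raw_days, keep) if k])
    sed = pooled[pooled < threshold]
    act = pooled[pooled >= threshold]

    def _stats(values: np.ndarray) -> tuple[float, float]:
        if values.size == 0:
            return float("nan"), float("nan")
        sd = float(np.std(values, ddof=1)) if values.size > 1 else float("nan")
        return float(np.mean(values)), sd

    mean_all, sd_all = _stats(pooled)
    mean_sed, sd_sed = _stats(sed)
    mean_act, sd_act = _stats(act)

    return SubjectFeatures(
        subject_id=selected[0].subject_id,
        group=group,
        day_subset=subset,
        n_days=len(selected),
        sed_bout_time=np.mean([d.sed_bout_time for d in selected], axis=0),
        sed_total=float(np.mean([d.sed_total for d in selected])),
        wake_total=float(np.mean([d.wake_total for d in selected])),
        count_mean=mean_all,
        count_sd=sd_all,
        count_mean_sed=mean_sed,
        count_sd_sed=sd_sed,
        count_mean_act=mean_act,
        count_sd_act=sd_act,
    )


FEATURE_COLUMNS = (
    "sed_bouts_1_3",
    "sed_bouts_4_5",
    "sed_bouts_6_30",
    "sed_bouts_31_60",
    "sed_bouts_gt60",
    "sed_total",
    "wake_total",
)

DESCRIPTIVE_COLUMNS = (
    "count_mean",
    "count_sd",
    "count_mean_sed",
    "count_sd_sed",
    "count_mean_act",
    "count_sd_act",
)


def features_frame(features: Iterable[SubjectFeatures]) -> pd.DataFrame:
    """Tidy feature table: one row per subject x day_subset."""
    rows = []
    for f in features:
        row = {
            "subject_id": f.subject_id,
            "group": f.group,
            "day_subset": f.day_subset,
            "n_days": f.n_days,
        }
        row.update(dict(zip(FEATURE_COLUMNS[:5], f.sed_bout_time)))
        row["sed_total"] = f.sed_total
        row["wake_total"] = f.wake_total
        for col in DESCRIPTIVE_COLUMNS:
            row[col] = getattr(f, col)
        rows.append(row)
    return pd.DataFrame(rows)


def group_table(features: Sequence[SubjectFeatures], group: str) -> pd.Series:
    """Arithmetic mean of every per-subject feature across a group."""
    members = [f for f in features if f.group == group]
    if not members:
        raise ValueError(f"no subjects in group {group!r}")
    frame = features_frame(members)
    return frame[list(FEATURE_COLUMNS + DESCRIPTIVE_COLUMNS)].mean()
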