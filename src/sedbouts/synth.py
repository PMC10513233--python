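"""Synthetic actigraphy cohorts from an alternating renewal process.

Each subject alternates between a sedentary and an active state with
independent exponentially distributed dwell times (rounded up to whole
minutes, minimum one epoch).  Epoch counts are drawn conditional on the
state from discretized gamma distributions whose supports respect the
100-cpm partition -- sedentary counts on [0, 100), active counts on
[100, 1500] -- so the threshold classifier recovers the simulated state
sequence exactly.  Active intensity is modulated by a cosine diurnal
profile peaking at a group-specific hour.

The default group presets are calibrated so that cohort-level outputs
land near the contrast the analysis targets: acute-insomnia subjects
around 540 sedentary minutes/day dominated by medium and long bouts,
healthy controls around 460 minutes/day accumulated in short bouts with
more active time.  This is a qualitative calibration of the generator,
not a claim of numeric reproduction of any particular cohort.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from sedbouts.actigraphy_io import (
    EpochSeries,
    SubjectRecord,
    write_epoch_csv,
    write_manifest,
)
from sedbouts.bouts import Bout, extract_bouts
from sedbouts.preprocess import MINUTES_PER_DAY, DaytimeDay

MINUTES_PER_CALENDAR_DAY = 1440
DAY_START = time(8, 0)
# first simulated day is a Monday so a 7-day week has 5 weekdays + 2 weekend days
DEFAULT_START_DATE = date(2024, 1, 1)

SUBJECT_DWELL_SD = 0.2  # sd of the log-normal subject-level dwell multiplier


@dataclass(frozen=True)
class GroupPreset:
    """Generator parameters for one group.

    Dwell means are in minutes; count levels are mean cpm conditional on
    state; ``diurnal_peak`` is the wall-clock hour of maximum active
    intensity.
    """

    group: str
    mean_sed_bout: float
    mean_act_bout: float
    sed_count_level: float
    act_count_level: float
    missing_frac: float = 0.01
    diurnal_peak: time = time(15, 0)
    diurnal_amplitude: float = 0.3

    def __post_init__(self) -> None:
        if self.mean_sed_bout <= 0:
            raise ValueError("mean_sed_bout must be positive")
        if self.mean_act_bout < 0:
            raise ValueError("mean_act_bout must be non-negative")
        if not 0 <= self.sed_count_level < 100 <= self.act_count_level:
            raise ValueError("count levels must satisfy 0 <= sed < 100 <= act")
        if not 0 <= self.missing_frac < 0.1:
            raise ValueError("missing_frac must lie in [0, 0.1)")


# Dwell means solved so that the expected epoch-scale occupancy
# E[ceil(S)] / (E[ceil(S)] + E[ceil(A)]) matches the target sedentary
# fraction of each group (~541/840 and ~461/840); count levels are the
# group-conditional mean cpm of each state.
AI_PRESET = GroupPreset(
    group="AI",
    mean_sed_bout=10.0,
    mean_act_bout=5.272,
    sed_count_level=19.3,
    act_count_level=333.0,
    diurnal_peak=time(19, 0),
)
HC_PRESET = GroupPreset(
    group="HC",
    mean_sed_bout=7.5,
    mean_act_bout=6.074,
    sed_count_level=23.5,
    act_count_level=355.0,
    diurnal_peak=time(15, 0),
)


@dataclass
class CohortData:
    """A simulated cohort: manifest rows, epoch series and ground truth."""

    records: list[SubjectRecord]
    series: dict[str, EpochSeries]
    # subject_id -> one Bout list per simulated daytime day (pre-missingness)
    ground_truth: dict[str, list[list[Bout]]]


def _expected_epoch_dwell(mean: float) -> float:
    """E[ceil(Exp(mean))] = 1 / (1 - exp(-1/mean))."""
    return 1.0 / (1.0 - math.exp(-1.0 / mean))


def sample_dwell_times(
    mean: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Continuous exponential dwell times (minutes) of one state.

    This is the raw dwell law of the renewal process; the simulator
    discretizes these draws to whole epochs with ``ceil`` (minimum 1).
    """
    return rng.exponential(mean, size)


def _dwell_minutes(mean: float, size: int, rng: np.random.Generator) -> np.ndarray:
    return np.maximum(1, np.ceil(sample_dwell_times(mean, size, rng))).astype(int)


def _simulate_state_mask(
    n_minutes: int,
    mean_sed: float,
    mean_act: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Boolean sedentary mask from the alternating renewal process."""
    if mean_act <= 0:  # degenerate: never leaves the sedentary state
        return np.ones(n_minutes, dtype=bool)
    e_sed = _expected_epoch_dwell(mean_sed)
    e_act = _expected_epoch_dwell(mean_act)
    start_sed = bool(rng.random() < e_sed / (e_sed + e_act))

    # draw dwell pairs in bulk; 50% headroom plus a floor avoids refills
    n_pairs = int(n_minutes / (e_sed + e_act) * 1.5) + 16
    mask = np.empty(n_minutes, dtype=bool)
    pos = 0
    state = start_sed
    while pos < n_minutes:
        sed_d = _dwell_minutes(mean_sed, n_pairs, rng)
        act_d = _dwell_minutes(mean_act, n_pairs, rng)
        if state:
            durs = np.empty(2 * n_pairs, dtype=int)
            durs[0::2], durs[1::2] = sed_d, act_d
        else:
            durs = np.empty(2 * n_pairs, dtype=int)
            durs[0::2], durs[1::2] = act_d, sed_d
        states = np.empty(2 * n_pairs, dtype=bool)
        states[0::2], states[1::2] = state, not state
        for d, s in zip(durs, states):
            end = min(pos + d, n_minutes)
            mask[pos:end] = s
            pos = end
            if pos >= n_minutes:
                break
        state = not states[-1]  # next chunk continues the alternation
    return mask


def _diurnal_factor(
    minute_of_day: np.ndarray, peak: time, amplitude: float
) -> np.ndarray:
    peak_minutes = peak.hour * 60 + peak.minute
    phase = 2.0 * np.pi * (minute_of_day - peak_minutes) / MINUTES_PER_CALENDAR_DAY
    return 1.0 + amplitude * np.cos(phase)


def _draw_counts(
    sed_mask: np.ndarray,
    minute_of_day: np.ndarray,
    preset: GroupPreset,
    rng: np.random.Generator,
) -> np.ndarray:
    """Counts conditional on state, respecting the 100-cpm partition."""
    n = len(sed_mask)
    counts = np.empty(n, dtype=float)

    n_sed = int(sed_mask.sum())
    if n_sed:
        shape = 1.5
        draw = rng.gamma(shape, preset.sed_count_level / shape, n_sed)
        counts[sed_mask] = np.clip(np.floor(draw), 0, 99)

    act_mask = ~sed_mask
    n_act = int(act_mask.sum())
    if n_act:
        factor = _diurnal_factor(
            minute_of_day[act_mask], preset.diurnal_peak, preset.diurnal_amplitude
        )
        excess_mean = np.maximum(preset.act_count_level * factor - 100.0, 10.0)
        shape = 2.0
        draw = rng.gamma(shape, excess_mean / shape)
        counts[act_mask] = np.clip(100.0 + np.floor(draw), 100, 1500)
    return counts


def simulate_day(
    preset: GroupPreset,
    rng_seed: int | np.random.Generator = 0,
    day: date = DEFAULT_START_DATE,
    subject_id: str = "sim",
) -> tuple[DaytimeDay, list[Bout]]:
    """Simulate one daytime day and return it with its true segmentation."""
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    sed_mask = _simulate_state_mask(
        MINUTES_PER_DAY, preset.mean_sed_bout, preset.mean_act_bout, rng
    )
    start_minute = DAY_START.hour * 60 + DAY_START.minute
    minute_of_day = start_minute + np.arange(MINUTES_PER_DAY)
    counts = _draw_counts(sed_mask, minute_of_day, preset, rng)
    truth = extract_bouts(sed_mask)
    return DaytimeDay(subject_id=subject_id, date=day, counts=counts), truth


def _simulate_subject(
    subject_id: str,
    preset: GroupPreset,
    n_days: int,
    start_date: date,
    rng: np.random.Generator,
) -> tuple[EpochSeries, list[list[Bout]]]:
    # subject-level variability: independent log-normal multipliers on
    # the two dwell means
    mult = np.exp(rng.normal(0.0, SUBJECT_DWELL_SD, 2))
    mean_sed = preset.mean_sed_bout * mult[0]
    mean_act = preset.mean_act_bout * mult[1] if preset.mean_act_bout > 0 else 0.0

    total = (n_days - 1) * MINUTES_PER_CALENDAR_DAY + MINUTES_PER_DAY
    sed_mask = _simulate_state_mask(total, mean_sed, mean_act, rng)
    start_dt = datetime.combine(start_date, DAY_START)
    start_minute = DAY_START.hour * 60 + DAY_START.minute
    minute_of_day = (start_minute + np.arange(total)) % MINUTES_PER_CALENDAR_DAY
    counts = _draw_counts(sed_mask, minute_of_day, preset, rng)

    truth = []
    for d in range(n_days):
        offset = d * MINUTES_PER_CALENDAR_DAY
        truth.append(extract_bouts(sed_mask[offset : offset + MINUTES_PER_DAY]))

    if preset.missing_frac > 0:
        missing = rng.random(total) < preset.missing_frac
        counts = counts.copy()
        counts[missing] = np.nan

    series = EpochSeries(
        subject_id=subject_id,
        group=preset.group,
        start_times=pd.date_range(start_dt, periods=total, freq="min"),
        counts=counts,
    )
    return series, truth


def simulate_cohort(
    n_ai: int = 15,
    n_hc: int = 22,
    n_days: int = 7,
    presets: tuple[GroupPreset, GroupPreset] = (AI_PRESET, HC_PRESET),
    rng_seed: int = 0,
    start_date: date = DEFAULT_START_DATE,
) -> CohortData:
    """Simulate a two-group cohort, reproducible from ``rng_seed``.

    Subjects get independent random substreams spawned from the single
    seed, so the cohort is bit-reproducible and subjects independent.
    Recording weeks start on a Monday; ages are uniform on [20, 40].
    """
    if min(n_ai, n_hc, n_days) < 1:
        raise ValueError("n_ai, n_hc and n_days must all be >= 1")
    ai_preset, hc_preset = presets
    n_subjects = n_ai + n_hc
    seeds = np.random.SeedSequence(rng_seed).spawn(n_subjects + 1)
    demo_rng = np.random.default_rng(seeds[0])

    records: list[SubjectRecord] = []
    series: dict[str, EpochSeries] = {}
    truth: dict[str, list[list[Bout]]] = {}
    specs = [("AI", ai_preset, i + 1) for i in range(n_ai)] + [
        ("HC", hc_preset, i + 1) for i in range(n_hc)
    ]
    for k, (group, preset, idx) in enumerate(specs):
        subject_id = f"{group}{idx:02d}"
        rng = np.random.default_rng(seeds[k + 1])
        s, t = _simulate_subject(subject_id, preset, n_days, start_date, rng)
        series[subject_id] = s
        truth[subject_id] = t
        records.append(
            SubjectRecord(
                subject_id=subject_id,
                group=group,
                age=int(demo_rng.integers(20, 41)),
                sex=str(demo_rng.choice(["male", "female"])),
                file=f"{subject_id}.csv",
                n_days=n_days,
            )
        )
    return CohortData(records=records, series=series, ground_truth=truth)


def write_cohort(cohort: CohortData, out_dir: str | Path) -> Path:
    """Write manifest, per-subject epoch CSVs and ground-truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_manifest(cohort.records, out_dir / "manifest.csv")
    for rec in cohort.records:
        write_epoch_csv(cohort.series[rec.subject_id], out_dir / rec.file)
    truth_json = {
        sid: [
            [
                {"start_index": b.start_index, "duration": b.duration, "state": b.state}
                for b in day
            ]
            for day in days
        ]
        for sid, days in cohort.ground_truth.items()
    }
    (out_dir / "ground_truth.json").write_text(
        json.dumps(truth_json), encoding="utf-8"
    )
    return out_dir / "manifest.csv"
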