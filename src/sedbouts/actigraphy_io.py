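"""Epoch-level actigraphy I/O and cohort manifest handling.

The canonical interchange format is a per-subject CSV with two columns,
``timestamp`` (ISO-8601, minute precision) and ``count`` (non-negative
integer activity counts per minute; empty cell = missing epoch), plus a
manifest CSV ``subject_id,group,age,sex,file`` that carries the cohort
metadata.  Other device exports can be mapped onto this layout with a thin
adapter via :class:`CsvDialect`.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GROUPS = ("AI", "HC")
SEXES = ("male", "female", "unknown")

EPOCH_SECONDS = 60


class EpochParseError(ValueError):
    """Malformed epoch file (bad timestamp, count or spacing)."""


@dataclass
class CsvDialect:
    """Column naming and timestamp format of an epoch CSV."""

    timestamp_col: str = "timestamp"
    count_col: str = "count"
    timestamp_format: str = "%Y-%m-%d %H:%M"


DEFAULT_DIALECT = CsvDialect()


@dataclass
class EpochSeries:
    """One subject's per-minute activity counts.

    ``counts`` is a float array with ``nan`` at missing epochs; the boolean
    ``missing_mask`` property mirrors that.  Timestamps are wall-clock,
    strictly increasing at exactly 60-second spacing.
    """

    subject_id: str
    group: str
    start_times: pd.DatetimeIndex
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.start_times = pd.DatetimeIndex(self.start_times)
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.start_times) != len(self.counts):
            raise ValueError("timestamps and counts must have equal length")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if len(self.start_times) > 1:
            deltas = np.diff(self.start_times.asi8) / 1e9
            if not np.all(deltas == EPOCH_SECONDS):
                bad = int(np.flatnonzero(deltas != EPOCH_SECONDS)[0])
                raise EpochParseError(
                    f"epoch spacing must be {EPOCH_SECONDS} s; "
                    f"found {deltas[bad]:.0f} s between rows {bad + 1} and {bad + 2}"
                )
        observed = self.counts[~np.isnan(self.counts)]
        if np.any(observed < 0):
            raise ValueError("activity counts must be non-negative")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.counts)

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class SubjectRecord:
    """Manifest row: subject identity, group label and demographics."""

    subject_id: str
    group: str
    age: int
    sex: str = "unknown"
    file: str | None = None
    n_days: int | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.age < 0:
            raise ValueError("age must be non-negative")
        if self.n_days is not None and self.n_days < 1:
            raise ValueError("n_days must be >= 1 when known")


def read_epoch_csv(
    path: str | Path,
    dialect: CsvDialect = DEFAULT_DIALECT,
    subject_id: str | None = None,
    group: str = "HC",
) -> EpochSeries:
    """Read one subject's epoch CSV into an :class:`EpochSeries`.

    Rows with an empty or NA count become missing epochs.  Raises
    :class:`EpochParseError` naming the offending line for malformed
    timestamps, and rejects negative counts, non-monotone timestamps and
    spacing other than one minute.
    """
    path = Path(path)
    times: list[datetime] = []
    counts: list[float] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or dialect.timestamp_col not in reader.fieldnames:
            raise EpochParseError(
                f"{path.name}: missing required column {dialect.timestamp_col!r}"
            )
        if dialect.count_col not in reader.fieldnames:
            raise EpochParseError(
                f"{path.name}: missing required column {dialect.count_col!r}"
            )
        for row in reader:
            lineno = reader.line_num
            raw_ts = (row[dialect.timestamp_col] or "").strip()
            try:
                ts = datetime.strptime(raw_ts, dialect.timestamp_format)
            except ValueError as exc:
                raise EpochParseError(
                    f"{path.name}, line {lineno}: cannot parse timestamp {raw_ts!r} "
                    f"with format {dialect.timestamp_format!r}"
                ) from exc
            raw_count = (row[dialect.count_col] or "").strip()
            if raw_count == "" or raw_count.upper() in {"NA", "NAN"}:
                value = float("nan")
            else:
                try:
                    value = float(raw_count)
                except ValueError as exc:
                    raise EpochParseError(
                        f"{path.name}, line {lineno}: non-numeric count {raw_count!r}"
                    ) from exc
                if value < 0:
                    raise ValueError(
                        f"{path.name}, line {lineno}: negative count {raw_count}"
                    )
            if times and ts <= times[-1]:
                raise EpochParseError(
                    f"{path.name}, line {lineno}: timestamps not strictly increasing"
                )
            times.append(ts)
            counts.append(value)
    return EpochSeries(
        subject_id=subject_id or path.stem,
        group=group,
        start_times=pd.DatetimeIndex(times),
        counts=np.array(counts, dtype=float),
    )


def write_epoch_csv(
    series: EpochSeries,
    path: str | Path,
    dialect: CsvDialect = DEFAULT_DIALECT,
) -> None:
    """Write an epoch CSV (UTF-8, Unix line endings, empty cell = missing)."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow([dialect.timestamp_col, dialect.count_col])
    for ts, value in zip(series.start_times, series.counts):
        cell = "" if np.isnan(value) else str(int(value))
        writer.writerow([ts.strftime(dialect.timestamp_format), cell])
    Path(path).write_text(buf.getvalue(), encoding="utf-8", newline="\n")


def read_manifest(path: str | Path) -> list[SubjectRecord]:
    """Read the cohort manifest CSV into :class:`SubjectRecord` rows."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                group=str(row.group),
                age=int(row.age),
                sex=str(getattr(row, "sex", "unknown")),
                file=str(row.file) if getattr(row, "file", None) is not None else None,
            )
        )
    return records


def write_manifest(records: Iterable[SubjectRecord], path: str | Path) -> None:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["subject_id", "group", "age", "sex", "file"])
    for rec in records:
        writer.writerow([rec.subject_id, rec.group, rec.age, rec.sex, rec.file or ""])
    Path(path).write_text(buf.getvalue(), encoding="utf-8", newline="\n")


def filter_cohort(
    records: Sequence[SubjectRecord],
    min_age: int = 20,
    max_age: int = 40,
) -> list[SubjectRecord]:
    """Keep subjects with ``min_age <= age <= max_age`` (order preserved).

    Bounds are inclusive so that an age-balanced 20-40 cohort keeps both
    endpoints; the bounds are parameters so other inclusion windows are
    reproducible.
    """
    if min_age > max_age:
        raise ValueError("min_age must not exceed max_age")
    return [rec for rec in records if min_age <= rec.age <= max_age]
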