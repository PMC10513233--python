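"""End-to-end orchestration: manifest -> preprocessing -> features -> reports.

The pipeline reads a cohort manifest plus per-subject epoch CSVs, imputes
and carves each recording, computes per-day and per-subject sedentary
features, and writes a report bundle: the tidy feature table, descriptive
count statistics, group-comparison tables (exponential means with 95%
bounds and K-S tests) for all-7/weekday/weekend day subsets, the logistic
coefficient table, 2-hour aggregates, and a run log.  Every report row is
recomputable from the per-subject feature CSV alone.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings as _warnings
from dataclasses import dataclass, field
from datetime import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import sedbouts
from sedbouts.actigraphy_io import (
    DEFAULT_DIALECT,
    SubjectRecord,
    filter_cohort,
    read_epoch_csv,
    read_manifest,
)
from sedbouts.bouts import (
    DAY_SUBSETS,
    DEFAULT_BIN_SCHEME,
    FEATURE_COLUMNS,
    N_TWO_HOUR_SLOTS,
    DailySummary,
    SubjectFeatures,
    average_features,
    features_frame,
    summarize_day,
)
from sedbouts.dist_stats import fit_exponential, ks_two_sample
from sedbouts.logit import SeparationWarning, coefficient_table, fit_logistic
from sedbouts.preprocess import MINUTES_PER_DAY, carve_daytime_days, impute_moving_median
from sedbouts.synth import CohortData

logger = logging.getLogger(__name__)

BIN_COLUMNS = FEATURE_COLUMNS[:5]

DESCRIPTIVE_ROWS = (
    ("mean", "count_mean"),
    ("sd", "count_sd"),
    ("mean_lt100", "count_mean_sed"),
    ("sd_lt100", "count_sd_sed"),
    ("mean_ge100", "count_mean_act"),
    ("sd_ge100", "count_sd_act"),
)

SLOT_LABELS = tuple(f"{8 + 2 * k:02d}-{10 + 2 * k:02d}" for k in range(N_TWO_HOUR_SLOTS))


@dataclass
class RunConfig:
    """Pipeline parameters; defaults reproduce the standard analysis."""

    manifest: str | Path | None = None
    out_dir: str | Path | None = None
    threshold_cpm: float = 100.0
    window_start: str = "08:00"
    window_end: str = "22:00"
    imputation_window: int = 30
    min_age: int = 20
    max_age: int = 40
    day_subsets: tuple[str, ...] = DAY_SUBSETS
    ks_granularity: str = "subject"  # "subject" | "subject-day"
    report_precision: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.ks_granularity not in ("subject", "subject-day"):
            raise ValueError("ks_granularity must be 'subject' or 'subject-day'")
        for subset in self.day_subsets:
            if subset not in DAY_SUBSETS:
                raise ValueError(f"unknown day subset {subset!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "day_subsets" in data:
            data["day_subsets"] = tuple(data["day_subsets"])
        data.update(overrides)
        return cls(**data)

    def window_times(self) -> tuple[time, time]:
        def _parse(s: str) -> time:
            h, m = s.split(":")
            return time(int(h), int(m))

        return _parse(self.window_start), _parse(self.window_end)


@dataclass
class ReportBundle:
    """All machine-readable pipeline outputs, in memory."""

    features: pd.DataFrame
    daily: pd.DataFrame
    descriptive: pd.DataFrame
    comparisons: dict[str, pd.DataFrame]
    logistic: pd.DataFrame
    logistic_converged: bool
    two_hour: pd.DataFrame
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# report-layer arithmetic


def write_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Machine CSV writer: %.17g keeps every float bit-round-trippable."""
    table.to_csv(path, index=False, float_format="%.17g")


def bin_time_sum(table: pd.DataFrame) -> pd.Series:
    """Sum of the five bout-bin time columns, row by row.

    This is the summation used to check the decomposition invariant
    ``sum(bins) == sed_total`` on any feature or report table.
    """
    return table[list(BIN_COLUMNS)].sum(axis=1)


def decomposition_residuals(table: pd.DataFrame) -> pd.Series:
    """Absolute shortfall between the bin sum and ``sed_total`` per row."""
    return (bin_time_sum(table) - table["sed_total"]).abs()


# ---------------------------------------------------------------------------
# feature computation


def summarize_subject(
    record: SubjectRecord,
    series,
    config: RunConfig,
) -> tuple[list[SubjectFeatures], list[DailySummary], list[str]]:
    """Impute, carve and summarize one subject's recording."""
    notes: list[str] = []
    imputed = impute_moving_median(series, config.imputation_window)
    start, end = config.window_times()
    days = carve_daytime_days(imputed, start, end)
    if not days:
        raise ValueError(f"{record.subject_id}: no complete daytime days")
    summaries = [summarize_day(d, config.threshold_cpm) for d in days]
    for s in summaries:
        short = abs((s.sed_total + s.wake_total) - MINUTES_PER_DAY)
        if short > 1e-9:
            notes.append(
                f"{record.subject_id} {s.date}: conservation shortfall {short:.2f} min"
            )
    features = []
    for subset in config.day_subsets:
        day_types = {d.day_type for d in days}
        if subset != "all7" and subset not in day_types:
            notes.append(f"{record.subject_id}: no {subset} days, subset skipped")
            continue
        features.append(
            average_features(
                summaries, days, subset, group=record.group, threshold=config.threshold_cpm
            )
        )
    return features, summaries, notes


def daily_frame(summaries: list[DailySummary], groups: dict[str, str]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "subject_id": s.subject_id,
            "group": groups[s.subject_id],
            "date": s.date,
            "day_type": s.day_type,
        }
        row.update(dict(zip(BIN_COLUMNS, s.sed_bout_time)))
        row["sed_total"] = s.sed_total
        row["wake_total"] = s.wake_total
        for k in range(N_TWO_HOUR_SLOTS):
            row[f"sed_time_{SLOT_LABELS[k]}"] = s.two_hour_sed_time[k]
            row[f"sed_mean_{SLOT_LABELS[k]}"] = s.two_hour_sed_mean[k]
            row[f"act_time_{SLOT_LABELS[k]}"] = s.two_hour_act_time[k]
            row[f"act_mean_{SLOT_LABELS[k]}"] = s.two_hour_act_mean[k]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# report tables


def _fit_with_bounds(values: np.ndarray, warnings_out: list[str], label: str):
    """Exponential mean and bounds; mean-only when zeros leave the model."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        return np.nan, np.nan, np.nan
    if np.all(values > 0):
        fit = fit_exponential(values)
        return fit.mean_hat, fit.ci_lower, fit.ci_upper
    warnings_out.append(
        f"{label}: non-positive values present; exponential bounds not computed"
    )
    return float(np.mean(values)), np.nan, np.nan


def comparison_table(
    features: pd.DataFrame,
    subset: str,
    daily: pd.DataFrame | None = None,
    granularity: str = "subject",
    warnings_out: list[str] | None = None,
) -> pd.DataFrame:
    """Group means with 95% exponential bounds and K-S tests per feature.

    ``granularity`` selects the statistical unit: per-subject averages
    (default) or per-subject-day values (requires ``daily``).
    """
    if warnings_out is None:
        warnings_out = []
    if granularity == "subject":
        table = features[features["day_subset"] == subset]
    elif granularity == "subject-day":
        if daily is None:
            raise ValueError("subject-day granularity requires the daily table")
        table = daily if subset == "all7" else daily[daily["day_type"] == subset]
    else:
        raise ValueError(f"unknown granularity {granularity!r}")

    rows = []
    for feature in FEATURE_COLUMNS:
        ai = table.loc[table["group"] == "AI", feature].to_numpy(dtype=float)
        hc = table.loc[table["group"] == "HC", feature].to_numpy(dtype=float)
        ai_mean, ai_lo, ai_hi = _fit_with_bounds(ai, warnings_out, f"AI {feature}")
        hc_mean, hc_lo, hc_hi = _fit_with_bounds(hc, warnings_out, f"HC {feature}")
        if ai.size and hc.size:
            ks = ks_two_sample(ai[~np.isnan(ai)], hc[~np.isnan(hc)])
            ks_d, ks_p = ks.D, ks.p
        else:
            ks_d, ks_p = np.nan, np.nan
        rows.append(
            {
                "feature": feature,
                "ai_mean": ai_mean,
                "ai_ci_lower": ai_lo,
                "ai_ci_upper": ai_hi,
                "hc_mean": hc_mean,
                "hc_ci_lower": hc_lo,
                "hc_ci_upper": hc_hi,
                "ks_D": ks_d,
                "ks_p": ks_p,
            }
        )
    return pd.DataFrame(rows)


def descriptive_table(features: pd.DataFrame) -> pd.DataFrame:
    """Raw-count descriptive statistics per group with K-S p-values."""
    table = features[features["day_subset"] == "all7"]
    rows = []
    for label, column in DESCRIPTIVE_ROWS:
        ai = table.loc[table["group"] == "AI", column].dropna().to_numpy(dtype=float)
        hc = table.loc[table["group"] == "HC", column].dropna().to_numpy(dtype=float)
        ks = ks_two_sample(ai, hc) if ai.size and hc.size else None
        rows.append(
            {
                "statistic": label,
                "ai_mean": float(np.mean(ai)) if ai.size else np.nan,
                "ai_sd": float(np.std(ai, ddof=1)) if ai.size > 1 else np.nan,
                "hc_mean": float(np.mean(hc)) if hc.size else np.nan,
                "hc_sd": float(np.std(hc, ddof=1)) if hc.size > 1 else np.nan,
                "ks_D": ks.D if ks else np.nan,
                "ks_p": ks.p if ks else np.nan,
            }
        )
    return pd.DataFrame(rows)


def logistic_table(features: pd.DataFrame) -> tuple[pd.DataFrame, bool, list[str]]:
    """Logistic regression of group (1 = HC) on the five bout bins."""
    table = features[features["day_subset"] == "all7"]
    X = table[list(BIN_COLUMNS)].to_numpy(dtype=float)
    y = (table["group"] == "HC").to_numpy(dtype=float)
    notes: list[str] = []
    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always", SeparationWarning)
        model = fit_logistic(X, y)
        for w in caught:
            if issubclass(w.category, SeparationWarning):
                notes.append(f"logistic regression: {w.message}")
    return coefficient_table(model), model.converged, notes


def two_hour_table(daily: pd.DataFrame) -> pd.DataFrame:
    """Group-level 2-hour aggregates (sedentary/active time and mean cpm).

    Slot means undefined for a subject-day (no epochs of that state in
    the slot) are excluded from the cross-day averages.
    """
    rows = []
    for group, gtab in daily.groupby("group", sort=True):
        for k, slot in enumerate(SLOT_LABELS):
            per_subject = gtab.groupby("subject_id").agg(
                sed_time=(f"sed_time_{slot}", "mean"),
                sed_mean=(f"sed_mean_{slot}", "mean"),  # nan slots auto-excluded
                act_time=(f"act_time_{slot}", "mean"),
                act_mean=(f"act_mean_{slot}", "mean"),
            )
            rows.append(
                {
                    "group": group,
                    "slot": slot,
                    "sed_time_min": per_subject["sed_time"].mean(),
                    "sed_mean_cpm": per_subject["sed_mean"].mean(),
                    "act_time_min": per_subject["act_time"].mean(),
                    "act_mean_cpm": per_subject["act_mean"].mean(),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration


def analyze_features(
    all_features: list[SubjectFeatures],
    all_summaries: list[DailySummary],
    groups: dict[str, str],
    config: RunConfig,
    notes: list[str],
) -> ReportBundle:
    features = features_frame(all_features)
    daily = daily_frame(all_summaries, groups)

    residuals = decomposition_residuals(features)
    if (residuals > 1e-9).any():
        notes.append(
            f"bin decomposition shortfall up to {residuals.max():.3f} min "
            "in the feature table"
        )

    have_both = {"AI", "HC"} <= set(features["group"])
    comparisons: dict[str, pd.DataFrame] = {}
    if have_both:
        for subset in config.day_subsets:
            comparisons[subset] = comparison_table(
                features, subset, daily, config.ks_granularity, notes
            )
        descriptive = descriptive_table(features)
        logistic, converged, lnotes = logistic_table(features)
        notes.extend(lnotes)
    else:
        notes.append("one group absent; comparison stages skipped")
        descriptive = pd.DataFrame()
        logistic = pd.DataFrame()
        converged = False
    two_hour = two_hour_table(daily)
    return ReportBundle(
        features=features,
        daily=daily,
        descriptive=descriptive,
        comparisons=comparisons,
        logistic=logistic,
        logistic_converged=converged,
        two_hour=two_hour,
        warnings=notes,
    )


def analyze_cohort(cohort: CohortData, config: RunConfig | None = None) -> ReportBundle:
    """Run the full analysis on an in-memory synthetic cohort."""
    config = config or RunConfig()
    records = filter_cohort(cohort.records, config.min_age, config.max_age)
    notes: list[str] = []
    all_features: list[SubjectFeatures] = []
    all_summaries: list[DailySummary] = []
    groups: dict[str, str] = {}
    for rec in records:
        feats, summaries, subject_notes = summarize_subject(
            rec, cohort.series[rec.subject_id], config
        )
        all_features.extend(feats)
        all_summaries.extend(summaries)
        groups[rec.subject_id] = rec.group
        notes.extend(subject_notes)
    return analyze_features(all_features, all_summaries, groups, config, notes)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """File-based pipeline: read manifest and epoch CSVs, write reports."""
    if config.manifest is None or config.out_dir is None:
        raise ValueError("run_pipeline requires manifest and out_dir")
    manifest_path = Path(config.manifest)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    records = filter_cohort(read_manifest(manifest_path), config.min_age, config.max_age)
    notes: list[str] = []
    all_features: list[SubjectFeatures] = []
    all_summaries: list[DailySummary] = []
    groups: dict[str, str] = {}
    for rec in records:
        path = manifest_path.parent / (rec.file or f"{rec.subject_id}.csv")
        try:
            series = read_epoch_csv(
                path, DEFAULT_DIALECT, subject_id=rec.subject_id, group=rec.group
            )
            feats, summaries, subject_notes = summarize_subject(rec, series, config)
        except (OSError, ValueError) as exc:
            notes.append(f"{rec.subject_id}: skipped ({exc})")
            logger.warning("%s: skipped (%s)", rec.subject_id, exc)
            continue
        all_features.extend(feats)
        all_summaries.extend(summaries)
        groups[rec.subject_id] = rec.group
        notes.extend(subject_notes)
    if not all_features:
        raise ValueError("no subject could be processed")

    bundle = analyze_features(all_features, all_summaries, groups, config, notes)
    write_bundle(bundle, out_dir, config)
    return bundle


# ---------------------------------------------------------------------------
# output


def format_p(p: float) -> str:
    """Display form of a p-value: scientific below 1e-4 (e.g. 1.8E-04)."""
    if np.isnan(p):
        return "NA"
    if p != 0 and p < 1e-4:
        return f"{p:.1E}"
    return f"{p:.4f}"


def render_report(bundle: ReportBundle, precision: int = 2) -> str:
    """Human-readable rendering with display rounding."""
    lines: list[str] = []

    def _fmt(v: float) -> str:
        return "NA" if v is None or (isinstance(v, float) and np.isnan(v)) else f"{v:.{precision}f}"

    lines.append("Descriptive statistics (cpm), per-subject values pooled by group")
    for row in bundle.descriptive.itertuples(index=False):
        lines.append(
            f"  {row.statistic:<12} AI {_fmt(row.ai_mean)} ± {_fmt(row.ai_sd)}"
            f"   HC {_fmt(row.hc_mean)} ± {_fmt(row.hc_sd)}"
            f"   p(K-S) {format_p(row.ks_p)}"
        )
    for subset, table in bundle.comparisons.items():
        lines.append("")
        lines.append(f"Group comparison [{subset}] (minutes/day, 95% bounds)")
        for row in table.itertuples(index=False):
            lines.append(
                f"  {row.feature:<16}"
                f" AI {_fmt(row.ai_mean)} [{_fmt(row.ai_ci_lower)}, {_fmt(row.ai_ci_upper)}]"
                f"   HC {_fmt(row.hc_mean)} [{_fmt(row.hc_ci_lower)}, {_fmt(row.hc_ci_upper)}]"
                f"   D {_fmt(row.ks_D)}  p {format_p(row.ks_p)}"
            )
    if len(bundle.logistic):
        lines.append("")
        lines.append("Logistic regression (label 1 = healthy control)")
        for row in bundle.logistic.itertuples(index=False):
            lines.append(
                f"  {row.term:<16} beta {row.estimate:.3f}  SE {row.se:.3f}"
                f"  p {format_p(row.p)}"
            )
        if not bundle.logistic_converged:
            lines.append("  (fit flagged non-converged; see run log)")
    return "\n".join(lines) + "\n"


def write_bundle(bundle: ReportBundle, out_dir: Path, config: RunConfig) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_csv(bundle.features, out_dir / "features.csv")
    write_csv(bundle.daily, out_dir / "daily.csv")
    if len(bundle.descriptive):
        write_csv(bundle.descriptive, out_dir / "descriptive.csv")
    for subset, table in bundle.comparisons.items():
        write_csv(table, out_dir / f"comparison_{subset}.csv")
    if len(bundle.logistic):
        write_csv(bundle.logistic, out_dir / "logistic.csv")
    write_csv(bundle.two_hour, out_dir / "two_hour.csv")
    (out_dir / "report.txt").write_text(
        render_report(bundle, config.report_precision), encoding="utf-8"
    )
    log_lines = [
        f"sedbouts {sedbouts.__version__}; numpy {np.__version__}; "
        f"pandas {pd.__version__}",
        "config: "
        + "; ".join(
            f"{f.name}={getattr(config, f.name)}" for f in dataclasses.fields(config)
        ),
    ]
    log_lines += [f"warning: {w}" for w in bundle.warnings] or ["no warnings"]
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
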