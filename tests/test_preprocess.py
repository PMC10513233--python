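"""Moving-median imputation and daytime carving."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_series
from sedbouts.preprocess import (
    ImputationError,
    carve_daytime_days,
    impute_moving_median,
)


def brute_force_impute(counts, window):
    """Independent per-position oracle: median of observed neighbours in a
    centered, edge-truncated window; nearest observed value as fallback."""
    counts = np.asarray(counts, dtype=float)
    out = counts.copy()
    n = len(counts)
    observed = [i for i in range(n) if not np.isnan(counts[i])]
    for i in range(n):
        if not np.isnan(counts[i]):
            continue
        lo = max(0, i - window // 2)
        hi = min(n, i + (window - 1) // 2 + 1)
        neigh = [counts[j] for j in range(lo, hi) if not np.isnan(counts[j])]
        if neigh:
            out[i] = float(np.median(neigh))
        else:
            out[i] = counts[min(observed, key=lambda j: abs(j - i))]
    return out


class TestImputeMovingMedian:
    def test_constant_series(self):
        series = make_series([5, 5, None, 5, 5])
        assert list(impute_moving_median(series, 30).counts) == [5] * 5

    def test_hand_median_of_truncated_window(self):
        series = make_series([0, 10, None, 20, 100])
        result = impute_moving_median(series, 5)
        assert result.counts[2] == 15  # median of {0, 10, 20, 100}

    @pytest.mark.parametrize("window", [5, 30, 31])
    def test_matches_brute_force_oracle(self, window, rng):
        counts = rng.integers(0, 800, 2000).astype(float)
        counts[rng.random(2000) < 0.01] = np.nan
        series = make_series(counts)
        result = impute_moving_median(series, window)
        np.testing.assert_array_equal(result.counts, brute_force_impute(counts, window))
        assert not result.missing_mask.any()

    def test_noop_on_complete_series(self, rng):
        counts = rng.integers(0, 500, 100).astype(float)
        series = make_series(counts)
        np.testing.assert_array_equal(impute_moving_median(series).counts, counts)

    def test_isolated_gap_falls_back_to_nearest(self):
        # window 3 around index 3 contains only missing values
        series = make_series([7, 9, None, None, None, 4, 4])
        result = impute_moving_median(series, 3)
        assert result.counts[3] == 9  # nearest observed (tie broken earlier)

    def test_all_missing_rejected(self):
        with pytest.raises(ImputationError):
            impute_moving_median(make_series([None, None, None]))

    @given(
        missing=st.sets(st.integers(0, 59), max_size=20),
        window=st.integers(1, 40),
    )
    def test_observed_unchanged_and_fills_bounded(self, missing, window):
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 300, 60).astype(float)
        original = counts.copy()
        idx = sorted(missing)
        if len(idx) == 60:
            idx = idx[:-1]
        counts[idx] = np.nan
        result = impute_moving_median(make_series(counts), window)
        obs = ~np.isnan(counts)
        np.testing.assert_array_equal(result.counts[obs], original[obs])
        observed_vals = original[obs]
        assert np.all(result.counts >= observed_vals.min())
        assert np.all(result.counts <= observed_vals.max())


class TestCarveDaytimeDays:
    def test_seven_complete_days(self, rng):
        # Monday 2024-01-01 00:00 through Sunday 23:59
        counts = rng.integers(0, 500, 7 * 1440).astype(float)
        series = make_series(counts, start="2024-01-01 00:00")
        days = carve_daytime_days(series)
        assert len(days) == 7
        assert all(len(d.counts) == 840 for d in days)
        kinds = [d.day_type for d in days]
        assert kinds.count("weekday") == 5 and kinds.count("weekend") == 2
        # counts of day 1 start at the 08:00 offset
        np.testing.assert_array_equal(days[0].counts, counts[480:1320])

    def test_partial_first_day_dropped(self, rng):
        counts = rng.integers(0, 500, 3 * 1440).astype(float)
        series = make_series(counts, start="2024-01-01 09:00")
        days = carve_daytime_days(series)
        dates = [d.date.isoformat() for d in days]
        assert "2024-01-01" not in dates
        assert dates == ["2024-01-02", "2024-01-03"]

    def test_weekend_is_saturday_sunday(self, rng):
        counts = rng.integers(0, 500, 7 * 1440).astype(float)
        series = make_series(counts, start="2024-01-01 00:00")
        for day in carve_daytime_days(series):
            expected = "weekend" if day.date.isoweekday() >= 6 else "weekday"
            assert day.day_type == expected

    def test_requires_imputed_series(self):
        series = make_series([1, None, 3])
        with pytest.raises(ValueError, match="imputed"):
            carve_daytime_days(series)
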