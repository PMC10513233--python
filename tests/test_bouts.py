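"""Sedentary classification, bout extraction, binning and feature averaging."""

from datetime import date, timedelta

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sedbouts.bouts import (
    DEFAULT_BIN_SCHEME,
    BinScheme,
    Bout,
    average_features,
    bin_sedentary_time,
    classify_sedentary,
    extract_bouts,
    group_table,
    summarize_day,
)
from sedbouts.preprocess import DaytimeDay


def brute_force_bouts(mask):
    """Independent scanner oracle: test every index for a state change."""
    bouts = []
    start = 0
    for i in range(1, len(mask) + 1):
        if i == len(mask) or mask[i] != mask[i - 1]:
            bouts.append(
                Bout(
                    start_index=start,
                    duration=i - start,
                    state="sedentary" if mask[start] else "active",
                )
            )
            start = i
    return bouts


def _day(counts, day=date(2024, 1, 1)):
    return DaytimeDay(subject_id="s1", date=day, counts=np.asarray(counts, float))


class TestClassifySedentary:
    def test_strict_cut_point(self):
        out = classify_sedentary(np.array([0, 99, 100, 250]))
        assert list(out) == [True, True, False, False]

    def test_all_zero_day_is_sedentary(self):
        assert classify_sedentary(np.zeros(840)).all()

    def test_counts_at_threshold_are_active(self):
        assert not classify_sedentary(np.full(840, 100.0)).any()


class TestExtractBouts:
    def test_hand_rle(self):
        mask = np.array([1, 1, 1, 0, 1, 1], dtype=bool)
        assert extract_bouts(mask) == [
            Bout(0, 3, "sedentary"),
            Bout(3, 1, "active"),
            Bout(4, 2, "sedentary"),
        ]

    def test_all_sedentary_single_bout(self):
        assert extract_bouts(np.ones(840, bool)) == [Bout(0, 840, "sedentary")]

    def test_matches_brute_force_scanner(self, rng):
        for _ in range(200):
            mask = rng.random(840) < rng.uniform(0.2, 0.8)
            assert extract_bouts(mask) == brute_force_bouts(mask)

    @given(st.lists(st.booleans(), min_size=1, max_size=200))
    def test_durations_tile_the_day(self, bits):
        mask = np.array(bits, dtype=bool)
        bouts = extract_bouts(mask)
        assert sum(b.duration for b in bouts) == len(mask)
        assert bouts[0].start_index == 0
        for a, b in zip(bouts, bouts[1:]):
            assert b.start_index == a.start_index + a.duration
            assert b.state != a.state  # maximality


class TestBinSedentaryTime:
    def _sed(self, durations):
        pos, bouts = 0, []
        for d in durations:
            bouts.append(Bout(pos, d, "sedentary"))
            pos += d + 1
        return bouts

    def test_one_bout_per_bin(self):
        time, count = bin_sedentary_time(self._sed([2, 5, 10, 45, 120]))
        assert list(time) == [2, 5, 10, 45, 120]
        assert list(count) == [1, 1, 1, 1, 1]
        assert time.sum() == 182

    def test_inclusive_boundaries(self):
        time, count = bin_sedentary_time(self._sed([3, 4, 6, 30, 31, 60, 61]))
        assert list(time) == [3, 4, 36, 91, 61]
        assert list(count) == [1, 1, 2, 2, 1]

    def test_no_sedentary_bouts(self):
        time, count = bin_sedentary_time([Bout(0, 840, "active")])
        assert time.sum() == 0 and count.sum() == 0

    def test_bin_scheme_must_tile(self):
        with pytest.raises(ValueError):
            BinScheme(edges=((1, 3), (5, 10), (11, None)), labels=("a", "b", "c"))


class TestSummarizeDay:
    def test_constant_sedentary_day(self):
        s = summarize_day(_day(np.full(840, 50.0)))
        assert s.sed_total == 840 and s.wake_total == 0
        assert list(s.sed_bout_count) == [0, 0, 0, 0, 1]
        assert s.sed_bout_time[-1] == 840
        np.testing.assert_array_equal(s.two_hour_sed_time, np.full(7, 120.0))
        np.testing.assert_array_equal(s.two_hour_sed_mean, np.full(7, 50.0))
        assert np.isnan(s.two_hour_act_mean).all()

    def test_alternating_minutes(self):
        counts = np.tile([50.0, 150.0], 420)
        s = summarize_day(_day(counts))
        assert s.sed_total == 420 and s.wake_total == 420
        assert s.sed_bout_time[0] == 420 and s.sed_bout_count[0] == 420
        assert s.sed_bout_time[1:].sum() == 0

    def test_compositional_oracle(self, rng):
        counts = rng.integers(0, 400, 840).astype(float)
        s = summarize_day(_day(counts))
        mask = classify_sedentary(counts)
        time, count = bin_sedentary_time(extract_bouts(mask))
        np.testing.assert_array_equal(s.sed_bout_time, time)
        np.testing.assert_array_equal(s.sed_bout_count, count)
        assert s.sed_total == mask.sum()

    def test_threshold_monotonicity(self, rng):
        counts = rng.integers(0, 400, 840).astype(float)
        totals = [summarize_day(_day(counts), thr).sed_total for thr in (50, 100, 150)]
        assert totals == sorted(totals)

    def test_bin_time_bracketed_by_counts(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 200, 840).astype(float)
            s = summarize_day(_day(counts))
            for k, (lo, hi) in enumerate(DEFAULT_BIN_SCHEME.edges):
                assert s.sed_bout_count[k] * lo <= s.sed_bout_time[k]
                if hi is not None:
                    assert s.sed_bout_time[k] <= s.sed_bout_count[k] * hi


class TestAverageFeatures:
    def _week(self, rng, start=date(2024, 1, 1), n=7):
        days = [
            _day(rng.integers(0, 300, 840).astype(float), start + timedelta(d))
            for d in range(n)
        ]
        return days, [summarize_day(d) for d in days]

    def test_single_day_identity(self, rng):
        days, summaries = self._week(rng, n=1)
        f = average_features(summaries, days, "all7")
        np.testing.assert_array_equal(f.sed_bout_time, summaries[0].sed_bout_time)
        assert f.sed_total == summaries[0].sed_total

    def test_two_day_mean(self, rng):
        days, summaries = self._week(rng, n=2)
        f = average_features(summaries, days, "all7")
        assert f.sed_total == pytest.approx(
            (summaries[0].sed_total + summaries[1].sed_total) / 2
        )

    def test_weekday_subset_uses_five_days(self, rng):
        days, summaries = self._week(rng)  # Monday..Sunday
        assert average_features(summaries, days, "weekday").n_days == 5
        assert average_features(summaries, days, "weekend").n_days == 2

    def test_descriptive_stats_pool_epochs(self, rng):
        days, summaries = self._week(rng, n=3)
        f = average_features(summaries, days, "all7")
        pooled = np.concatenate([d.counts for d in days])
        assert f.count_mean == pytest.approx(pooled.mean())
        assert f.count_mean_sed == pytest.approx(pooled[pooled < 100].mean())
        assert f.count_mean_act == pytest.approx(pooled[pooled >= 100].mean())

    def test_empty_subset_rejected(self, rng):
        days, summaries = self._week(rng, n=2)  # Mon, Tue only
        with pytest.raises(ValueError, match="weekend"):
            average_features(summaries, days, "weekend")


class TestGroupTable:
    def test_single_subject_identity(self, rng):
        days, summaries = self._features(rng, 1)
        table = group_table(days, "HC")
        assert table["sed_total"] == days[0].sed_total

    def test_two_subject_mean(self, rng):
        feats, _ = None, None
        days, _ = self._features(rng, 2)
        table = group_table(days, "HC")
        assert table["sed_total"] == pytest.approx(
            (days[0].sed_total + days[1].sed_total) / 2
        )

    def _features(self, rng, n):
        feats = []
        for i in range(n):
            day = _day(rng.integers(0, 300, 840).astype(float))
            feats.append(
                average_features([summarize_day(day)], [day], "all7", group="HC")
            )
        return feats, None

    def test_heavier_long_bout_group_has_larger_gt60_mean(self, default_bundle):
        table = default_bundle.features
        sub = table[table["day_subset"] == "all7"]
        ai = sub.loc[sub["group"] == "AI", "sed_bouts_gt60"].mean()
        hc = sub.loc[sub["group"] == "HC", "sed_bouts_gt60"].mean()
        assert ai > hc
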