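import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import newtflow as nf
from newtflow.events import (
    annual_flow,
    day_counts_table,
    dry_season_qdiff,
    duration_histogram,
    seasonal_days_below,
)

from conftest import mk_series


class TestQdiff:
    def test_consecutive_differences(self):
        qd = nf.qdiff_series(mk_series([1, 3, 2, 10]))
        np.testing.assert_array_equal(qd.values, [2, -1, 8])
        assert qd.start == dt.date(2011, 1, 2)

    def test_constant_series_all_zero(self):
        np.testing.assert_array_equal(nf.qdiff_series(mk_series([4, 4, 4, 4])).values, 0.0)

    def test_missing_day_invalidates_both_neighbours(self):
        qd = nf.qdiff_series(mk_series([1, np.nan, 3, 4]))
        assert np.isnan(qd.values[0]) and np.isnan(qd.values[1])
        assert qd.values[2] == 1.0

    def test_gap_boundaries_reduce_count(self):
        """k observed runs leave n_obs - k valid differences."""
        values = np.concatenate([
            np.ones(10), [np.nan] * 3, np.ones(7), [np.nan], np.ones(5)])
        qd = nf.qdiff_series(mk_series(values))
        assert int(qd.mask.sum()) == 22 - 3  # 22 observed days in 3 runs

    def test_reversal_antisymmetry(self):
        v = np.array([1.0, 5.0, 2.0, 8.0, 3.0])
        fwd = nf.qdiff_series(mk_series(v)).values
        rev = nf.qdiff_series(mk_series(v[::-1])).values
        np.testing.assert_array_equal(rev, -fwd[::-1])

    def test_requires_ls_units(self):
        with pytest.raises(nf.UnitsError):
            nf.qdiff_series(mk_series([1, 2], units=nf.MM_PER_DAY))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            nf.qdiff_series(mk_series([1.0]))


class TestPercentileThreshold:
    def test_linear_interpolation_rule(self):
        assert nf.percentile_threshold(np.arange(1.0, 101.0), 0.99) == pytest.approx(99.01)

    def test_constant_values(self):
        assert nf.percentile_threshold(np.full(20, 7.0), 0.99) == 7.0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            nf.percentile_threshold(np.arange(5.0), 0.99)

    def test_dry_season_filter_uses_later_day(self):
        # series spanning the Mar 31 -> Apr 1 boundary
        q = mk_series([10, 20, 30, 40], start=dt.date(2014, 3, 30))
        qd = nf.qdiff_series(q)  # values on Mar 31, Apr 1, Apr 2
        dry = dry_season_qdiff(qd)
        np.testing.assert_array_equal(dry, [10, 10])  # Apr 1 and Apr 2 only


class TestCountsAndEvents:
    SPEC_VALUES = [0.5, 0.2, 0.1, 0.4, 0.3, 0.3]

    def test_days_below_strict(self):
        assert nf.count_days_below(mk_series(self.SPEC_VALUES), 0.33) == 4

    def test_all_above(self):
        assert nf.count_days_below(mk_series([1, 2, 3]), 0.33) == 0

    def test_threshold_tie_not_counted(self):
        assert nf.count_days_below(mk_series([0.33, 0.32]), 0.33) == 1

    def test_two_events_of_two_days(self):
        events = nf.events_below(mk_series(self.SPEC_VALUES), 0.33)
        assert [d for _, d in events] == [2, 2]
        assert events[0][0] == dt.date(2011, 1, 2)

    def test_all_below_single_event(self):
        events = nf.events_below(mk_series([0.1, 0.1, 0.1]), 0.33)
        assert events == [(dt.date(2011, 1, 1), 3)]

    def test_missing_day_breaks_run(self):
        events = nf.events_below(mk_series([0.1, np.nan, 0.1]), 0.33)
        assert [d for _, d in events] == [1, 1]

    @given(st.lists(
        st.one_of(st.none(), st.floats(0, 1, allow_nan=False)),
        min_size=1, max_size=60))
    @settings(max_examples=100, derandomize=True)
    def test_durations_partition_days_below(self, raw):
        values = np.array([np.nan if v is None else v for v in raw])
        q = mk_series(values)
        durations = [d for _, d in nf.events_below(q, 0.33)]
        assert sum(durations) == nf.count_days_below(q, 0.33)
        assert all(d >= 1 for d in durations)

    def test_single_day_events(self):
        qd = mk_series([100, 98, 50, 10], start=dt.date(2011, 1, 2))
        assert nf.count_single_day_events_above(qd, 97) == 2

    def test_no_exceedance(self):
        qd = mk_series([10, 20])
        assert nf.count_single_day_events_above(qd, 97) == 0

    def test_duration_histogram_bins(self):
        hist = duration_histogram([1, 3, 6, 7, 30, 31, 90, 91, 200])
        assert hist == {"<7": 3, "7-30": 2, "31-90": 2, ">90": 2}


class TestFlowDurationCurve:
    def test_weibull_positions(self):
        fdc = nf.flow_duration_curve(mk_series([1, 2, 3]))
        np.testing.assert_allclose(fdc["exceedance_percent"], [25, 50, 75])
        np.testing.assert_allclose(fdc["flow"], [3, 2, 1])

    def test_constant_series_horizontal(self):
        fdc = nf.flow_duration_curve(mk_series([5, 5, 5, 5]))
        assert fdc["flow"].nunique() == 1

    def test_permutation_invariant(self):
        rng = np.random.default_rng(5)
        v = rng.uniform(0, 10, 50)
        a = nf.flow_duration_curve(mk_series(v))
        b = nf.flow_duration_curve(mk_series(rng.permutation(v)))
        pd.testing.assert_frame_equal(a, b)

    def test_time_below_threshold_consistency(self):
        rng = np.random.default_rng(6)
        v = rng.uniform(0, 1, 500)
        q = mk_series(v)
        fdc = nf.flow_duration_curve(q)
        frac_curve = (fdc["flow"] < 0.33).mean()
        assert frac_curve == pytest.approx(nf.count_days_below(q, 0.33) / 500, abs=0.01)


class TestSeasonalAndAnnual:
    def test_seasonal_split(self):
        # Jan (winter) and Jul (summer) low-flow days
        n = 365
        v = np.ones(n)
        v[:10] = 0.1           # 10 January days
        v[181:186] = 0.1       # 5 July days
        counts = seasonal_days_below(mk_series(v, start=dt.date(2013, 1, 1)), 0.33)
        assert counts["winter"] == 10 and counts["summer"] == 5
        assert counts["spring"] == 0 and counts["autumn"] == 0

    def test_annual_flow_scaling(self):
        q = mk_series(np.full(730, 1.0), units=nf.MM_PER_DAY)
        assert annual_flow(q) == pytest.approx(365.25)


class TestThresholdRobustness:
    def table(self, columns):
        return pd.DataFrame(columns, index=[f"s{i}" for i in range(3)])

    def test_identical_vectors(self):
        t = self.table({0.33: [1, 2, 3], 2.0: [1, 2, 3]})
        r = nf.threshold_robustness(t, alternative_thresholds=(2.0,))
        assert r[2.0] == pytest.approx(1.0)

    def test_scale_invariance(self):
        t = self.table({0.33: [1, 2, 3], 1.0: [2, 4, 6]})
        r = nf.threshold_robustness(t, alternative_thresholds=(1.0,))
        assert r[1.0] == pytest.approx(1.0)

    def test_anti_ordered(self):
        t = self.table({0.33: [1, 2, 3], 0.2: [3, 2, 1]})
        r = nf.threshold_robustness(t, alternative_thresholds=(0.2,))
        assert r[0.2] == pytest.approx(-1.0)

    def test_constant_vector_undefined(self):
        t = self.table({0.33: [1, 2, 3], 0.5: [4, 4, 4]})
        r = nf.threshold_robustness(t, alternative_thresholds=(0.5,))
        assert np.isnan(r[0.5])

    def test_day_counts_monotone_in_threshold(self, truth_run):
        """A larger Q_low can only admit more below-threshold days."""
        obs, _ = truth_run
        q_ls = nf.convert_flow_series(obs, nf.LITRES_PER_SECOND, 2.0)
        thresholds = (2.0, 1.0, 0.5, 0.33, 0.25, 0.2)
        table = day_counts_table({"obs": q_ls}, thresholds)
        counts = table.loc["obs", list(thresholds)].to_numpy()
        assert (np.diff(counts) <= 0).all()


class TestBestLag:
    def test_exact_one_day_shift(self):
        rng = np.random.default_rng(1)
        p = rng.gamma(0.7, 8, 300) * (rng.uniform(size=300) < 0.3)
        q = np.roll(p, 1)
        q[0] = 0
        ps = mk_series(p, units=nf.MM)
        qs = mk_series(q)
        assert nf.best_lag(ps, qs, max_lag=5) == 1

    def test_zero_lag(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0, 10, 200)
        assert nf.best_lag(mk_series(p, units=nf.MM), mk_series(p), max_lag=5) == 0

    def test_noisy_shift_recovers_one_day(self):
        """Q = 0.7 P(t-1) + 10% noise finds lag 1 for nearly every seed."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            p = rng.gamma(0.7, 8, 400) * (rng.uniform(size=400) < 0.35)
            q = 0.7 * np.roll(p, 1) + rng.normal(0, 0.1 * max(p.mean(), 1), 400)
            q[0] = 0
            q = np.clip(q, 0, None)
            if nf.best_lag(mk_series(p, units=nf.MM), mk_series(q), max_lag=5) == 1:
                hits += 1
        assert hits >= 19

    def test_missing_days_handled_pairwise(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0, 10, 100)
        q = np.roll(p, 1)
        q[0] = 0
        q[40:60] = np.nan
        assert nf.best_lag(mk_series(p, units=nf.MM), mk_series(q), max_lag=3) == 1
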