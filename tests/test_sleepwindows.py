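"""Sleep-anchored window pooling and the pre-bed/bed/rise comparisons."""

import numpy as np
import pytest
from scipy import stats

from chronotap import EventStream, compare_windows, pool_window_params, segment_windows
from chronotap.sleepwindows import WINDOWS, weekday_weekend_split
from chronotap.types import SleepPeriod, WindowSample

DAY = 86400.0
H = 3600.0


def night(j, onset_h=23.0, offset_h=7.0, subject="s"):
    on = j * DAY + onset_h * H
    off = j * DAY + (offset_h + 24.0) * H if offset_h < onset_h else j * DAY + offset_h * H
    from chronotap.types import weekday

    return SleepPeriod(subject, on, off, j, int(weekday(on)))


class TestSegment:
    def test_standard_night(self):
        iv = segment_windows([night(0)], 3600.0, 3600.0)
        by = {i.window: i for i in iv}
        assert by["pre_bed"].t0 == 22 * H and by["pre_bed"].t1 == 23 * H
        assert by["bed"].t0 == 23 * H and by["bed"].t1 == 31 * H
        assert by["rise"].t0 == 31 * H and by["rise"].t1 == 32 * H

    def test_custom_pre_len(self):
        iv = segment_windows([night(0)], pre_len=1800.0)
        pre = next(i for i in iv if i.window == "pre_bed")
        assert pre.t0 == 22.5 * H and pre.t1 == 23 * H

    def test_many_nights_no_overlap(self):
        periods = [night(j) for j in range(100)]
        iv = segment_windows(periods)
        assert len(iv) == 300
        spans = sorted((i.t0, i.t1) for i in iv)
        assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))

    def test_overlapping_nights_error(self):
        a = SleepPeriod("s", 0.0, 10 * H, 0, 0)
        b = SleepPeriod("s", 8 * H, 18 * H, 1, 0)
        with pytest.raises(ValueError, match="overlapping"):
            segment_windows([a, b])


def touches_at(times):
    ev = sorted((float(t), "touch") for t in times)
    return np.array([e[0] for e in ev]), np.array([e[1] for e in ev], dtype=object)


def stream_with_bursts(burst_starts, interval_s=0.2, k=5, subject="s"):
    """k-touch bursts at given start times (intervals well under max_gap)."""
    times = []
    for t0 in burst_starts:
        times.extend(t0 + interval_s * np.arange(k))
    t, kind = touches_at(times)
    return EventStream(subject, t, kind)


class TestPooling:
    def test_no_in_bed_touches_excluded(self):
        periods = [night(j) for j in range(5)]
        iv = segment_windows(periods)
        # bursts only pre-bed and rise
        starts = [p.onset - 1800 for p in periods] + [p.offset + 1800 for p in periods]
        stream = stream_with_bursts(starts)
        pooled = pool_window_params(stream, iv, min_episodes=3)
        assert pooled == {}

    def test_ts_pooled_quartile(self):
        periods = [night(j) for j in range(5)]
        iv = segment_windows(periods)
        starts = ([p.onset - 1800 for p in periods]
                  + [p.onset + 4 * H for p in periods]
                  + [p.offset + 1800 for p in periods])
        stream = stream_with_bursts(starts, interval_s=0.2)
        pooled = pool_window_params(stream, iv, min_episodes=3)
        assert "TS" in pooled
        for w in WINDOWS:
            assert pooled["TS"][w].value_ms == pytest.approx(200.0)
            assert pooled["TS"][w].n_episodes == 5 * 4

    def test_episode_in_exactly_one_window(self):
        """No observation is double-counted across window types."""
        periods = [night(j) for j in range(10)]
        iv = segment_windows(periods)
        rng = np.random.default_rng(0)
        starts = rng.uniform(0, 10 * DAY, 300)
        stream = stream_with_bursts(starts, k=3)
        pooled = pool_window_params(stream, iv, min_episodes=1)
        if "TS" in pooled:
            total = sum(pooled["TS"][w].n_episodes for w in WINDOWS)
            from chronotap.tappigraphy import inter_touch_observations
            from chronotap.sleepwindows import _assign

            obs = inter_touch_observations(stream, 30.0)
            t = np.array([o.t for o in obs])
            lab = _assign(t, iv)
            assert total == (lab != "").sum()

    def test_exclusion_monotone_in_min_episodes(self):
        periods = [night(j) for j in range(5)]
        iv = segment_windows(periods)
        starts = ([p.onset - 1800 for p in periods[:2]]
                  + [p.onset + 4 * H for p in periods]
                  + [p.offset + 1800 for p in periods])
        stream = stream_with_bursts(starts)
        lo = pool_window_params(stream, iv, min_episodes=1)
        hi = pool_window_params(stream, iv, min_episodes=20)
        assert set(hi) <= set(lo)


def samples_from_matrix(mat):
    """n x 3 value matrix -> list of per-subject window dicts (US)."""
    out = []
    for i, row in enumerate(mat):
        out.append({
            w: WindowSample(f"s{i}", "US", w, float(v), 10)
            for w, v in zip(WINDOWS, row)
        })
    return out


class TestCompare:
    def test_identical_windows(self):
        mat = np.tile([[1000.0, 1000.0, 1000.0]], (6, 1))
        rec = compare_windows(samples_from_matrix(mat), "US")
        assert rec.f == 0.0 and all(p.t == 0.0 for p in rec.paired)

    def test_paired_t_matches_scipy_oracle(self):
        rng = np.random.default_rng(2)
        pre = 2000 + rng.normal(0, 100, 5)
        bed = pre + 300 + rng.normal(0, 50, 5)
        rise = pre + rng.normal(0, 50, 5)
        mat = np.column_stack([pre, bed, rise])
        rec = compare_windows(samples_from_matrix(mat), "US")
        t_oracle = stats.ttest_rel(bed, pre)
        bed_pre = next(p for p in rec.paired if p.contrast == "bed_vs_pre_bed")
        assert bed_pre.t == pytest.approx(float(t_oracle.statistic), abs=1e-10)
        assert bed_pre.p == pytest.approx(float(t_oracle.pvalue), abs=1e-12)
        assert bed_pre.df == 4

    def test_rm_anova_identity_two_windows_subset(self):
        # with a real effect the ANOVA must reject
        rng = np.random.default_rng(3)
        pre = 2000 + rng.normal(0, 100, 12)
        mat = np.column_stack([pre, pre * 1.3 + rng.normal(0, 30, 12),
                               pre + rng.normal(0, 30, 12)])
        rec = compare_windows(samples_from_matrix(mat), "US")
        assert rec.p < 0.001
        assert rec.df1 == 2 and rec.df2 == 22

    def test_needs_three_subjects(self):
        mat = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="3 complete-case"):
            compare_windows(samples_from_matrix(mat), "US")


class TestSplit:
    def _cohort(self, bed_factor_weekend, bed_factor_weekday, n=6):
        """Bursty streams with a controllable bed-window slowing per subset."""
        streams, periods = [], []
        rng = np.random.default_rng(4)
        for s in range(n):
            # epoch day 0 is a Thursday; 21 nights cover all weekdays
            nights = [night(j, subject=f"s{s}") for j in range(21)]
            times = []
            kinds = []
            for p in nights:
                factor = (bed_factor_weekend
                          if p.onset_weekday in (4, 5, 6) else bed_factor_weekday)
                for t0 in (p.onset - 1800, p.offset + 1800):
                    base = 0.2 * (1 + 0.05 * rng.random())
                    for k in range(5):
                        times.append(t0 + k * base)
                for t0 in (p.onset + 3 * H, p.onset + 5 * H):
                    base = 0.2 * factor * (1 + 0.05 * rng.random())
                    for k in range(5):
                        times.append(t0 + k * base)
            t, kind = touches_at(times)
            streams.append(EventStream(f"s{s}", t, kind))
            periods.append(nights)
        return streams, periods

    def test_concordant_when_same_penalty(self):
        streams, periods = self._cohort(1.3, 1.3)
        res = weekday_weekend_split(streams, periods, "TS")
        assert res.concordant

    def test_discordant_when_sign_flipped(self):
        streams, periods = self._cohort(0.7, 1.3)
        res = weekday_weekend_split(streams, periods, "TS")
        assert not res.concordant

    def test_all_weekday_nights_error(self):
        streams, periods = self._cohort(1.3, 1.3)
        weekday_only = [[p for p in ps if p.onset_weekday < 4] for ps in periods]
        with pytest.raises(ValueError, match="weekend"):
            weekday_weekend_split(streams, weekday_only, "TS")
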