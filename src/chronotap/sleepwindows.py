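"""Cognitive performance around actigraphy-scored sleep.

Latency episodes are pooled into three window types per night — pre_bed
(the hour before sleep onset), bed (the scored sleep period itself) and
rise (the hour after offset) — then summarized per subject and compared
with a repeated-measures ANOVA plus paired t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tappigraphy import episode_observations, inter_touch_observations
from .types import EventStream, SleepPeriod, WindowSample

__all__ = [
    "segment_windows",
    "LabeledInterval",
    "pool_window_params",
    "compare_windows",
    "WindowComparison",
    "PairedT",
    "weekday_weekend_split",
    "SplitResult",
]

WINDOWS = ("pre_bed", "bed", "rise")
WEEKEND_ONSET = (4, 5, 6)  # Friday, Saturday, Sunday


@dataclass(frozen=True)
class LabeledInterval:
    t0: float
    t1: float
    window: str
    night_index: int
    onset_weekday: int


def segment_windows(
    periods: list[SleepPeriod],
    pre_len: float = 3600.0,
    post_len: float = 3600.0,
) -> list[LabeledInterval]:
    """Per night: pre_bed [onset-pre, onset), bed [onset, offset), rise [offset, offset+post)."""
    ordered = sorted(periods, key=lambda p: p.onset)
    for a, b in zip(ordered, ordered[1:]):
        if b.onset < a.offset:
            raise ValueError(
                f"overlapping sleep periods: night {a.night_index} and {b.night_index}"
            )
    out: list[LabeledInterval] = []
    for p in ordered:
        for t0, t1, w in (
            (p.onset - pre_len, p.onset, "pre_bed"),
            (p.onset, p.offset, "bed"),
            (p.offset, p.offset + post_len, "rise"),
        ):
            out.append(LabeledInterval(t0, t1, w, p.night_index, p.onset_weekday))
    return out


def _assign(times: np.ndarray, intervals: list[LabeledInterval]) -> np.ndarray:
    """Window label per time ('' when outside all intervals).

    Interval starts are half-open [t0, t1); bed takes precedence at the
    shared onset/offset instants by construction of the half-open edges.
    """
    labels = np.full(times.size, "", dtype=object)
    for iv in intervals:
        m = (times >= iv.t0) & (times < iv.t1)
        labels[m] = iv.window
    return labels


def pool_window_params(
    stream: EventStream,
    intervals: list[LabeledInterval],
    min_episodes: int = 3,
    max_gap: float = 30.0,
    max_episode_s: float = 60.0,
    ts_statistic: str = "p25",
) -> dict[str, dict[str, WindowSample]]:
    """Pooled per-subject latency summaries by parameter and window.

    For US and ALS the summary is the median of all episode latencies
    completing inside any interval of a window type, pooled over the whole
    recording. For TS the pooled inter-touch intervals get the fastest 25th
    percentile (``ts_statistic="p25"``; "median" switches to the pooled
    median). A parameter is reported only when *all three* windows reach
    ``min_episodes`` (complete case).
    """
    if ts_statistic not in ("p25", "median"):
        raise ValueError("ts_statistic must be 'p25' or 'median'")
    pools: dict[str, dict[str, list[float]]] = {
        p: {w: [] for w in WINDOWS} for p in ("TS", "US", "ALS")
    }
    sources = {
        "TS": inter_touch_observations(stream, max_gap),
        "US": episode_observations(
            stream, "screen_on", "unlock_complete", "unlock", max_episode_s
        ).observations,
        "ALS": episode_observations(
            stream, "home_shown", "app_launch", "app_locate", max_episode_s
        ).observations,
    }
    for param, obs in sources.items():
        if not obs:
            continue
        t = np.array([o.t for o in obs])
        v = np.array([o.value_ms for o in obs])
        lab = _assign(t, intervals)
        for w in WINDOWS:
            pools[param][w] = list(v[lab == w])

    out: dict[str, dict[str, WindowSample]] = {}
    for param, by_window in pools.items():
        if any(len(by_window[w]) < min_episodes for w in WINDOWS):
            continue  # complete-case: subject excluded for this parameter
        summaries = {}
        for w in WINDOWS:
            vals = np.array(by_window[w])
            if param == "TS" and ts_statistic == "p25":
                val = float(np.percentile(vals, 25.0))
            else:
                val = float(np.median(vals))
            summaries[w] = WindowSample(stream.subject_id, param, w, val, vals.size)
        out[param] = summaries
    return out


@dataclass(frozen=True)
class PairedT:
    contrast: str
    mean_a: float
    mean_b: float
    t: float
    df: int
    p: float


@dataclass
class WindowComparison:
    parameter: str
    n_subjects: int
    means: dict[str, float]
    f: float
    df1: int
    df2: int
    p: float
    paired: list[PairedT]


def compare_windows(
    samples: list[dict[str, WindowSample]], parameter: str
) -> WindowComparison:
    """Repeated-measures ANOVA over pre_bed/bed/rise plus paired follow-ups.

    ``samples`` is a list of per-subject window dicts for one parameter
    (complete cases only). Follow-up paired t-tests: bed vs pre_bed, bed vs
    rise, pre_bed vs rise.
    """
    from statsmodels.stats.anova import AnovaRM

    mat = np.array(
        [[s[w].value_ms for w in WINDOWS] for s in samples], dtype=float
    )
    n = mat.shape[0]
    if n < 3:
        raise ValueError("need at least 3 complete-case subjects")
    means = {w: float(mat[:, i].mean()) for i, w in enumerate(WINDOWS)}
    within_var = mat.var(axis=0).sum()
    if np.allclose(mat, mat[:, [0]]):
        f, p, df1, df2 = 0.0, 1.0, 2, 2 * (n - 1)
    else:
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), 3),
                "window": np.tile(WINDOWS, n),
                "v": mat.ravel(),
            }
        )
        res = AnovaRM(long, depvar="v", subject="subject", within=["window"]).fit()
        row = res.anova_table.iloc[0]
        f, p = float(row["F Value"]), float(row["Pr > F"])
        df1, df2 = int(row["Num DF"]), int(row["Den DF"])

    paired = []
    idx = {w: i for i, w in enumerate(WINDOWS)}
    for a, b in (("bed", "pre_bed"), ("bed", "rise"), ("pre_bed", "rise")):
        xa, xb = mat[:, idx[a]], mat[:, idx[b]]
        if np.allclose(xa, xb):
            t, pv = 0.0, 1.0
        else:
            res_t = stats.ttest_rel(xa, xb)
            t, pv = float(res_t.statistic), float(res_t.pvalue)
        paired.append(
            PairedT(f"{a}_vs_{b}", float(xa.mean()), float(xb.mean()), t, n - 1, pv)
        )
    return WindowComparison(parameter, n, means, f, df1, df2, p, paired)


@dataclass
class SplitResult:
    weekend: WindowComparison
    weekday: WindowComparison
    concordant: bool


def weekday_weekend_split(
    streams: list[EventStream],
    periods_by_subject: list[list[SleepPeriod]],
    parameter: str,
    pre_len: float = 3600.0,
    post_len: float = 3600.0,
    min_episodes: int = 3,
    max_gap: float = 30.0,
    max_episode_s: float = 60.0,
) -> SplitResult:
    """Run the window comparison separately for weekend- and weekday-onset nights.

    Weekend nights are those whose sleep onset falls on Friday, Saturday or
    Sunday. The two comparisons are flagged concordant when the sign
    pattern of the three paired contrasts matches.
    """
    results = {}
    for name, days in (("weekend", WEEKEND_ONSET), ("weekday", (0, 1, 2, 3))):
        samples = []
        for stream, periods in zip(streams, periods_by_subject):
            subset = [p for p in periods if p.onset_weekday in days]
            if not subset:
                continue
            intervals = segment_windows(subset, pre_len, post_len)
            pooled = pool_window_params(
                stream, intervals, min_episodes, max_gap, max_episode_s
            )
            if parameter in pooled:
                samples.append(pooled[parameter])
        if len(samples) < 3:
            raise ValueError(f"insufficient {name} data for {parameter}")
        results[name] = compare_windows(samples, parameter)
    signs = [
        tuple(np.sign(pt.mean_a - pt.mean_b) for pt in results[k].paired)
        for k in ("weekend", "weekday")
    ]
    return SplitResult(results["weekend"], results["weekday"], signs[0] == signs[1])
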