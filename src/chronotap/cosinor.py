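"""Fixed-period cosinor fitting and time-of-day / day-of-week analyses.

The cosinor model is ``x(t) = M + beta cos(wt) + gamma sin(wt)`` with
``w = 2*pi/period``; amplitude ``A = sqrt(beta^2 + gamma^2)`` and acrophase
the local clock time at which the fitted curve peaks. Latency parameters
(TS, US, ALS) are negated before fitting so their acrophase is the time of
*fastest* performance. The zero-amplitude test is the F-test of the joint
null beta = gamma = 0 with (2, n-3) degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .circular import hours_to_angle
from .types import (
    SECONDS_PER_DAY,
    SECONDS_PER_HOUR,
    BinnedSeries,
    CosinorFit,
    weekday,
)

__all__ = [
    "fit_cosinor",
    "acrophase_sample",
    "AngleSample",
    "peak_vs_offpeak",
    "model_free_peak",
    "day_of_week_analysis",
    "DayOfWeekResult",
]


def fit_cosinor(
    series: BinnedSeries,
    period_h: float = 24.0,
    orientation: str | None = None,
) -> CosinorFit:
    """Least-squares fixed-period cosinor fit of one binned series.

    ``orientation`` is "amplitude" (peak = largest values) or "latency"
    (series negated, peak = fastest); by default latency parameters get the
    latency orientation. The acrophase is reported as local clock time in
    [0, period) hours.
    """
    if orientation is None:
        orientation = "latency" if series.is_latency else "amplitude"
    if orientation not in ("amplitude", "latency"):
        raise ValueError("orientation must be 'amplitude' or 'latency'")
    t, y = series.nonmissing()
    if t.size < 4:
        raise ValueError("cosinor needs at least 4 non-missing bins")
    if t[-1] - t[0] <= period_h * SECONDS_PER_HOUR:
        raise ValueError("cosinor needs data spanning more than one period")
    if orientation == "latency":
        y = -y
    w = 2.0 * np.pi / (period_h * SECONDS_PER_HOUR)
    X = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 3:
        raise ValueError("under-determined cosinor fit (degenerate sampling)")
    M, beta, gamma = coef
    A = float(np.hypot(beta, gamma))
    resid = y - X @ coef
    sse = float(resid @ resid)
    yc = y - y.mean()
    sst = float(yc @ yc)
    ssr = max(sst - sse, 0.0)
    n = t.size
    if sst <= 0 or ssr <= 1e-12 * max(sst, 1.0):
        p = 1.0
    elif sse <= 1e-12 * sst:
        p = 0.0
    else:
        f = (ssr / 2.0) / (sse / (n - 3))
        p = float(stats.f.sf(f, 2, n - 3))
    # peak of the fitted cosine in absolute time, then onto the local clock
    t_peak = np.arctan2(gamma, beta) / w  # seconds, mod period
    period_s = period_h * SECONDS_PER_HOUR
    acro_h = ((t_peak + series.utc_offset_s) % period_s) / SECONDS_PER_HOUR
    return CosinorFit(
        subject_id=series.subject_id,
        parameter=series.parameter,
        period_h=period_h,
        mesor=float(M) if orientation == "amplitude" else float(-M),
        amplitude=A,
        acrophase_h=float(acro_h),
        p_zero_amplitude=p,
        n_obs=n,
    )


@dataclass
class AngleSample:
    """Per-subject acrophases (radians) for one parameter, after screening."""

    parameter: str
    angles: np.ndarray
    subject_ids: list[str]
    excluded_fraction: float


def acrophase_sample(fits: list[CosinorFit], alpha: float = 0.05) -> AngleSample:
    """Keep subjects whose zero-amplitude test passes at ``alpha``.

    The excluded fraction is reported: it is the share of the cohort in
    which no 24-h rhythm was detectable for this parameter.
    """
    if not fits:
        raise ValueError("no fits supplied")
    params = {f.parameter for f in fits}
    if len(params) != 1:
        raise ValueError("acrophase sample must come from a single parameter")
    kept = [f for f in fits if f.p_zero_amplitude < alpha]
    excluded = 1.0 - len(kept) / len(fits)
    if not kept:
        raise ValueError("all subjects excluded: no significant rhythms")
    period = kept[0].period_h
    return AngleSample(
        parameter=kept[0].parameter,
        angles=hours_to_angle(np.array([f.acrophase_h for f in kept]), period),
        subject_ids=[f.subject_id for f in kept],
        excluded_fraction=excluded,
    )


def peak_vs_offpeak(series: BinnedSeries, fit: CosinorFit) -> tuple[float, float]:
    """Mean raw value in the acrophase clock-hour bin vs the bathyphase bin.

    Uses the 1-h clock bin containing each phase, pooled over all recorded
    days. Returns (peak_mean, offpeak_mean) on the raw scale; for latency
    parameters the peak is the *fast* phase, so peak_mean < offpeak_mean
    when the rhythm is real.
    """
    hours = np.floor(series.clock_hours()).astype(int)
    peak_bin = int(np.floor(fit.acrophase_h)) % 24
    off_bin = int(np.floor(fit.bathyphase_h)) % 24
    vals = series.values
    pk = vals[(hours == peak_bin) & ~np.isnan(vals)]
    off = vals[(hours == off_bin) & ~np.isnan(vals)]
    if pk.size == 0 or off.size == 0:
        raise ValueError("empty acrophase or bathyphase clock bin")
    return float(pk.mean()), float(off.mean())


def model_free_peak(series: BinnedSeries, orientation: str | None = None) -> int:
    """Clock hour whose across-day mean is maximal (minimal for latency).

    A sinusoid-free peak estimate; returns the hour-of-day bin as an int in
    0..23. Ties break toward the earliest hour.
    """
    if orientation is None:
        orientation = "latency" if series.is_latency else "amplitude"
    if series.span_s() < SECONDS_PER_DAY:
        raise ValueError("need at least one full day")
    hours = np.floor(series.clock_hours()).astype(int)
    means = np.full(24, np.nan)
    for h in range(24):
        sel = series.values[(hours == h) & ~np.isnan(series.values)]
        if sel.size:
            means[h] = sel.mean()
    if np.all(np.isnan(means)):
        raise ValueError("all bins missing")
    if orientation == "latency":
        return int(np.nanargmin(means))
    return int(np.nanargmax(means))


@dataclass
class DayOfWeekResult:
    parameter: str
    day_means: np.ndarray     # Monday..Sunday mean of daily values
    f: float
    df1: int
    df2: int
    p: float
    peak_day: int             # Monday=0
    peak_angle: float         # 2*pi*day/7


def day_of_week_analysis(series: BinnedSeries, orientation: str | None = None) -> DayOfWeekResult:
    """Weekly structure of one subject's series.

    Daily means are computed per calendar day, then a one-way
    repeated-measures ANOVA across the 7 weekdays (weeks as the repeated
    unit; only complete weeks enter) tests for systematic day-of-week
    variance. The peak day (max mean, or min for latency parameters) is
    returned as an angle 2*pi*d/7 for cross-parameter circular comparison.
    """
    from statsmodels.stats.anova import AnovaRM

    if orientation is None:
        orientation = "latency" if series.is_latency else "amplitude"
    days = np.floor((series.t_start + series.utc_offset_s) / SECONDS_PER_DAY).astype(int)
    wdays = weekday(series.t_start, series.utc_offset_s)
    df = pd.DataFrame({"day": days, "wd": wdays, "v": series.values}).dropna()
    daily = df.groupby(["day", "wd"], as_index=False)["v"].mean()
    daily["week"] = (daily["day"] - daily["day"].min()) // 7
    # keep only weeks with all 7 weekdays observed
    complete = daily.groupby("week")["wd"].transform("nunique") == 7
    daily = daily[complete]
    if daily["week"].nunique() < 2:
        raise ValueError("need at least 2 complete weeks")
    day_means = (
        daily.groupby("wd")["v"].mean().reindex(range(7)).to_numpy(dtype=float)
    )
    if np.allclose(daily.groupby("week")["v"].transform("mean"), daily["v"]):
        # identical days within every week: no weekday effect by construction
        f, p = 0.0, 1.0
        df1 = 6
        df2 = 6 * (daily["week"].nunique() - 1)
    else:
        res = AnovaRM(daily, depvar="v", subject="week", within=["wd"]).fit()
        row = res.anova_table.iloc[0]
        f, p = float(row["F Value"]), float(row["Pr > F"])
        df1, df2 = int(row["Num DF"]), int(row["Den DF"])
    peak_day = int(np.nanargmin(day_means) if orientation == "latency"
                   else np.nanargmax(day_means))
    return DayOfWeekResult(
        parameter=series.parameter,
        day_means=day_means,
        f=f, df1=df1, df2=df2, p=p,
        peak_day=peak_day,
        peak_angle=float(2.0 * np.pi * peak_day / 7.0),
    )
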