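"""End-to-end orchestration: raw streams -> binned parameters -> rhythm,
cosinor and sleep-window results for a whole cohort.

These helpers exist so scripts, examples and the CLI all run the same code
path; each step is a thin composition of the stage modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import actigraphy, cosinor, rhythms, sleepwindows, tappigraphy
from .config import AnalysisConfig
from .types import BinnedSeries, EventStream, Periodogram, WearableSeries

__all__ = [
    "wearable_series",
    "subject_parameters",
    "cohort_parameters",
    "cohort_periodograms",
    "rhythm_summary",
    "cosinor_summary",
    "sleep_window_analysis",
]


def wearable_series(
    wearable: WearableSeries, cfg: AnalysisConfig | None = None
) -> dict[str, BinnedSeries]:
    """Bin a wearable trace into activity (summed counts) and lux (mean) series."""
    cfg = cfg or AnalysisConfig()
    counts = actigraphy.accel_to_counts(wearable, cfg.ck_epoch_s)
    width = cfg.bin_width_s
    t0 = np.floor(counts.t_start[0] / width) * width
    idx = np.floor((counts.t_start - t0) / width).astype(np.int64)
    n = int(idx.max()) + 1
    starts = t0 + width * np.arange(n)
    act = np.bincount(idx, weights=np.nan_to_num(counts.counts), minlength=n)

    lx_t = wearable.t_start
    lx_idx = np.floor((lx_t - t0) / width).astype(np.int64)
    good = ~np.isnan(wearable.lux) & (lx_idx >= 0) & (lx_idx < n)
    nsamp = np.bincount(lx_idx[good], minlength=n).astype(float)
    with np.errstate(invalid="ignore"):
        lux = np.bincount(lx_idx[good], weights=wearable.lux[good], minlength=n) / nsamp
    lux = np.where(nsamp == 0, 0.0, lux)
    mk = lambda p, v: BinnedSeries(wearable.subject_id, p, width, starts, v,
                                   wearable.utc_offset_s)
    return {"activity": mk("activity", act), "lux": mk("lux", lux)}


def subject_parameters(
    stream: EventStream,
    wearable: WearableSeries | None = None,
    cfg: AnalysisConfig | None = None,
) -> dict[str, BinnedSeries]:
    """All six analysis parameters for one subject."""
    cfg = cfg or AnalysisConfig()
    out = tappigraphy.extract_all(stream, cfg)
    if wearable is not None:
        out.update(wearable_series(wearable, cfg))
    return out


def cohort_parameters(
    cohort: list[tuple[EventStream, WearableSeries]],
    cfg: AnalysisConfig | None = None,
) -> list[dict[str, BinnedSeries]]:
    return [subject_parameters(s, w, cfg) for s, w in cohort]


def cohort_periodograms(
    per_subject: list[dict[str, BinnedSeries]],
    cfg: AnalysisConfig | None = None,
) -> dict[str, list[Periodogram]]:
    """Per-parameter Lomb-Scargle periodograms on one common grid.

    The grid spans [min_period, record_length/2] of the shortest recording so
    every subject shares it.
    """
    cfg = cfg or AnalysisConfig()
    span_h = min(
        series.span_s() / 3600.0
        for d in per_subject
        for series in d.values()
    )
    grid = rhythms.period_grid(span_h, cfg.min_period_h, cfg.oversampling)
    params = sorted({p for d in per_subject for p in d}, key=str)
    out: dict[str, list[Periodogram]] = {p: [] for p in params}
    for d in per_subject:
        for p, series in d.items():
            t, v = series.nonmissing()
            if t.size < 2 or np.allclose(v, v[0] if v.size else 0):
                continue  # constant or empty series has no spectrum
            out[p].append(rhythms.lomb_scargle(series, grid))
    return out


@dataclass
class RhythmSummary:
    parameter: str
    n_subjects: int
    mean_diurnal_peak_h: float
    mean_diurnal_power: float
    vs24: rhythms.TestRecord
    population: rhythms.PopulationPeriodogram
    infradian_significant: bool
    mean_infradian_peak_h: float


def rhythm_summary(
    periodograms: dict[str, list[Periodogram]],
    cfg: AnalysisConfig | None = None,
) -> dict[str, RhythmSummary]:
    """Cohort spectral statistics per parameter: diurnal peaks, tests, FDR mask."""
    cfg = cfg or AnalysisConfig()
    out = {}
    for param, pgs in periodograms.items():
        if len(pgs) < 3:
            continue
        peaks = [rhythms.peak_in_band(pg, cfg.diurnal_band_h) for pg in pgs]
        periods = np.array([p.peak_period_h for p in peaks])
        powers = np.array([p.peak_power for p in peaks])
        pop = rhythms.population_periodogram(pgs, cfg.fdr_q)
        lo, hi = cfg.infradian_band_h
        band = (pop.periods_h >= lo) & (pop.periods_h <= hi)
        infr_peaks = [rhythms.peak_in_band(pg, cfg.infradian_band_h) for pg in pgs] \
            if band.any() else []
        out[param] = RhythmSummary(
            parameter=param,
            n_subjects=len(pgs),
            mean_diurnal_peak_h=float(periods.mean()),
            mean_diurnal_power=float(powers.mean()),
            vs24=rhythms.test_peaks_vs_24(periods, param, cfg.alpha_fwer),
            population=pop,
            infradian_significant=bool(pop.significant[band].any()) if band.any() else False,
            mean_infradian_peak_h=float(
                np.mean([p.peak_period_h for p in infr_peaks])) if infr_peaks else float("nan"),
        )
    return out


@dataclass
class CosinorSummary:
    parameter: str
    fits: list
    sample: cosinor.AngleSample | None
    excluded_fraction: float


def cosinor_summary(
    per_subject: list[dict[str, BinnedSeries]],
    cfg: AnalysisConfig | None = None,
) -> dict[str, CosinorSummary]:
    """Per-parameter fixed-24 h cosinor fits and screened acrophase samples."""
    cfg = cfg or AnalysisConfig()
    params = sorted({p for d in per_subject for p in d}, key=str)
    out = {}
    for param in params:
        fits = []
        for d in per_subject:
            if param not in d:
                continue
            series = d[param]
            t, v = series.nonmissing()
            if t.size < 4 or np.allclose(v, v[0]):
                continue
            fits.append(cosinor.fit_cosinor(series, cfg.cosinor_period_h))
        if not fits:
            continue
        try:
            sample = cosinor.acrophase_sample(fits, cfg.alpha)
            excl = sample.excluded_fraction
        except ValueError:
            sample, excl = None, 1.0
        out[param] = CosinorSummary(param, fits, sample, excl)
    return out


def sleep_window_analysis(
    cohort: list[tuple[EventStream, WearableSeries]],
    cfg: AnalysisConfig | None = None,
) -> dict[str, sleepwindows.WindowComparison]:
    """Score sleep from actigraphy, pool pre_bed/bed/rise latencies, compare."""
    cfg = cfg or AnalysisConfig()
    pooled: dict[str, list] = {"TS": [], "US": [], "ALS": []}
    for stream, wearable in cohort:
        periods = actigraphy.score_sleep(wearable, cfg)
        if not periods:
            continue
        intervals = sleepwindows.segment_windows(
            periods, cfg.window_len_s, cfg.window_len_s)
        subj = sleepwindows.pool_window_params(
            stream, intervals, cfg.min_episodes_window,
            cfg.max_gap_s, cfg.max_episode_s)
        for param, sample in subj.items():
            pooled[param].append(sample)
    out = {}
    for param, samples in pooled.items():
        if len(samples) >= 3:
            out[param] = sleepwindows.compare_windows(samples, param)
    return out
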