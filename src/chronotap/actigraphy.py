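"""Actigraphy: acceleration -> activity counts -> Cole-Kripke sleep scoring.

The Cole-Kripke score for minute i is ``S_i = P * sum_k w_k * count_{i+k}``
over the window k = -4..+2; an epoch is scored sleep when ``S_i`` falls
below the threshold. Defaults are the published one-minute-mode
parameterization (P = 0.00001, weights 404, 598, 326, 441, 1408, 508, 350,
threshold 1). Webster rescoring is available but off by default.
"""

from __future__ import annotations

import numpy as np

from .types import (
    SECONDS_PER_DAY,
    ActivityCounts,
    SleepPeriod,
    WearableSeries,
    weekday,
)

__all__ = ["accel_to_counts", "cole_kripke", "consolidate_sleep", "score_sleep"]

CK_WEIGHTS = (404.0, 598.0, 326.0, 441.0, 1408.0, 508.0, 350.0)
CK_SCALE = 0.00001
CK_THRESHOLD = 1.0


def accel_to_counts(
    series: WearableSeries, epoch_s: float = 60.0, gain: float = 100.0
) -> ActivityCounts:
    """Per-epoch activity counts from acceleration magnitude.

    Each epoch's count is ``gain * sum(max(0, |a| - 1 g))`` over its samples
    (gravity-subtracted rectified magnitude). If the series already carries
    counts they are passed through (summed when re-epoching is needed).
    """
    if series.counts is not None:
        return _regroup(series.t_start, series.counts, series.epoch_s, epoch_s,
                        series.subject_id, series.utc_offset_s)
    if series.accel_mag is None:
        raise ValueError("wearable series has neither acceleration nor counts")
    excess = np.maximum(0.0, np.nan_to_num(series.accel_mag, nan=1.0) - 1.0) * gain
    return _regroup(series.t_start, excess, series.epoch_s, epoch_s,
                    series.subject_id, series.utc_offset_s)


def _regroup(t, v, src_epoch, dst_epoch, subject_id, utc_offset_s) -> ActivityCounts:
    if np.isclose(src_epoch, dst_epoch):
        return ActivityCounts(subject_id, t.copy(), dst_epoch,
                              np.nan_to_num(v, nan=0.0), utc_offset_s)
    ratio = dst_epoch / src_epoch
    if ratio < 1 or not np.isclose(ratio, round(ratio)):
        raise ValueError(
            f"cannot regroup {src_epoch:g}s epochs into {dst_epoch:g}s epochs"
        )
    t0 = np.floor(t[0] / dst_epoch) * dst_epoch
    idx = np.floor((t - t0) / dst_epoch).astype(np.int64)
    n = int(idx.max()) + 1
    counts = np.bincount(idx, weights=np.nan_to_num(v, nan=0.0), minlength=n)
    return ActivityCounts(subject_id, t0 + dst_epoch * np.arange(n), dst_epoch,
                          counts, utc_offset_s)


def cole_kripke(
    counts: ActivityCounts,
    weights: tuple[float, ...] = CK_WEIGHTS,
    scale: float = CK_SCALE,
    threshold: float = CK_THRESHOLD,
) -> np.ndarray:
    """Per-epoch sleep(True)/wake(False) labels from 1-min activity counts.

    Epochs longer or shorter than one minute are regrouped first (shorter is
    summed up; anything that does not divide evenly is an error). Missing
    neighbours at the edges count as zero activity.
    """
    if not np.isclose(counts.epoch_s, 60.0):
        counts = _regroup(counts.t_start, counts.counts, counts.epoch_s, 60.0,
                          counts.subject_id, counts.utc_offset_s)
    w = np.asarray(weights, dtype=float)
    if w.size != 7:
        raise ValueError("expected 7 weights for minutes -4..+2")
    c = np.nan_to_num(counts.counts, nan=0.0)
    # S_i = scale * sum_{k=-4..+2} w_k c_{i+k}; correlate aligns w_0 at lag 0
    padded = np.concatenate([np.zeros(4), c, np.zeros(2)])
    score = scale * np.correlate(padded, w, mode="valid")
    return score < threshold


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where mask is True."""
    if mask.size == 0:
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def consolidate_sleep(
    counts: ActivityCounts,
    labels: np.ndarray,
    min_bout_min: float = 20.0,
    merge_gap_min: float = 60.0,
) -> list[SleepPeriod]:
    """Main consolidated sleep period per noon-to-noon day.

    Sleep bouts shorter than ``min_bout_min`` are dropped; surviving bouts
    separated by less than ``merge_gap_min`` of wake are merged; the longest
    merged bout inside each local noon-to-noon window becomes that day's
    sleep period (assigned by onset time).
    """
    epoch = counts.epoch_s
    bouts = [
        (counts.t_start[a], counts.t_start[b - 1] + epoch)
        for a, b in _runs(np.asarray(labels, dtype=bool))
        if (b - a) * epoch >= min_bout_min * 60.0
    ]
    merged: list[list[float]] = []
    for on, off in bouts:
        if merged and on - merged[-1][1] < merge_gap_min * 60.0:
            merged[-1][1] = off
        else:
            merged.append([on, off])

    # group by the noon-to-noon local day containing the onset
    by_day: dict[int, list[float]] = {}
    for on, off in merged:
        day = int(np.floor((on + counts.utc_offset_s - SECONDS_PER_DAY / 2)
                           / SECONDS_PER_DAY))
        best = by_day.get(day)
        if best is None or (off - on) > (best[1] - best[0]):
            by_day[day] = [on, off]

    periods = []
    for night_index, day in enumerate(sorted(by_day)):
        on, off = by_day[day]
        periods.append(
            SleepPeriod(
                subject_id=counts.subject_id,
                onset=float(on),
                offset=float(off),
                night_index=night_index,
                onset_weekday=int(weekday(on, counts.utc_offset_s)),
            )
        )
    return periods


def score_sleep(series: WearableSeries, cfg=None) -> list[SleepPeriod]:
    """Wearable series -> consolidated sleep periods with one config."""
    from .config import AnalysisConfig

    cfg = cfg or AnalysisConfig()
    counts = accel_to_counts(series, cfg.ck_epoch_s)
    labels = cole_kripke(counts, cfg.ck_weights, cfg.ck_scale, cfg.ck_threshold)
    return consolidate_sleep(counts, labels, cfg.min_bout_min, cfg.merge_gap_min)
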