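"""Smartphone parameter extraction: usage, TS, US and ALS per time bin.

Usage is the raw touch count per bin. TS (tapping speed) is the fastest
25th percentile of inter-touch intervals completing in a bin, after
dropping session breaks (gaps above ``max_gap``). US (unlocking speed) and
ALS (app-locating speed) are per-bin medians of episode latencies:
screen-on -> unlock-complete and home-screen -> app-launch respectively.
All latencies are milliseconds; the completing event decides the bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import BinnedSeries, EventStream, LatencyObservation

__all__ = [
    "usage_counts",
    "tapping_speed",
    "unlocking_speed",
    "app_locating_speed",
    "inter_touch_observations",
    "episode_observations",
    "extract_all",
]


def _bin_grid(stream: EventStream, bin_width: float) -> np.ndarray:
    """Contiguous bin starts covering the stream, anchored to bin_width."""
    t0 = np.floor(stream.t[0] / bin_width) * bin_width
    n = int(np.floor((stream.t[-1] - t0) / bin_width)) + 1
    return t0 + bin_width * np.arange(n)


def _bin_index(t: np.ndarray, starts: np.ndarray, bin_width: float) -> np.ndarray:
    return np.floor((t - starts[0]) / bin_width).astype(np.int64)


def usage_counts(stream: EventStream, bin_width: float = 3600.0) -> BinnedSeries:
    """Touch count per half-open bin [start, start+width); empty bins are 0."""
    starts = _bin_grid(stream, bin_width)
    touches = stream.of_kind("touch")
    counts = np.zeros(starts.size)
    if touches.size:
        idx = _bin_index(touches, starts, bin_width)
        counts = np.bincount(idx, minlength=starts.size).astype(float)
    return BinnedSeries(stream.subject_id, "usage", bin_width, starts, counts,
                        stream.utc_offset_s)


def inter_touch_observations(
    stream: EventStream, max_gap: float = 30.0
) -> list[LatencyObservation]:
    """Inter-touch intervals (ms) stamped at the completing touch.

    Intervals longer than ``max_gap`` seconds are session breaks and dropped.
    """
    touches = stream.of_kind("touch")
    if touches.size < 2:
        return []
    dt = np.diff(touches)
    keep = dt <= max_gap
    return [
        LatencyObservation(float(t), "inter_touch", float(d) * 1000.0)
        for t, d in zip(touches[1:][keep], dt[keep])
    ]


def tapping_speed(
    stream: EventStream,
    bin_width: float = 3600.0,
    max_gap: float = 30.0,
    min_intervals: int = 5,
) -> BinnedSeries:
    """Fastest 25th percentile of inter-touch intervals per bin (ms).

    The percentile uses linear interpolation between order statistics. Bins
    with fewer than ``min_intervals`` retained intervals are missing.
    """
    starts = _bin_grid(stream, bin_width)
    values = np.full(starts.size, np.nan)
    obs = inter_touch_observations(stream, max_gap)
    if obs:
        t = np.array([o.t for o in obs])
        v = np.array([o.value_ms for o in obs])
        idx = _bin_index(t, starts, bin_width)
        for b in np.unique(idx):
            sel = v[idx == b]
            if sel.size >= min_intervals:
                values[b] = np.percentile(sel, 25.0)
    return BinnedSeries(stream.subject_id, "TS", bin_width, starts, values,
                        stream.utc_offset_s)


@dataclass
class EpisodeExtraction:
    observations: list[LatencyObservation]
    n_orphans: int      # completions with no usable preceding start event
    n_discarded: int    # episodes over max_duration or broken by screen_off


def episode_observations(
    stream: EventStream,
    start_kind: str,
    end_kind: str,
    obs_kind: str,
    max_duration: float = 60.0,
) -> EpisodeExtraction:
    """Pair each ``end_kind`` event with its nearest preceding ``start_kind``.

    An episode is discarded when a ``screen_off`` intervenes or the latency
    exceeds ``max_duration`` seconds; completions with no preceding start are
    counted as orphans.
    """
    starts = stream.of_kind(start_kind)
    ends = stream.of_kind(end_kind)
    offs = stream.of_kind("screen_off")
    obs: list[LatencyObservation] = []
    n_orphans = n_discarded = 0
    for te in ends:
        i = np.searchsorted(starts, te, side="right") - 1
        if i < 0:
            n_orphans += 1
            continue
        ts = starts[i]
        lat = te - ts
        if lat > max_duration:
            n_discarded += 1
            continue
        # screen_off strictly inside (ts, te) breaks the episode
        j = np.searchsorted(offs, ts, side="right")
        if j < offs.size and offs[j] < te:
            n_discarded += 1
            continue
        if lat <= 0:
            n_orphans += 1
            continue
        obs.append(LatencyObservation(float(te), obs_kind, float(lat) * 1000.0))
    return EpisodeExtraction(obs, n_orphans, n_discarded)


def _episode_series(
    stream: EventStream,
    parameter: str,
    start_kind: str,
    end_kind: str,
    obs_kind: str,
    bin_width: float,
    max_duration: float,
    min_episodes: int,
) -> BinnedSeries:
    starts = _bin_grid(stream, bin_width)
    values = np.full(starts.size, np.nan)
    ext = episode_observations(stream, start_kind, end_kind, obs_kind, max_duration)
    if ext.observations:
        t = np.array([o.t for o in ext.observations])
        v = np.array([o.value_ms for o in ext.observations])
        idx = _bin_index(t, starts, bin_width)
        for b in np.unique(idx):
            sel = v[idx == b]
            if sel.size >= min_episodes:
                values[b] = np.median(sel)
    return BinnedSeries(stream.subject_id, parameter, bin_width, starts, values,
                        stream.utc_offset_s)


def unlocking_speed(
    stream: EventStream,
    bin_width: float = 3600.0,
    max_duration: float = 60.0,
    min_episodes: int = 1,
) -> BinnedSeries:
    """Per-bin median screen-on -> unlock-complete latency (ms)."""
    return _episode_series(stream, "US", "screen_on", "unlock_complete",
                           "unlock", bin_width, max_duration, min_episodes)


def app_locating_speed(
    stream: EventStream,
    bin_width: float = 3600.0,
    max_duration: float = 60.0,
    min_episodes: int = 1,
) -> BinnedSeries:
    """Per-bin median home-screen -> app-launch latency (ms)."""
    return _episode_series(stream, "ALS", "home_shown", "app_launch",
                           "app_locate", bin_width, max_duration, min_episodes)


def extract_all(stream: EventStream, cfg=None) -> dict[str, BinnedSeries]:
    """All four smartphone parameters with one config."""
    from .config import AnalysisConfig

    cfg = cfg or AnalysisConfig()
    return {
        "usage": usage_counts(stream, cfg.bin_width_s),
        "TS": tapping_speed(stream, cfg.bin_width_s, cfg.max_gap_s, cfg.min_intervals_ts),
        "US": unlocking_speed(stream, cfg.bin_width_s, cfg.max_episode_s, cfg.min_episodes_bin),
        "ALS": app_locating_speed(stream, cfg.bin_width_s, cfg.max_episode_s, cfg.min_episodes_bin),
    }
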