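"""Synthetic cohorts of coupled touch streams, actigraphy and luminescence.

The generator emulates the statistical structure the analysis assumes:
~21-day recordings; touch events from an inhomogeneous Poisson process with
diurnal (~24 h) and weekly (~7 d) intensity modulation, silenced during
sleep except for occasional in-bed use bouts; unlock and app-launch
episodes with lognormal latencies whose location is scaled by diurnal,
bed-window and post-wake-inertia multipliers; consolidated nocturnal sleep
as near-zero activity counts; and a day plateau / night floor luminescence
trace. Every generating parameter is recorded per subject as ground truth.

Touch intensity: ``lambda(t) = base * (1 + a24 cos(2 pi (h - phi24)/24))
* (1 + a7 cos(2 pi (d - d7)/7))``, clipped at zero and multiplied by the
awake fraction of each hour bin. Counts per hour bin are exact Poisson
draws; touches are laid out in short sessions (screen-on, unlock, home
screen, app launch, then a run of touches) so that every tappigraphy
parameter is observable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .types import (
    SECONDS_PER_DAY,
    SECONDS_PER_HOUR,
    EventStream,
    WearableSeries,
    hour_of_day,
    weekday,
)

__all__ = ["LatencyModel", "SynthConfig", "generate_subject", "generate_cohort",
           "SubjectTruth", "write_cohort"]

#: Monday 2020-01-06 00:00 UTC — recordings start on a Monday midnight.
DEFAULT_START = 1578268800.0


@dataclass
class LatencyModel:
    """Lognormal latency model for one parameter.

    ``baseline_ms`` is the median latency; multipliers act on the lognormal
    location, so they read as fractional slowing. ``diurnal_peak_h`` is the
    clock hour of *slowest* performance (fastest is 12 h opposite);
    ``bed_penalty`` applies inside scored sleep; ``inertia_penalty`` decays
    exponentially after wake with time constant ``inertia_tau_min``.
    """

    baseline_ms: float
    diurnal_amp: float = 0.10
    diurnal_peak_h: float = 4.0
    bed_penalty: float = 0.0
    inertia_penalty: float = 0.0
    inertia_tau_min: float = 45.0
    sigma: float = 0.3

    def __post_init__(self) -> None:
        if self.baseline_ms <= 0:
            raise ValueError("baseline must be positive")
        if not 0 <= self.diurnal_amp < 1:
            raise ValueError("diurnal amplitude fraction must be in [0, 1)")
        if min(self.bed_penalty, self.inertia_penalty, self.sigma) < 0:
            raise ValueError("penalties and sigma must be nonnegative")


@dataclass
class SynthConfig:
    """Ground-truth generating parameters for a synthetic cohort."""

    n_subjects: int = 20
    days: int = 21
    start_t: float = DEFAULT_START
    utc_offset_s: float = 0.0

    # touch intensity (events/h) and its rhythms
    base_rate_per_h: float = 60.0
    diurnal_amp: float = 0.8
    diurnal_acro_h: float = 16.0
    weekly_amp: float = 0.2
    weekly_peak_day: float = 2.0      # Monday=0; usage peaks midweek
    mean_session_touches: float = 8.0

    # latency models
    ts: LatencyModel = field(default_factory=lambda: LatencyModel(
        200.0, diurnal_amp=0.10, bed_penalty=0.05, inertia_penalty=0.05, sigma=0.30))
    us: LatencyModel = field(default_factory=lambda: LatencyModel(
        2000.0, diurnal_amp=0.10, bed_penalty=0.20, inertia_penalty=0.10, sigma=0.40))
    als: LatencyModel = field(default_factory=lambda: LatencyModel(
        1200.0, diurnal_amp=0.05, bed_penalty=0.0, inertia_penalty=0.0, sigma=0.50))

    # sleep schedule (clock hours; offset is next morning)
    sleep_onset_h: float = 23.5
    sleep_offset_h: float = 7.5
    jitter_min: float = 30.0
    weekend_shift_min: float = 60.0
    in_bed_prob: float = 0.8
    max_in_bed_bouts: int = 3

    # actigraphy counts (per minute) and luminescence
    actigraphy_epoch_s: float = 60.0
    wake_count_mean: float = 250.0
    wake_count_shape: float = 2.0
    sleep_count_mean: float = 2.0
    lux_day: float = 200.0
    lux_night: float = 1.0
    lux_sigma: float = 0.5
    lux_day_start_h: float = 8.0
    lux_day_end_h: float = 20.0

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.days < 2:
            raise ValueError("need n_subjects >= 1 and days >= 2")
        if self.base_rate_per_h < 0 or self.weekly_amp < 0:
            raise ValueError("rates and amplitudes must be nonnegative")
        if not 0 <= self.diurnal_amp < 1:
            raise ValueError("diurnal amplitude fraction must be in [0, 1)")
        if self.base_rate_per_h == 0 and self.in_bed_prob > 0:
            raise ValueError("zero base rate with nonzero in-bed probability")
        dur = (self.sleep_offset_h - self.sleep_onset_h) % 24.0
        if dur <= 0:
            raise ValueError("sleep onset must precede offset modulo 24 h")


@dataclass
class SubjectTruth:
    """Everything the generator decided for one subject."""

    subject_id: str
    sleep_onsets: np.ndarray
    sleep_offsets: np.ndarray
    params: dict


def _latency_multiplier(t: float, model: LatencyModel, onsets: np.ndarray,
                        offsets: np.ndarray, utc_offset_s: float) -> float:
    h = hour_of_day(t, utc_offset_s)
    mult = 1.0 + model.diurnal_amp * np.cos(
        2.0 * np.pi * (h - model.diurnal_peak_h) / 24.0)
    # in-bed penalty
    i = np.searchsorted(onsets, t, side="right") - 1
    if i >= 0 and t < offsets[i]:
        mult *= 1.0 + model.bed_penalty
    # post-wake inertia from the most recent offset
    j = np.searchsorted(offsets, t, side="right") - 1
    if j >= 0 and model.inertia_penalty > 0:
        dt_min = (t - offsets[j]) / 60.0
        mult *= 1.0 + model.inertia_penalty * np.exp(-dt_min / model.inertia_tau_min)
    return float(mult)


def _lognormal(rng: np.random.Generator, median: float, sigma: float) -> float:
    return float(median * np.exp(sigma * rng.standard_normal()))


def _session(rng, t0, n_touches, cfg, onsets, offsets):
    """One phone session: screen_on, unlock, home screen, app launch, touches."""
    events = [(t0, "screen_on")]
    t = t0 + _lognormal(
        rng, cfg.us.baseline_ms / 1000.0
        * _latency_multiplier(t0, cfg.us, onsets, offsets, cfg.utc_offset_s),
        cfg.us.sigma)
    events.append((t, "unlock_complete"))
    t += 0.3
    events.append((t, "home_shown"))
    t += _lognormal(
        rng, cfg.als.baseline_ms / 1000.0
        * _latency_multiplier(t, cfg.als, onsets, offsets, cfg.utc_offset_s),
        cfg.als.sigma)
    events.append((t, "app_launch"))
    t += 0.2
    for k in range(int(n_touches)):
        if k > 0:
            t += _lognormal(
                rng, cfg.ts.baseline_ms / 1000.0
                * _latency_multiplier(t, cfg.ts, onsets, offsets, cfg.utc_offset_s),
                cfg.ts.sigma)
        events.append((t, "touch"))
    events.append((t + 0.5, "screen_off"))
    return events


def _awake_segments(b0: float, b1: float, onsets: np.ndarray,
                    offsets: np.ndarray) -> list[tuple[float, float]]:
    """Sub-intervals of [b0, b1) not covered by any sleep period."""
    segs = []
    t = b0
    for on, off in zip(onsets, offsets):
        if off <= t or on >= b1:
            continue
        if on > t:
            segs.append((t, min(on, b1)))
        t = max(t, off)
        if t >= b1:
            break
    if t < b1:
        segs.append((t, b1))
    return segs


def _sleep_schedule(rng, cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    dur_h = (cfg.sleep_offset_h - cfg.sleep_onset_h) % 24.0
    onsets, offsets = [], []
    for j in range(cfg.days - 1):
        on = (cfg.start_t + j * SECONDS_PER_DAY
              + cfg.sleep_onset_h * SECONDS_PER_HOUR
              + rng.normal(0.0, cfg.jitter_min * 60.0))
        if int(weekday(on, cfg.utc_offset_s)) in (4, 5):  # Fri/Sat night
            on += cfg.weekend_shift_min * 60.0
        off = on + dur_h * SECONDS_PER_HOUR + rng.normal(0.0, cfg.jitter_min * 60.0)
        onsets.append(on)
        offsets.append(off)
    return np.array(onsets), np.array(offsets)


def generate_subject(
    cfg: SynthConfig, subject_index: int
) -> tuple[EventStream, WearableSeries, SubjectTruth]:
    """One subject's coupled touch stream, wearable trace and ground truth.

    Per-subject randomness derives deterministically from the master seed
    and the subject index.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, subject_index]))
    sid = f"synth{subject_index:03d}"
    end_t = cfg.start_t + cfg.days * SECONDS_PER_DAY
    onsets, offsets = _sleep_schedule(rng, cfg)

    events: list[tuple[float, str]] = []
    n_bins = cfg.days * 24
    for b in range(n_bins):
        b0 = cfg.start_t + b * SECONDS_PER_HOUR
        b1 = b0 + SECONDS_PER_HOUR
        tc = b0 + SECONDS_PER_HOUR / 2.0
        h = hour_of_day(tc, cfg.utc_offset_s)
        dow = ((tc + cfg.utc_offset_s) / SECONDS_PER_DAY + 3.0) % 7.0
        lam = cfg.base_rate_per_h
        lam *= 1.0 + cfg.diurnal_amp * np.cos(2 * np.pi * (h - cfg.diurnal_acro_h) / 24.0)
        lam *= 1.0 + cfg.weekly_amp * np.cos(2 * np.pi * (dow - cfg.weekly_peak_day) / 7.0)
        lam = max(lam, 0.0)
        segs = _awake_segments(b0, b1, onsets, offsets)
        awake_s = sum(s1 - s0 for s0, s1 in segs)
        if awake_s <= 0 or lam <= 0:
            continue
        n_touch = rng.poisson(lam * awake_s / SECONDS_PER_HOUR)
        if n_touch == 0:
            continue
        n_sessions = max(1, int(round(n_touch / cfg.mean_session_touches)))
        sizes = rng.multinomial(n_touch, np.full(n_sessions, 1.0 / n_sessions))
        # spread sessions over awake segments proportional to their length
        seg_lens = np.array([s1 - s0 for s0, s1 in segs])
        seg_of = rng.choice(len(segs), size=n_sessions, p=seg_lens / seg_lens.sum())
        for seg_idx in np.unique(seg_of):
            in_seg = np.flatnonzero(seg_of == seg_idx)
            s0, s1 = segs[seg_idx]
            slot = (s1 - s0) / in_seg.size
            for rank, si in enumerate(in_seg):
                if sizes[si] == 0:
                    continue
                t0 = s0 + (rank + 0.3 * rng.random()) * slot
                events.extend(_session(rng, t0, sizes[si], cfg, onsets, offsets))

    # in-bed use bouts: short sessions at physical rest during scored sleep
    for on, off in zip(onsets, offsets):
        if rng.random() >= cfg.in_bed_prob or cfg.max_in_bed_bouts < 1:
            continue
        for _ in range(int(rng.integers(1, cfg.max_in_bed_bouts + 1))):
            lo = on + 300.0
            hi = off - 1800.0
            if hi <= lo:
                continue
            t0 = float(rng.uniform(lo, hi))
            n = int(rng.integers(3, 9))
            events.extend(_session(rng, t0, n, cfg, onsets, offsets))

    events.sort(key=lambda e: e[0])
    t = np.array([e[0] for e in events])
    kind = np.array([e[1] for e in events], dtype=object)
    stream = EventStream(sid, t, kind, cfg.utc_offset_s)

    # wearable: activity counts + lux per epoch
    ne = int(round(cfg.days * SECONDS_PER_DAY / cfg.actigraphy_epoch_s))
    ts = cfg.start_t + cfg.actigraphy_epoch_s * np.arange(ne)
    asleep = np.zeros(ne, dtype=bool)
    for on, off in zip(onsets, offsets):
        asleep |= (ts >= on) & (ts < off)
    shape = cfg.wake_count_shape
    counts = np.where(
        asleep,
        rng.exponential(cfg.sleep_count_mean, ne),
        rng.gamma(shape, cfg.wake_count_mean / shape, ne),
    )
    hrs = hour_of_day(ts, cfg.utc_offset_s)
    daylight = (hrs >= cfg.lux_day_start_h) & (hrs < cfg.lux_day_end_h)
    lux_base = np.where(daylight & ~asleep, cfg.lux_day, cfg.lux_night)
    lux = lux_base * np.exp(cfg.lux_sigma * rng.standard_normal(ne))
    wearable = WearableSeries(sid, ts, cfg.actigraphy_epoch_s, lux,
                              counts=counts, utc_offset_s=cfg.utc_offset_s)

    truth = SubjectTruth(
        subject_id=sid,
        sleep_onsets=onsets,
        sleep_offsets=offsets,
        params={
            "base_rate_per_h": cfg.base_rate_per_h,
            "diurnal_amp": cfg.diurnal_amp,
            "diurnal_acro_h": cfg.diurnal_acro_h,
            "weekly_amp": cfg.weekly_amp,
            "weekly_peak_day": cfg.weekly_peak_day,
            "ts": asdict(cfg.ts),
            "us": asdict(cfg.us),
            "als": asdict(cfg.als),
            "sleep_onset_h": cfg.sleep_onset_h,
            "sleep_offset_h": cfg.sleep_offset_h,
        },
    )
    return stream, wearable, truth


def generate_cohort(
    cfg: SynthConfig,
) -> list[tuple[EventStream, WearableSeries, SubjectTruth]]:
    """Reproducible cohort: per-subject seeds derive from the master seed."""
    return [generate_subject(cfg, i) for i in range(cfg.n_subjects)]


def write_cohort(cfg: SynthConfig, out_dir) -> None:
    """Write the cohort as the CSV dialects the readers consume, plus truth.json."""
    import json
    from pathlib import Path

    from .io import write_event_stream, write_wearable

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truths = {}
    for stream, wearable, truth in generate_cohort(cfg):
        write_event_stream(stream, out / f"{stream.subject_id}_events.csv")
        write_wearable(wearable, out / f"{stream.subject_id}_wearable.csv")
        truths[truth.subject_id] = {
            "sleep_onsets": truth.sleep_onsets.tolist(),
            "sleep_offsets": truth.sleep_offsets.tolist(),
            "params": truth.params,
        }
    (out / "truth.json").write_text(json.dumps(truths, indent=2, sort_keys=True))
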