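"""Core data model shared by every analysis stage.

All timestamps are seconds since the Unix epoch (UTC). Local clock time is
obtained by adding a per-subject UTC offset, so "hour of day" always means
the subject's wall clock. Hour-of-day bins are half-open ``[h, h+1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "EVENT_KINDS",
    "LATENCY_PARAMETERS",
    "COUNT_PARAMETERS",
    "PARAMETERS",
    "EventStream",
    "WearableSeries",
    "ActivityCounts",
    "BinnedSeries",
    "LatencyObservation",
    "Periodogram",
    "PeakEstimate",
    "CosinorFit",
    "SleepPeriod",
    "WindowSample",
    "hour_of_day",
    "weekday",
    "SECONDS_PER_DAY",
    "SECONDS_PER_HOUR",
]

SECONDS_PER_HOUR = 3600.0
SECONDS_PER_DAY = 86400.0

#: Closed vocabulary of touchscreen event kinds.
EVENT_KINDS = (
    "touch",
    "screen_on",
    "unlock_complete",
    "home_shown",
    "app_launch",
    "screen_off",
)

#: Latency-valued smartphone parameters (milliseconds; missing when no data).
LATENCY_PARAMETERS = ("TS", "US", "ALS")
#: Count/intensity parameters (zero when no data in a bin).
COUNT_PARAMETERS = ("usage", "activity", "lux")
PARAMETERS = COUNT_PARAMETERS[:1] + LATENCY_PARAMETERS + COUNT_PARAMETERS[1:]


def hour_of_day(t: np.ndarray | float, utc_offset_s: float = 0.0) -> np.ndarray | float:
    """Local clock hour in [0, 24) for epoch seconds ``t``."""
    return ((np.asarray(t, dtype=float) + utc_offset_s) % SECONDS_PER_DAY) / SECONDS_PER_HOUR


def weekday(t: np.ndarray | float, utc_offset_s: float = 0.0) -> np.ndarray:
    """Local weekday, Monday=0 .. Sunday=6 (1970-01-01 was a Thursday)."""
    days = np.floor((np.asarray(t, dtype=float) + utc_offset_s) / SECONDS_PER_DAY)
    return (days.astype(np.int64) + 3) % 7


@dataclass
class EventStream:
    """Ordered timestamped smartphone events for one subject."""

    subject_id: str
    t: np.ndarray          # epoch seconds, non-decreasing
    kind: np.ndarray       # strings from EVENT_KINDS
    utc_offset_s: float = 0.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.kind = np.asarray(self.kind, dtype=object)
        if self.t.shape != self.kind.shape:
            raise ValueError("t and kind must have the same length")
        if np.any(np.diff(self.t) < 0):
            raise ValueError("event timestamps must be non-decreasing")
        bad = set(np.unique(self.kind)) - set(EVENT_KINDS)
        if bad:
            raise ValueError(f"unknown event kinds: {sorted(bad)}")

    def __len__(self) -> int:
        return self.t.size

    @property
    def span_s(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) else 0.0

    def of_kind(self, kind: str) -> np.ndarray:
        """Timestamps of one event kind."""
        return self.t[self.kind == kind]

    def shifted(self, dt: float) -> "EventStream":
        return replace(self, t=self.t + dt)


@dataclass
class WearableSeries:
    """Uniform-epoch wrist recording: acceleration (or counts) plus lux.

    Either ``accel_mag`` (g) or ``counts`` must be present. Missing epochs
    carry NaN.
    """

    subject_id: str
    t_start: np.ndarray
    epoch_s: float
    lux: np.ndarray
    accel_mag: np.ndarray | None = None
    counts: np.ndarray | None = None
    utc_offset_s: float = 0.0

    def __post_init__(self) -> None:
        self.t_start = np.asarray(self.t_start, dtype=float)
        self.lux = np.asarray(self.lux, dtype=float)
        if self.accel_mag is not None:
            self.accel_mag = np.asarray(self.accel_mag, dtype=float)
        if self.counts is not None:
            self.counts = np.asarray(self.counts, dtype=float)
        if self.accel_mag is None and self.counts is None:
            raise ValueError("wearable series needs accel_mag or counts")
        d = np.diff(self.t_start)
        if d.size and not np.allclose(d, self.epoch_s):
            raise ValueError("epochs must be uniform")

    def __len__(self) -> int:
        return self.t_start.size


@dataclass
class ActivityCounts:
    """Per-epoch activity counts at a fixed epoch length (default 60 s)."""

    subject_id: str
    t_start: np.ndarray
    epoch_s: float
    counts: np.ndarray
    utc_offset_s: float = 0.0

    def __post_init__(self) -> None:
        self.t_start = np.asarray(self.t_start, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if np.nanmin(self.counts, initial=0.0) < 0:
            raise ValueError("activity counts must be nonnegative")

    def __len__(self) -> int:
        return self.t_start.size


@dataclass
class BinnedSeries:
    """Regular time-binned values of one parameter.

    ``values`` uses NaN for missing bins. Latency parameters (TS, US, ALS)
    are in milliseconds and strictly positive where present; count
    parameters (usage, activity, lux) are nonnegative with empty bins = 0.
    """

    subject_id: str
    parameter: str
    bin_width_s: float
    t_start: np.ndarray
    values: np.ndarray
    utc_offset_s: float = 0.0

    def __post_init__(self) -> None:
        if self.parameter not in PARAMETERS:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        self.t_start = np.asarray(self.t_start, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t_start.shape != self.values.shape:
            raise ValueError("t_start and values must align")
        d = np.diff(self.t_start)
        if d.size and not np.allclose(d, self.bin_width_s):
            raise ValueError("bins must be contiguous and uniform")
        present = self.values[~np.isnan(self.values)]
        if self.parameter in LATENCY_PARAMETERS:
            if present.size and present.min() <= 0:
                raise ValueError(f"{self.parameter} values must be > 0")
        elif present.size and present.min() < 0:
            raise ValueError(f"{self.parameter} values must be >= 0")

    def __len__(self) -> int:
        return self.t_start.size

    @property
    def is_latency(self) -> bool:
        return self.parameter in LATENCY_PARAMETERS

    @property
    def t_center(self) -> np.ndarray:
        return self.t_start + self.bin_width_s / 2.0

    def nonmissing(self) -> tuple[np.ndarray, np.ndarray]:
        """(bin-center times, values) with missing bins dropped."""
        m = ~np.isnan(self.values)
        return self.t_center[m], self.values[m]

    def clock_hours(self) -> np.ndarray:
        """Local clock hour of each bin start."""
        return hour_of_day(self.t_start, self.utc_offset_s)

    def span_s(self) -> float:
        """Total covered duration including the last bin."""
        return float(self.t_start[-1] + self.bin_width_s - self.t_start[0])


@dataclass(frozen=True)
class LatencyObservation:
    """One latency episode: completion time, kind, value in ms."""

    t: float
    kind: str  # inter_touch | unlock | app_locate
    value_ms: float


@dataclass
class Periodogram:
    """Normalized Lomb-Scargle power over a common period grid (hours)."""

    subject_id: str
    parameter: str
    periods_h: np.ndarray   # ascending periods == strictly decreasing frequency
    power: np.ndarray
    n_obs: int

    def __post_init__(self) -> None:
        self.periods_h = np.asarray(self.periods_h, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.periods_h) <= 0):
            raise ValueError("period grid must be strictly increasing")
        if np.any(self.power < -1e-12):
            raise ValueError("power must be nonnegative")


@dataclass(frozen=True)
class PeakEstimate:
    """Band-limited dominant period and its normalized power."""

    subject_id: str
    parameter: str
    peak_period_h: float
    peak_power: float


@dataclass(frozen=True)
class CosinorFit:
    """Fixed-period cosinor fit: mesor, amplitude, acrophase (clock hours).

    For latency parameters the series is negated before fitting so the
    acrophase is the clock time of *fastest* performance.
    """

    subject_id: str
    parameter: str
    period_h: float
    mesor: float
    amplitude: float
    acrophase_h: float        # in [0, period_h)
    p_zero_amplitude: float
    n_obs: int

    @property
    def bathyphase_h(self) -> float:
        return (self.acrophase_h + self.period_h / 2.0) % self.period_h


@dataclass(frozen=True)
class SleepPeriod:
    """One consolidated actigraphy-scored main sleep period."""

    subject_id: str
    onset: float
    offset: float
    night_index: int
    onset_weekday: int  # Monday=0

    def __post_init__(self) -> None:
        if not self.onset < self.offset:
            raise ValueError("sleep onset must precede offset")


@dataclass(frozen=True)
class WindowSample:
    """Per-subject pooled latency summary for one sleep-anchored window."""

    subject_id: str
    parameter: str
    window: str  # pre_bed | bed | rise
    value_ms: float
    n_episodes: int
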