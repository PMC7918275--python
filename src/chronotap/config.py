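"""Analysis configuration: one flat record of every tunable the pipeline uses."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig", "load_config", "dump_config"]


@dataclass
class AnalysisConfig:
    """Shared knobs for binning, spectra, cosinor, sleep scoring and windows.

    Times are seconds, periods hours unless noted. ``alpha_fwer`` is the
    Bonferroni-style family-wise level used for the peak-vs-24 h t-tests
    (0.05 over six parameters); ``fdr_q`` controls the Benjamini-Hochberg
    step-up across the period grid.
    """

    # binning
    bin_width_s: float = 3600.0
    utc_offset_s: float = 0.0

    # tappigraphy extraction
    max_gap_s: float = 30.0            # inter-touch intervals above this are session breaks
    min_intervals_ts: int = 5          # intervals needed for a TS bin
    min_episodes_bin: int = 1          # episodes needed for a US/ALS bin
    max_episode_s: float = 60.0        # unlock / app-locate episodes longer than this dropped

    # spectral grid
    min_period_h: float = 3.0
    oversampling: float = 4.0
    diurnal_band_h: tuple[float, float] = (16.0, 32.0)
    infradian_band_h: tuple[float, float] = (5.0 * 24.0, 9.0 * 24.0)

    # significance levels
    alpha: float = 0.05
    alpha_fwer: float = 0.0083
    fdr_q: float = 0.05

    # Cole-Kripke (1992 one-minute mode)
    ck_weights: tuple[float, ...] = (404.0, 598.0, 326.0, 441.0, 1408.0, 508.0, 350.0)
    ck_scale: float = 0.00001
    ck_threshold: float = 1.0
    ck_epoch_s: float = 60.0

    # sleep consolidation
    min_bout_min: float = 20.0
    merge_gap_min: float = 60.0

    # sleep-anchored windows
    window_len_s: float = 3600.0
    min_episodes_window: int = 3

    # cosinor
    cosinor_period_h: float = 24.0

    seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_width_s <= 0 or self.min_period_h <= 0 or self.oversampling <= 0:
            raise ValueError("bounds must be positive")
        lo, hi = self.diurnal_band_h
        if not (lo < 24.0 < hi):
            raise ValueError("diurnal band must contain 24 h")
        if len(self.ck_weights) != 7:
            raise ValueError("Cole-Kripke needs 7 weights (minutes -4..+2)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


def load_config(path: str | Path) -> AnalysisConfig:
    """Read a flat YAML mapping; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    names = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(raw) - names
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("diurnal_band_h", "infradian_band_h", "ck_weights"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return AnalysisConfig(**raw)


def dump_config(cfg: AnalysisConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
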