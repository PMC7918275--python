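"""Lomb-Scargle spectral analysis and cohort-level periodogram statistics.

Powers are classically normalized: the data are mean-centered and the
periodogram divided by the ddof-1 sample variance, so pure white noise has
expected power ~1 at every frequency and a sinusoid of amplitude A on noise
of variance s2 peaks near ``n A^2 / (4 s2)``. Equivalently, the power at a
period equals ``(n-1) R^2 / 2`` for the least-squares sinusoid fit to the
centered data at that period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.signal import lombscargle as _lombscargle

from .types import BinnedSeries, PeakEstimate, Periodogram

__all__ = [
    "period_grid",
    "lomb_scargle",
    "population_periodogram",
    "PopulationPeriodogram",
    "peak_in_band",
    "test_peaks_vs_24",
    "TestRecord",
    "compare_parameters",
    "AnovaRecord",
    "bh_mask",
]

SECONDS_PER_HOUR = 3600.0


def period_grid(
    record_length_h: float,
    min_period_h: float = 3.0,
    oversampling: float = 4.0,
) -> np.ndarray:
    """Period grid (hours, ascending) spanning [min_period, record_length/2].

    Frequencies are linearly spaced with step 1/(oversampling * record
    length), the standard oversampled Fourier grid for unevenly sampled data.
    """
    if min_period_h <= 0 or record_length_h / 2 <= min_period_h:
        raise ValueError("need 0 < min_period < record_length/2")
    f_lo = 2.0 / record_length_h
    f_hi = 1.0 / min_period_h
    df = 1.0 / (oversampling * record_length_h)
    freqs = np.arange(f_lo, f_hi + df / 2, df)
    return 1.0 / freqs[::-1]


def lomb_scargle(series: BinnedSeries, periods_h: np.ndarray) -> Periodogram:
    """Normalized Lomb-Scargle periodogram of one binned series.

    Missing bins are simply excluded (the unevenly-sampled formulation);
    a constant series has no defined normalization and raises.
    """
    t, y = series.nonmissing()
    if t.size < 2:
        raise ValueError("need at least 2 non-missing bins")
    yc = y - y.mean()
    var = float(yc @ yc) / (t.size - 1)
    if var <= 0:
        raise ValueError("constant series: normalized power undefined")
    periods_h = np.asarray(periods_h, dtype=float)
    omega = 2.0 * np.pi / (periods_h * SECONDS_PER_HOUR)
    # classic Lomb formula: scipy evaluates the tau-shifted two-term fit
    power = _lombscargle(t, yc, omega[::-1], floating_mean=False)[::-1] / var
    return Periodogram(series.subject_id, series.parameter, periods_h,
                       np.maximum(power, 0.0), n_obs=t.size)


def bh_mask(pvalues: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejections at FDR level q."""
    adj = stats.false_discovery_control(np.asarray(pvalues, dtype=float), method="bh")
    return adj <= q


@dataclass
class PopulationPeriodogram:
    parameter: str
    periods_h: np.ndarray
    mean_power: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    pvalues: np.ndarray        # one-sided t-test of power > 1 per period
    significant: np.ndarray    # BH-FDR mask across the grid
    n_subjects: int


def population_periodogram(
    periodograms: list[Periodogram], q: float = 0.05, ci: float = 0.95
) -> PopulationPeriodogram:
    """Across-subject mean power, t-based CI, and FDR-masked excess over noise.

    At each grid period the subject powers are tested against 1, the
    expected normalized power of a zero-amplitude (white-noise) signal, with
    a one-sample one-sided t-test; Benjamini-Hochberg at level ``q`` across
    the grid gives the significance mask.
    """
    if len(periodograms) < 3:
        raise ValueError("population periodogram needs at least 3 subjects")
    grid = periodograms[0].periods_h
    for pg in periodograms[1:]:
        if not np.array_equal(pg.periods_h, grid):
            raise ValueError("periodograms must share a common period grid")
    P = np.vstack([pg.power for pg in periodograms])
    n = P.shape[0]
    mean = P.mean(axis=0)
    sem = P.std(axis=0, ddof=1) / np.sqrt(n)
    tcrit = stats.t.ppf(0.5 + ci / 2, df=n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(sem > 0, (mean - 1.0) / sem, 0.0)
    pvals = stats.t.sf(tstat, df=n - 1)
    return PopulationPeriodogram(
        parameter=periodograms[0].parameter,
        periods_h=grid,
        mean_power=mean,
        ci_low=mean - tcrit * sem,
        ci_high=mean + tcrit * sem,
        pvalues=pvals,
        significant=bh_mask(pvals, q),
        n_subjects=n,
    )


def peak_in_band(pg: Periodogram, band_h: tuple[float, float]) -> PeakEstimate:
    """Dominant period and power within a band of the periodogram.

    Ties are broken toward 24 h when the band contains 24 h, otherwise
    toward the band center.
    """
    lo, hi = band_h
    mask = (pg.periods_h >= lo) & (pg.periods_h <= hi)
    if not mask.any():
        raise ValueError(f"band [{lo}, {hi}] h is empty on this grid")
    periods = pg.periods_h[mask]
    power = pg.power[mask]
    best = power.max()
    at_max = np.flatnonzero(np.isclose(power, best, rtol=0, atol=1e-12 * max(best, 1)))
    anchor = 24.0 if lo <= 24.0 <= hi else (lo + hi) / 2.0
    pick = at_max[np.argmin(np.abs(periods[at_max] - anchor))]
    return PeakEstimate(pg.subject_id, pg.parameter,
                        float(periods[pick]), float(power[pick]))


@dataclass(frozen=True)
class TestRecord:
    parameter: str
    mean: float
    t: float
    df: int
    p: float
    significant: bool


def test_peaks_vs_24(
    peak_periods_h: np.ndarray, parameter: str, alpha_fwer: float = 0.0083
) -> TestRecord:
    """One-sample t-test of per-subject peak periods against 24 h.

    A zero-variance sample equal to 24 h gives t=0, p=1; a zero-variance
    sample away from 24 h is treated as infinitely significant.
    """
    x = np.asarray(peak_periods_h, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 subjects")
    mean = float(x.mean())
    if np.allclose(x, x[0]):
        if np.isclose(mean, 24.0):
            t, p = 0.0, 1.0
        else:
            t = np.inf if mean > 24.0 else -np.inf
            p = 0.0
    else:
        res = stats.ttest_1samp(x, 24.0)
        t, p = float(res.statistic), float(res.pvalue)
    return TestRecord(parameter, mean, t, int(x.size - 1), p, p < alpha_fwer)


@dataclass(frozen=True)
class AnovaRecord:
    f: float
    df_between: int
    df_within: int
    p: float


def compare_parameters(groups: dict[str, np.ndarray]) -> AnovaRecord:
    """One-way ANOVA of per-subject values (peak periods or powers) by parameter."""
    if len(groups) < 2:
        raise ValueError("need at least 2 parameter groups")
    for name, g in groups.items():
        if np.asarray(g).size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 members")
    arrays = [np.asarray(g, dtype=float) for g in groups.values()]
    if all(np.allclose(a, arrays[0][0]) for a in arrays):
        k = len(arrays)
        n = sum(a.size for a in arrays)
        return AnovaRecord(0.0, k - 1, n - k, 1.0)
    res = stats.f_oneway(*arrays)
    k = len(arrays)
    n = sum(a.size for a in arrays)
    return AnovaRecord(float(res.statistic), k - 1, n - k, float(res.pvalue))
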