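"""Cosinor fitting, circular tests and time-of-day/week analyses."""

import numpy as np
import pytest

from chronotap import BinnedSeries, circ_corr, fit_cosinor, watson_williams
from chronotap.circular import (
    angle_to_hours,
    circular_mean,
    hours_to_angle,
    resultant_length,
)
from chronotap.cosinor import (
    acrophase_sample,
    day_of_week_analysis,
    model_free_peak,
    peak_vs_offpeak,
)

H = 3600.0


def cosine_series(mesor=10.0, amp=2.0, acro_h=16.0, days=3, noise=0.0,
                  parameter="activity", seed=0, start_bin=0):
    t = H * np.arange(start_bin, start_bin + days * 24)
    # values represent the bin, so they are the signal at the bin center
    v = mesor + amp * np.cos(2 * np.pi * ((t + H / 2) / H - acro_h) / 24.0)
    if noise:
        v = v + np.random.default_rng(seed).normal(0, noise, t.size)
        v = np.maximum(v, 0.01)
    return BinnedSeries("s", parameter, H, t, v)


class TestFitCosinor:
    def test_exact_recovery(self):
        fit = fit_cosinor(cosine_series(), 24.0)
        assert fit.mesor == pytest.approx(10.0, abs=1e-9)
        assert fit.amplitude == pytest.approx(2.0, abs=1e-9)
        assert fit.acrophase_h == pytest.approx(16.0, abs=1e-9)
        assert fit.p_zero_amplitude < 1e-12

    def test_constant_series(self):
        t = H * np.arange(72)
        s = BinnedSeries("s", "activity", H, t, np.full(72, 5.0))
        fit = fit_cosinor(s, 24.0)
        assert fit.amplitude == pytest.approx(0.0, abs=1e-9)
        assert fit.p_zero_amplitude == 1.0

    def test_noisy_acrophase_within_hour(self):
        fit = fit_cosinor(cosine_series(noise=1.0, days=21, seed=4), 24.0)
        assert abs(fit.acrophase_h - 16.0) < 1.0

    def test_acrophase_equivariant_under_shift(self):
        base = cosine_series(days=4)
        fit0 = fit_cosinor(base, 24.0)
        shifted = BinnedSeries("s", "activity", H, base.t_start + 5 * H, base.values)
        fit5 = fit_cosinor(shifted, 24.0)
        assert (fit5.acrophase_h - fit0.acrophase_h) % 24 == pytest.approx(5.0, abs=1e-8)

    def test_amplitude_invariant_to_offset(self):
        s = cosine_series(noise=0.5, days=7, seed=1)
        f1 = fit_cosinor(s, 24.0)
        s2 = BinnedSeries("s", "activity", H, s.t_start, s.values + 100.0)
        f2 = fit_cosinor(s2, 24.0)
        assert f1.amplitude == pytest.approx(f2.amplitude, abs=1e-9)
        assert f1.p_zero_amplitude == pytest.approx(f2.p_zero_amplitude, rel=1e-6)

    def test_latency_orientation_flips_phase(self):
        """A latency series peaks (fastest) 12 h from its value maximum."""
        s = cosine_series(mesor=300.0, amp=30.0, acro_h=4.0, days=7,
                          parameter="TS")
        lat = fit_cosinor(s, 24.0)          # latency orientation by default
        amp = fit_cosinor(s, 24.0, orientation="amplitude")
        assert lat.amplitude == pytest.approx(amp.amplitude, abs=1e-9)
        assert (lat.acrophase_h - amp.acrophase_h) % 24 == pytest.approx(12.0, abs=1e-8)
        assert lat.acrophase_h == pytest.approx(16.0, abs=1e-8)
        assert lat.mesor == pytest.approx(300.0, abs=1e-9)

    def test_insufficient_data_errors(self):
        t = H * np.arange(3)
        s = BinnedSeries("s", "activity", H, t, np.arange(3.0))
        with pytest.raises(ValueError, match="at least 4"):
            fit_cosinor(s, 24.0)


class TestAcrophaseSample:
    def make_fit(self, p, acro=10.0):
        from chronotap.types import CosinorFit

        return CosinorFit("s", "usage", 24.0, 1.0, 1.0, acro, p, 100)

    def test_all_significant_none_dropped(self):
        fits = [self.make_fit(0.001, a) for a in (1, 2, 3, 4)]
        sample = acrophase_sample(fits, 0.05)
        assert sample.excluded_fraction == 0.0
        assert sample.angles.size == 4

    def test_half_excluded(self):
        fits = [self.make_fit(0.001), self.make_fit(0.001),
                self.make_fit(0.5), self.make_fit(0.9)]
        assert acrophase_sample(fits, 0.05).excluded_fraction == 0.5

    def test_all_excluded_errors(self):
        with pytest.raises(ValueError, match="excluded"):
            acrophase_sample([self.make_fit(0.9)], 0.05)

    def test_null_cohort_exclusion_rate(self):
        """Pure-noise series: ~95% of subjects have no detectable rhythm."""
        rng = np.random.default_rng(9)
        from chronotap.cosinor import fit_cosinor as fc

        ps = []
        for i in range(200):
            t = H * np.arange(10 * 24)
            v = rng.normal(10, 1, t.size)
            ps.append(fc(BinnedSeries("s", "activity", H, t, np.maximum(v, 0.01)),
                         24.0).p_zero_amplitude)
        frac = np.mean(np.array(ps) < 0.05)
        assert frac == pytest.approx(0.05, abs=0.04)


def brute_watson_williams(groups):
    """Textbook formula computed step by step (independent of the package)."""
    import math

    def R(angles):
        C = sum(math.cos(a) for a in angles)
        S = sum(math.sin(a) for a in angles)
        return math.hypot(C, S)

    N = sum(len(g) for g in groups)
    k = len(groups)
    sumRi = sum(R(g) for g in groups)
    Rall = R([a for g in groups for a in g])
    rw = sumRi / N
    if rw < 0.53:
        kappa = 2 * rw + rw**3 + 5 * rw**5 / 6
    elif rw < 0.85:
        kappa = -0.4 + 1.39 * rw + 0.43 / (1 - rw)
    else:
        kappa = 1.0 / (rw**3 - 4 * rw**2 + 3 * rw)
    K = 1 + 3 / (8 * kappa)
    return K * ((N - k) * (sumRi - Rall)) / ((k - 1) * (N - sumRi))


class TestWatsonWilliams:
    def test_identical_groups_f_zero(self):
        g = np.array([0.1, 0.3, 0.5, 0.2])
        rec = watson_williams([g, g.copy()])
        assert rec.f == pytest.approx(0.0, abs=1e-10)
        assert rec.p == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 0.05, 20) % (2 * np.pi)
        b = (np.pi / 2 + rng.normal(0.0, 0.05, 20)) % (2 * np.pi)
        rec = watson_williams([a, b])
        assert rec.f > 50 and rec.p < 1e-6

    def test_matches_brute_force_small_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            groups = [rng.normal(m, 0.3, rng.integers(3, 5)) % (2 * np.pi)
                      for m in (0.2, 0.9, 1.5)]
            rec = watson_williams(groups)
            assert rec.f == pytest.approx(brute_watson_williams(groups), abs=1e-8)

    def test_low_concentration_warns(self):
        rng = np.random.default_rng(1)
        with pytest.warns(UserWarning, match="concentration"):
            watson_williams([rng.uniform(0, 2 * np.pi, 30) for _ in range(2)])


def brute_circ_corr(a, b):
    """Jammalamadaka-SenGupta r from explicit loops."""
    import math

    def cmean(x):
        return math.atan2(sum(math.sin(v) for v in x) / len(x),
                          sum(math.cos(v) for v in x) / len(x))

    am, bm = cmean(a), cmean(b)
    num = sum(math.sin(x - am) * math.sin(y - bm) for x, y in zip(a, b))
    d1 = sum(math.sin(x - am) ** 2 for x in a)
    d2 = sum(math.sin(y - bm) ** 2 for y in b)
    return num / math.sqrt(d1 * d2)


class TestCircCorr:
    def test_identity_r_one(self):
        a = np.array([0.1, 0.5, 1.0, 2.0, 3.0])
        rec = circ_corr(a, a.copy())
        assert rec.r == pytest.approx(1.0)

    def test_reflection_r_minus_one(self):
        a = np.array([0.1, 0.5, 1.0, 2.0, 3.0])
        rec = circ_corr(a, (-a) % (2 * np.pi))
        assert rec.r == pytest.approx(-1.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            a = rng.uniform(0, 2 * np.pi, 8)
            b = (a + rng.normal(0, 0.5, 8)) % (2 * np.pi)
            rec = circ_corr(a, b)
            assert rec.r == pytest.approx(brute_circ_corr(a, b), abs=1e-8)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 2 * np.pi, 30)
        b = (a + rng.normal(0, 0.8, 30)) % (2 * np.pi)
        rec = circ_corr(a, b)
        r_pg = pingouin.circ_corrcc(a, b)[0]
        assert rec.r == pytest.approx(float(r_pg), abs=1e-8)

    def test_independent_null(self):
        rng = np.random.default_rng(5)
        rs, ps = [], []
        for _ in range(50):
            a = rng.uniform(0, 2 * np.pi, 200)
            b = rng.uniform(0, 2 * np.pi, 200)
            rec = circ_corr(a, b)
            rs.append(rec.r)
            ps.append(rec.p)
        assert np.max(np.abs(rs)) < 0.25
        assert np.mean(np.array(ps) < 0.05) < 0.15

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            circ_corr(np.zeros(5), np.array([0.1, 0.2, 0.3, 0.4, 0.5]))


class TestPeakOffpeak:
    def test_noise_free_cosine_difference_2A(self):
        s = cosine_series(mesor=10.0, amp=2.0, acro_h=16.5, days=5)
        fit = fit_cosinor(s, 24.0)
        pk, off = peak_vs_offpeak(s, fit)
        assert pk - off == pytest.approx(2 * 2.0, abs=0.05)

    def test_flat_series_zero_difference(self):
        t = H * np.arange(72)
        s = BinnedSeries("s", "activity", H, t, np.full(72, 7.0))
        from chronotap.types import CosinorFit

        fit = CosinorFit("s", "activity", 24.0, 7.0, 0.0, 10.0, 1.0, 72)
        pk, off = peak_vs_offpeak(s, fit)
        assert pk == off == pytest.approx(7.0)


class TestModelFreePeak:
    def test_cosine_peak_hour(self):
        s = cosine_series(acro_h=16.5, days=4)
        assert model_free_peak(s) == 16

    def test_bimodal_larger_lobe(self):
        t = H * np.arange(48)
        h = (t / H) % 24
        v = 5 + 3 * np.exp(-0.5 * ((h - 9) / 1.5) ** 2) \
              + 2 * np.exp(-0.5 * ((h - 19) / 1.5) ** 2)
        s = BinnedSeries("s", "usage", H, t, v)
        assert model_free_peak(s) == 9

    def test_latency_orientation_takes_minimum(self):
        s = cosine_series(mesor=300.0, amp=30.0, acro_h=5.5, days=4,
                          parameter="US")
        # slowest at 5.5 h -> fastest at 17.5 h -> hour bin 17
        assert model_free_peak(s) == 17


class TestDayOfWeek:
    def weekly_series(self, day_values, weeks=3, parameter="usage"):
        # start on a Monday (epoch day 4 = 1970-01-05)
        start = 4 * 86400.0
        t = start + H * np.arange(weeks * 7 * 24)
        dow = (((t / 86400.0) + 3) % 7).astype(int)
        v = np.array([day_values[d] for d in dow], dtype=float)
        return BinnedSeries("s", parameter, H, t, v)

    def test_identical_days_f_zero(self):
        s = self.weekly_series([5.0] * 7)
        res = day_of_week_analysis(s)
        assert res.f == 0.0 and res.p == 1.0

    def test_weekend_peak(self):
        s = self.weekly_series([5, 5, 5, 5, 6, 9, 8], parameter="activity")
        res = day_of_week_analysis(s)
        assert res.peak_day in (5, 6)
        assert res.peak_angle == pytest.approx(2 * np.pi * res.peak_day / 7)

    def test_weekday_peak_latency(self):
        # US fastest on Wednesday: latency orientation picks day 2
        vals = [300, 295, 280, 300, 305, 320, 318]
        s = self.weekly_series(vals, parameter="US")
        res = day_of_week_analysis(s)
        assert res.peak_day == 2

    def test_needs_two_weeks(self):
        s = self.weekly_series([5, 5, 5, 5, 6, 9, 8])
        short = BinnedSeries("s", "usage", H, s.t_start[:7 * 24],
                             s.values[:7 * 24])
        with pytest.raises(ValueError, match="2 complete weeks"):
            day_of_week_analysis(short)


class TestAngles:
    def test_hours_angle_round_trip(self):
        h = np.array([0.0, 6.0, 12.0, 23.5])
        assert np.allclose(angle_to_hours(hours_to_angle(h)), h)

    def test_circular_mean_wraps(self):
        a = hours_to_angle(np.array([23.0, 1.0]))
        assert angle_to_hours(circular_mean(a)) == pytest.approx(0.0, abs=1e-9)

    def test_resultant_length_bounds(self):
        assert resultant_length(np.zeros(5)) == pytest.approx(1.0)
        assert resultant_length(np.array([0.0, np.pi])) == pytest.approx(0.0, abs=1e-12)
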