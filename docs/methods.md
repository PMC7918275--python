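# Methods

This note states the models, conventions, defaults, and numerical choices the
package implements, in one place. Units are SI unless noted; times are Unix
epoch seconds, and "clock hours" means `((t + utc_offset) mod 86400) / 3600`.

## 1. Event streams and binned parameters

An event stream is a time-sorted sequence of typed events: `touch`,
`screen_on`, `unlock_complete`, `home_shown`, `app_launch`, `screen_off`.
The grammar assumed (and produced by the generator) is
`screen_on → unlock_complete → home_shown → app_launch → … → screen_off`.

Four behavioural parameters are binned on a fixed grid of half-open intervals
`[t0 + k·w, t0 + (k+1)·w)` with default width `w = 3600 s`:

| parameter | definition | unit | missing rule |
|---|---|---|---|
| usage | touch count per bin | touches | empty bin = 0 |
| TS | 25th percentile of inter-touch intervals ≤ 30 s | ms | < 5 intervals → NaN |
| US | median screen-on → unlock latency | ms | no episodes → NaN |
| ALS | median home-shown → app-launch latency | ms | no episodes → NaN |

Rationale: the 25th percentile of inter-touch intervals tracks the fast,
habitual tapping mode while being robust to pauses; the 30 s gap cap excludes
between-session intervals. Unlock/app-locating episodes are stamped at the
completing event, matched to the nearest preceding starting event within the
same screen-on session, and discarded if longer than 60 s (distraction, not
speed). Counts from the wearable follow the same grid: `activity` is the sum
of per-epoch movement counts per bin, `lux` the mean ambient illuminance.

Latency parameters are "lower = faster" throughout; every analysis stage that
needs an orientation (cosinor acrophase, model-free peak, day-of-week peak)
negates latency series so the reported peak is the time of fastest
performance.

## 2. Spectral analysis (Lomb-Scargle)

Binned series are unevenly observed because latency bins can be missing.
Power is the classic normalized Lomb-Scargle periodogram: the Lomb power of
the mean-centered values divided by their sample variance (ddof = 1). Under
Gaussian white noise the expected power is 1 at every trial period, which
gives the cohort-level null below its natural scale. Numerically the power
equals `(n−1)R²/2`, where `R²` is from the no-intercept least-squares fit of
`cos(ωt)` and `sin(ωt)` to the mean-centered data — this identity (exact to
~1e-14) is the test oracle. A floating-mean (generalized) periodogram was
deliberately not used: with the mean removed beforehand the classic form has
the exact regression identity and the unit noise floor.

The period grid is linear in frequency from `2/L` to `1/T_min` (default
`T_min = 3 h`) with spacing `1/(4L)` (oversampling 4), where `L` is the series
span; periods are reported in hours, ascending. Cohort inference: at each
grid period, subject powers are tested against 1 with a one-sample one-sided
t-test, and Benjamini-Hochberg FDR at `q = 0.05` across the grid yields the
significance mask. Band summaries use a diurnal band of 16–32 h and an
infradian band of 120–216 h (5–9 days); within-band ties break toward 24 h
(diurnal) or the band center.

## 3. Cosinor and circular statistics

The fixed-period cosinor `x(t) = M + β cos(ωt) + γ sin(ωt)` (`ω = 2π/24 h`)
is fit by least squares at bin centers; amplitude `A = √(β²+γ²)`, acrophase
`φ = atan2(γ, β)/ω` converted to local clock time, zero-amplitude F-test with
(2, n−3) degrees of freedom. Subjects with `p ≥ 0.05` are excluded from group
acrophase samples and reported as an "arrhythmic fraction".

Group comparisons of acrophases use the Watson-Williams test with the
standard `K = 1 + 3/(8κ̂)` correction, `κ̂` from the Fisher (1993) piecewise
approximation of the pooled resultant length; a warning is raised when the
within-group resultant length is below 0.45, where the test is unreliable.
Circular-circular association is the Jammalamadaka-SenGupta correlation with
its asymptotic normal p-value. Day-of-week structure is tested by averaging
each parameter per weekday within complete weeks and running a
repeated-measures ANOVA across the seven weekdays.

## 4. Sleep scoring and sleep-anchored windows

Accelerometry is converted to one-minute activity counts and scored with the
Cole-Kripke (1992) one-minute weights `(404, 598, 326, 441, 1408, 508, 350)`
over epochs `i−4 … i+2`, scale `1e-5`, sleep iff the score `< 1`.
Consolidation drops sleep bouts shorter than 20 min, merges bouts separated
by gaps under 60 min, and keeps the longest bout per noon-to-noon local day
as that day's main sleep period. Weekday is computed from local time with
Monday = 0; "weekend nights" are those with onset on Friday, Saturday, or
Sunday.

Each main sleep period anchors three windows: `pre_bed = [onset − 1 h, onset)`,
`bed = [onset, offset)`, `rise = [offset, offset + 1 h)`. Latency episodes are
pooled across nights per window (TS: pooled 25th percentile; US/ALS: pooled
median); a subject enters the comparison only if all three windows have at
least 3 episodes (complete-case). Windows are compared with repeated-measures
ANOVA plus the three paired t-tests, and a weekday/weekend split reports
whether the paired mean differences agree in sign across the two subsets.

## 5. The synthetic generator

The generator emulates, per subject: (i) hourly touch counts as exact Poisson
draws with rate `λ(t) = λ₀ · (1 + a₂₄ cos) · (1 + a₇ cos) · awake(t)`
(defaults `λ₀ = 60/h`, `a₂₄ = 0.8` peaking at 16 h, `a₇ = 0.2` peaking on
Wednesday); (ii) touches organized into sessions whose inter-touch intervals
are lognormal with median 200 ms (TS); (iii) unlock and app-locating episodes
with lognormal latencies (medians 2000 and 1200 ms) whose medians are
multiplied by a diurnal factor (slowest at 4 h), an in-bed penalty, and a
sleep-inertia penalty decaying over ~45 min after rise; (iv) sleep from 23:30
to 07:30 with 30 min nightly jitter and a 60 min weekend delay, with a
probability 0.8 of any in-bed phone use; (v) wearable counts drawn from a
wake gamma / sleep exponential mixture and a day/night lux profile. Per-
subject randomness derives from `SeedSequence([seed, subject_index])`, so
cohorts are reproducible and extendable.

Not emulated: naps, shift work, missing-data bursts (device off), battery
artifacts, inter-subject chronotype differences beyond nightly jitter, and
non-stationary trends. These are the main caveats when reading pipeline
numbers as if they came from field data.

## 6. Problem sizes and numerical choices

The validation sizes are the package's own choices, picked to be decisive yet
fast: 20 subjects × 21 days for period recovery (three full weekly cycles;
~10 s), 200 series for the pure-noise FDR check (6,650 grid decisions), 30
subjects for the window-effect analysis (power > 0.99 for the injected 20%
slowing), 8 × 14 nights for sleep-timing recovery. `float64` throughout; the
Lomb-Scargle uses `scipy.signal.lombscargle`; ANOVAs use
`statsmodels.stats.anova.AnovaRM` and `scipy.stats`; no iterative solvers are
involved, so results are deterministic given the seed.

Open design decisions worth revisiting: the fixed 1-h pre-bed/rise window
lengths (configurable), the complete-case rule for window comparisons (a
mixed model would use partial data), the noon-to-noon main-sleep rule (naps
are discarded by construction), and the classic (non-floating-mean)
periodogram normalization (chosen for its exact oracle and unit noise floor).
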