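# chronotap

Chronobiology of smartphone touchscreen behaviour and wrist actigraphy:
rhythm detection, cosinor and circular statistics, sleep scoring, and
sleep-anchored behavioural comparisons — plus a fully specified synthetic
cohort generator for validating the whole pipeline against known ground truth.

## The scientific problem

Smartphone touchscreen logs ("tappigraphy") are a passive, high-resolution
record of human behaviour. From the raw event stream one can derive hourly
behavioural parameters:

- **usage** — touches per hour;
- **TS** (tapping speed) — the 25th percentile of inter-touch intervals within
  an hour, in ms (lower = faster);
- **US** (unlocking speed) — median latency from screen-on to unlock, in ms;
- **ALS** (app-locating speed) — median latency from home screen shown to app
  launch, in ms.

Alongside wrist-worn accelerometry (**activity** counts and ambient **lux**),
these series carry circadian (~24 h) and infradian (~7 d) structure, and they
change around sleep. The package answers three families of questions:

1. **Which periodicities does each parameter carry?** Series are unevenly
   observed (latencies are undefined in hours without enough episodes), so
   spectral analysis uses the Lomb-Scargle periodogram with the classic
   normalization: for observations `y(t_i)`, `P_N(T)` is normalized so that
   pure Gaussian noise has expected power 1 at every trial period `T`.
   Equivalently, `P_N = (n-1) R² / 2` where `R²` comes from the least-squares
   fit of `cos(2πt/T)` and `sin(2πt/T)` to the mean-centered data. At the
   cohort level, power at each grid period is tested against the white-noise
   expectation of 1 (one-sided t-test) with Benjamini-Hochberg FDR control
   across the grid.

2. **When in the day does each parameter peak?** A fixed-period cosinor
   `x(t) = M + A·cos(2π(t − φ)/24)` is fit per subject; `M` is the mesor, `A`
   the amplitude, and `φ` the acrophase in local clock hours. Latency series
   are negated before fitting so `φ` is the time of *fastest* performance.
   Acrophases are circular quantities: group comparisons use the
   Watson-Williams test and association uses the Jammalamadaka-SenGupta
   circular correlation.

3. **Does behaviour differ around sleep?** Actigraphy is scored minute by
   minute with the Cole-Kripke (1992) algorithm
   (`S = 1e-5 · Σ w_k · c_{i+k}`, k = −4..+2, sleep iff `S < 1`), short bouts
   dropped and near-adjacent bouts merged, keeping the longest sleep period
   per noon-to-noon day. Each night anchors three windows — the hour before
   bed (`pre_bed`), time in bed (`bed`), and the hour after rise (`rise`) —
   and pooled per-window parameters are compared with repeated-measures ANOVA
   plus paired t-tests.

## The synthetic generator

`chronotap.synth` generates event streams and wearable series from an explicit
behavioural model: hourly touch counts are exact Poisson draws whose rate is
modulated by a 24-h cosine (relative amplitude 0.8, acrophase 16 h), a weekly
cosine (amplitude 0.2), and the sleep/wake cycle; latencies are lognormal with
multiplicative diurnal, in-bed, and sleep-inertia modifiers; sleep runs
~23:30–07:30 with nightly jitter and a weekend delay. The generator returns
ground truth (true sleep times, true parameters) so every analysis stage can
be validated quantitatively. Its defaults are the modeled study conditions,
not tuned knobs.

## Worked example

```bash
python examples/02_rhythms.py
```

prints (8 synthetic subjects, 21 days, seed 12):

```
parameter   diurnal peak (h)  mean power
usage                  24.00       224.4
TS                     24.00        71.0
US                     24.00        35.0
ALS                    24.00         9.6
activity               24.00       157.1
lux                    24.00       203.3

usage ~weekly band: peak at 166.4 h (= 6.93 d), significant after FDR: True
```

and `python examples/04_sleep_and_windows.py` (12 subjects, seed 5):

```
sleep onset recovery over 240 nights: median error 3.9 min, max 5.0 min

unlocking speed by window (n = 12 subjects):
  pre_bed     2058 ms
  bed         2612 ms
  rise        2212 ms
repeated-measures ANOVA: F(2,22) = 32.8, p = 2.5e-07
  bed_vs_pre_bed       t(11) =   6.21, p = 6.6e-05
  bed_vs_rise          t(11) =   5.14, p = 0.00032
  pre_bed_vs_rise      t(11) =  -4.94, p = 0.00044
```

People in this synthetic cohort unlock their phones ~25% more slowly in bed —
exactly the effect the generator injects. The other examples
(`01_simulate_and_extract.py`, `03_cosinor.py`) walk through parameter
extraction and the cosinor/circular-statistics layer.

A thin CLI wraps the same pipeline:

```bash
chronotap simulate --config synth.yaml --seed 5 --out cohort/
chronotap extract --events cohort/synth000_events.csv --out params.csv
chronotap sleep --wearable cohort/synth000_wearable.csv --out sleep.csv
chronotap rhythms --params params.csv --out rhythms/
```

## Layout

- `src/chronotap/` — library (`io`, `tappigraphy`, `actigraphy`, `rhythms`,
  `cosinor`, `circular`, `sleepwindows`, `synth`, `pipeline`, `cli`)
- `examples/` — narrative scripts, one per capability
- `scripts/acceptance.py` — end-to-end reproduction script
- `docs/methods.md` — methods note: models, defaults, numerical choices
- `tests/` — unit, property-based, integration, and acceptance tests
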