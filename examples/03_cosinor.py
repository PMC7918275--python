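"""Cosinor fits and circular statistics on cohort acrophases.

A fixed 24-h cosinor is fit per subject and parameter; latency series are
negated first so the acrophase is the clock time of *fastest* performance.
Acrophases are then compared across parameters with circular statistics.
"""

import numpy as np

from chronotap import AnalysisConfig, pipeline, synth
from chronotap.circular import (
    angle_to_hours,
    circ_corr,
    circular_mean,
    watson_williams,
)

cfg = AnalysisConfig()
cohort = synth.generate_cohort(synth.SynthConfig(n_subjects=10, days=21, seed=8))
per_subject = pipeline.cohort_parameters([(s, w) for s, w, _ in cohort], cfg)
summary = pipeline.cosinor_summary(per_subject, cfg)

angles = {}
print(f"{'parameter':10s} {'mean acrophase (h)':>19s} {'rhythmic subjects':>18s}")
for param in ("usage", "TS", "US", "lux"):
    s = summary[param]
    if s.sample is None:
        continue
    angles[param] = s.sample.angles
    mean_h = float(angle_to_hours(circular_mean(s.sample.angles))) % 24
    print(f"{param:10s} {mean_h:19.2f} "
          f"{s.sample.angles.size:>10d}/{len(s.fits)}")

ww = watson_williams([angles["usage"], angles["TS"], angles["US"]])
print(f"\nWatson-Williams (usage vs TS vs US acrophases): "
      f"F({2},{ww.df2}) = {ww.f:.2f}, p = {ww.p:.3f}")

cc = circ_corr(angles["usage"], angles["US"])
print(f"circular correlation usage vs US acrophase: r = {cc.r:.2f}, "
      f"p = {cc.p:.3f}")
print("interpretation: all behavioural acrophases land within ~15 min of the "
      "16 h target while light peaks mid-day; note that with tightly "
      "concentrated angles the Watson-Williams test can flag even such "
      "minute-scale offsets between parameters.")
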