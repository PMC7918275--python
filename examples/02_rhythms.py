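"""Lomb-Scargle rhythm analysis of a small synthetic cohort.

Each subject's hourly series (with missing night-time latency bins) goes
through a normalized Lomb-Scargle periodogram; the cohort-level test asks,
period by period, whether mean power exceeds the white-noise expectation of 1,
controlling the false discovery rate across the grid.
"""

from chronotap import AnalysisConfig, pipeline, synth

cfg = AnalysisConfig()
cohort = synth.generate_cohort(synth.SynthConfig(n_subjects=8, days=21, seed=12))
per_subject = pipeline.cohort_parameters([(s, w) for s, w, _ in cohort], cfg)
pgs = pipeline.cohort_periodograms(per_subject, cfg)
summary = pipeline.rhythm_summary(pgs, cfg)

print(f"{'parameter':10s} {'diurnal peak (h)':>17s} {'mean power':>11s}")
for param in ("usage", "TS", "US", "ALS", "activity", "lux"):
    r = summary[param]
    print(f"{param:10s} {r.mean_diurnal_peak_h:17.2f} {r.mean_diurnal_power:11.1f}")

usage = summary["usage"]
print(f"\nusage ~weekly band: peak at {usage.mean_infradian_peak_h:.1f} h "
      f"(= {usage.mean_infradian_peak_h / 24:.2f} d), "
      f"significant after FDR: {usage.infradian_significant}")
print("interpretation: every parameter carries a clean 24-h rhythm, and the "
      "weekly modulation built into usage shows up as a ~7-day band peak.")
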