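"""Full pipeline: simulate, measure ROIs with two readers, and summarize.

Runs a 12-subject, 3-visit cohort under the default study conditions,
extracts the fixed-area circular ROI measurements for two readers with
placement jitter, and computes the repeatability/reproducibility report.
"""

from natsc import default_landmarks, measure_all, simulate_cohort, summarize

cohort = simulate_cohort(n_subjects=12, seed=7)
measurements = measure_all(
    cohort, default_landmarks(cohort.config), jitter_sd_mm=1.0, seed=7
)
print(f"{len(measurements)} ROI measurements "
      "(12 subjects x 3 visits x 2 readers x 11 landmarks)")

report = summarize(measurements, seed=7)
print()
print(report.render())
print()
lat = report.laterality.set_index("region")
print("caudate-head laterality: "
      f"left {lat.loc['HCN', 'left_mean']:.1f} vs "
      f"right {lat.loc['HCN', 'right_mean']:.1f} mmol/kg WW, "
      f"p = {lat.loc['HCN', 'p']:.4f}")
print()
print("family-wise (max-t) visit-contrast p per region:")
print({k: round(v, 3) for k, v in report.family_p.items()})
print()
print(
    "The simulator applies no systematic visit effect, so visit means "
    "agree closely; with this many uncorrected tests an occasional "
    "p < 0.05 is expected by chance (no multiplicity correction is "
    "applied across regions).  The pooled r^2 near 1 reflects that "
    "between-subject spread dominates session noise.  The caudate head "
    "carries a configured +4.4 mmol/kg left-right offset, which the "
    "paired sign-flip test detects."
)
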