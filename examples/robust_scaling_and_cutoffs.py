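"""Robust-scale a cohort and fit percentile outlier cutoffs.

Each protein is standardized by its pooled median and MAD (no consistency
constant), then the outlier cutoffs are taken as the 1st/99th percentiles of
the pooled score distribution and the spike cutoff as the 99th percentile of
adjacent-draw |Δscore|.
"""

from madtrack import SimulationConfig, fit_thresholds, generate_cohort, scale_cohort

cohort, _ = generate_cohort(SimulationConfig(n_cases=5, n_controls=30, n_proteins=120, seed=42))
scaled = scale_cohort(cohort)
thresholds = fit_thresholds(scaled)

ref = scaled.references
print(f"proteins analyzed: {len(scaled.analyzed_proteins)} of {len(ref)} "
      f"({int(ref.degenerate.sum())} degenerate)")
print(f"lower cutoff: {thresholds.lower:.3f} MAD (percentile {thresholds.lower_pct:g})")
print(f"upper cutoff: {thresholds.upper:.3f} MAD (percentile {thresholds.upper_pct:g})")
print(f"delta cutoff: {thresholds.delta:.3f} MAD (percentile {thresholds.delta_pct:g} of |dMAD|)")
# On Gaussian null data the upper cutoff approaches z_0.99/0.6745 ~ 3.45;
# a score above it (or below the lower cutoff) is a single-observation outlier,
# and an adjacent-draw change beyond the delta cutoff is a spike.
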