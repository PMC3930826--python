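"""Inclusion criteria and the trim/thin robustness variants.

Checks the per-decade design of a simulated cohort, then builds the two
dataset variants used to probe age-position stability: an age-window trim
and a half-resolution thinning that preserves the decade distribution.
"""

from agebend import (
    SimulationConfig,
    check_design,
    simulate_dataset,
    thin_dataset,
    trim_dataset,
)

dataset, _ = simulate_dataset(SimulationConfig(n_samples=72, seed=3))

report = check_design(dataset)
print(f"n = {report.n_samples}, ages {report.age_min:.0f}-{report.age_max:.0f}, "
      f"meets criteria: {report.meets_criteria}")
print("per-decade counts:",
      {f"{10 * d}s": c for d, c in report.per_decade_counts.items()})

trimmed = trim_dataset(dataset, 36, 95)
print(f"trimmed to 36-95: {trimmed.n_samples} samples "
      f"(ages {trimmed.ages.min():.0f}-{trimmed.ages.max():.0f})")

half = thin_dataset(dataset, keep=0.5)
print(f"half-resolution: {half.n_samples} samples, per-decade counts",
      {f"{10 * d}s": c for d, c in check_design(half).per_decade_counts.items()})
print("Thinning drops every other sample within each decade, so the age "
      "distribution keeps its shape at half the resolution.")
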