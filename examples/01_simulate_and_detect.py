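"""Simulate a cross-sectional aging study and locate its age-positions.

Generates 60 subjects aged 25-95 with 2000 probes, of which 2 x 300 carry
reciprocal trends bending at 45 and 75 years, then runs the full pipeline:
sex correction, quadratic filtering, absolute-correlation clustering and
bend detection with cross-k ranges.
"""

from agebend import SimulationConfig, run_pipeline, score_recovery, simulate_dataset

dataset, truth = simulate_dataset(SimulationConfig(seed=7))
result = run_pipeline(dataset, seed=1)

print(f"significant probes at p < 0.05: {len(result.significant_probe_ids)} "
      f"of {dataset.n_probes}")
for pos in result.positions:
    print(f"age-position {pos.age:5.1f} +/- {pos.range:.0f} y "
          f"({pos.method}; {len(pos.probe_ids)} probes, "
          f"{pos.n_up} up / {pos.n_down} down)")

report = score_recovery(truth, result.positions, result.significant_probe_ids)
print(f"filter recall of true signal probes: {report['recall']:.3f}; "
      f"direction accuracy: {report['direction_accuracy']:.3f}")
print("True bends sit at 45 and 75; detected crossings sit a few years "
      "toward the range center — the resolution limit of quadratic smoothing.")
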