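# agebend

**Age-regulated expression trends and age-position detection in
cross-sectional transcriptome datasets.**

Biological aging is rarely linear. In cross-sectional expression studies —
one transcriptome per subject, subjects spanning several decades — many
transcripts do not drift steadily with age but hold level and then *bend*
at a particular chronological age. `agebend` implements a five-step
statistical methodology that finds those bends:

1. **Screen** the whole dataset for age association with a permutation
   score test (statistic `Q = mean_g [(z_g · ã)² / (n−1)]`, where `z_g` is
   the standardized expression profile of probe `g` and `ã` the centered
   age vector; the null distribution comes from shuffling age labels).
   Sex is removed beforehand as an additive per-probe effect.
2. **Smooth** each probe's expression-versus-age relationship. Five model
   families are supported — linear, quadratic and cubic polynomials, an
   unpenalized quadratic B-spline, and LOESS — and compared genome-wide by
   leave-one-out cross-validation with pairwise Wilcoxon signed-rank tests.
   The quadratic `y = β₀ + β₁t + β₂t²` is the working default: flexible
   enough to bend, hard to overfit.
3. **Filter** probes with the F-test of the quadratic model against the
   intercept-only null, `F = [(SSE₀ − SSE₂)/2] / [SSE₂/(n−3)]`, keeping
   unadjusted `p < 0.05` (the dataset-level screen is the other filter; a
   companion permutation summary quantifies the false-positive load).
4. **Cluster** the centered smoothed trends with k-means — Euclidean
   distance for distinct shapes, or absolute-correlation distance
   `d(x, c) = 1 − |r(x, c)|`, which treats a trend and its mirror image as
   identical and so merges reciprocal up/down pairs into one cluster.
   Cluster spread is reported as point-wise 95th/99th percentile bands and
   stability as the fraction of restarts reaching the same partition.
5. **Locate the age-position**: within each absolute-correlation cluster,
   the age where the two reciprocal subgroup mean trends intersect
   (equivalently, where the 95th-percentile band pinches tightest around
   the centroid). Its ± range is the half-spread of matched estimates
   across k = 2, 3, 4; member probes are counted as up- or down-regulated
   past the bend.

A first-class synthetic-data generator (`agebend.simulate`) emulates such
studies — even per-decade age coverage, thousands of null probes, a
minority of reciprocal sigmoid-bend trends, additive sex effects — and
returns the ground truth needed to score every stage.

## Worked example

```sh
python examples/01_simulate_and_detect.py
```

```
significant probes at p < 0.05: 678 of 2000
age-position  50.3 +/- 6 y (intersection; 337 probes, 176 up / 161 down)
age-position  69.2 +/- 3 y (intersection; 341 probes, 169 up / 172 down)
filter recall of true signal probes: 1.000; direction accuracy: 0.918
```

The simulated cohort (60 subjects, ages 25–95) carries 300 reciprocal
signal probes bending at 45 years and 300 more at 75 years among 1400 pure
noise probes. The filter recovers essentially all signal probes at a ~5%
false-positive rate, clustering splits them cleanly by bend age, and the
two detected age-positions bracket the truth. The detected crossings sit a
few years toward the middle of the age range — the intrinsic resolution of
quadratic smoothing for off-center bends (see `docs/methods.md`); the ±
range reflects agreement across k = 2, 3, 4 clusterings.

The other scripts in `examples/` walk through model comparison
(`02_model_comparison.py`), the permutation null for the significant-probe
count (`03_permutation_null.py`), gene-set enrichment with ontology
grouping (`04_enrichment.py`), and the design checks plus trim/thin
robustness variants (`05_design_and_robustness.py`). Everything is also
reachable from the `agebend` command line (`agebend --help`), which wraps
the same library calls for TSV-file workflows.

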