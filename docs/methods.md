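# Methods

This note documents the statistical model behind `agebend`, the parameters
that matter, what the synthetic-data generator does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Data model and study design

The unit of analysis is a probe × sample matrix of log2 expression values
with per-sample age (years) and sex. Datasets are assumed cross-sectional:
one measurement per subject, no repeated measures. The design check
(`dataio.check_design`) encodes the inclusion criteria used throughout:
at least 25 subjects and a non-empty decade bin for every decade
intersecting [max(40, age_min), age_max]. Decade bins are half-open
[10d, 10(d+1)) with real-valued ages binned by floor(age/10).

Two dataset variants support robustness analysis: `trim_dataset` restricts
the age window (to probe how the detected bend ages depend on the cohort's
age range), and `thin_dataset` halves the resolution by sorting each
decade's samples by age and keeping alternate ones starting from the
first — a deterministic realization of "drop every other sample while
preserving the decade distribution". The tie-break (first-kept after a
stable age sort) is one of several equally defensible choices.

## Pre-processing

* **Normalization** (`normalize_glog`): arrays are rescaled
  multiplicatively so all column medians match the median of column
  medians, then values become log2(x + offset), offset 1 by default. This
  is a deliberately simple generalized-log: it removes per-array scale and
  damps the intensity-variance relationship. The pipeline equally accepts
  matrices normalized by heavier machinery (VSN and friends) upstream; a
  `normalized` flag prevents accidental double transformation.
* **Sex correction** (`correct_sex`): per probe, each sex group's mean is
  subtracted and the probe's grand mean restored. This removes exactly an
  additive sex offset, is idempotent, and leaves age-trend curvature
  untouched. More elaborate sex-by-age interactions are out of scope.
* **Dataset-level screen** (`global_age_test`): the score statistic
  Q = mean over probes of (z_g · ã)²/(n−1) summarizes genome-wide
  association between expression and age; its null distribution is built
  by permuting the age labels (B = 999 by default; p = (1 + #{Q_perm ≥
  Q_obs})/(B+1), so p ≥ 1/(B+1)). Zero-variance probes are dropped with a
  logged count. The permutation form was chosen over an asymptotic
  reference distribution so that the declared null — "no age
  association" — is exactly what is simulated; consequently p-values have
  permutation granularity. A dataset failing the screen (p ≥ 0.05) can
  still be pushed through the pipeline, but its positions are expected to
  be unstable and its filtered probes rich in false positives.

## Trend smoothing and filtering

Five per-probe smoothing families are implemented (`trendfit`):

| model     | form                                   | knobs (default)        |
|-----------|----------------------------------------|------------------------|
| linear    | β₀ + β₁t                               | —                      |
| quadratic | β₀ + β₁t + β₂t²                        | —                      |
| cubic     | up to β₃t³                             | —                      |
| qbspline  | degree-2 B-spline, unpenalized LSQ     | interior knots (2, at age terciles) |
| loess     | tri-cube-weighted local quadratic      | span (0.75)            |

Polynomials are fit on standardized ages for conditioning and reported on
the raw-age scale. The LOESS is written in-house because held-out
prediction at arbitrary ages is required for cross-validation, which
off-the-shelf local-linear smoothers do not expose; its span is surfaced
as configuration since it is the method's main tuning knob. B-spline
interior knots default to age terciles — a deterministic, data-adaptive
rule chosen in the absence of any principled alternative.

Model families are compared by leave-one-out cross-validation: each sample
is held out, the model refit, and the held-out value predicted; the
per-probe mean squared prediction error feeds pairwise two-sided Wilcoxon
signed-rank tests, and the family with the smallest mean error wins. On
curved trends the quadratic typically halves the linear model's LOOCV
error. A caveat worth knowing: when the truth is *exactly* quadratic, the
cubic's extra term carries a small (~3% here) but systematic LOOCV
penalty, so a well-powered paired test will call quadratic *significantly*
better than cubic even though the two are practically equivalent —
statistical distinguishability and practical equivalence diverge for
adequately large probe panels.

Probe filtering tests the quadratic model against the intercept-only null
with F = [(SSE₀ − SSE₂)/2]/[SSE₂/(n−3)] on (2, n−3) degrees of freedom,
keeping p < α (default 0.05) *unadjusted*. No multiple-testing correction
is applied at this stage by design: filtering is one of two dataset-level
gates, and the permutation summary (below) directly measures the
false-positive load instead. Degenerate cases: a constant probe gets
p = 1; an exact quadratic fit (SSE₂ ≤ 10⁻¹²·SSE₀) gets the smallest
positive double. The batched implementation (`quadratic_fit_table`) shares
one design matrix across all probes and is numerically identical to the
per-probe path.

## Permutation summary

`permtest.permutation_summary` shuffles age and sex labels jointly against
the expression columns (sex travels with age so the per-permutation sex
correction stays coherent), re-runs correction + filtering per
permutation, and reports the chronological significant count Cs against
the permuted counts Ps: mean ± SE, the #{Ps>Cs}/#{Ps<Cs} ratio (ties
excluded and reported separately), and Cs − mean(Ps) as an estimate of the
truly age-associated probe count. A master seed spawns per-permutation
seeds, so runs are reproducible.

## Clustering

Smoothed trends are evaluated on a 1-year grid spanning the observed age
range and centered by their grid mean, so clustering sees shape, not
level. Lloyd-style k-means is implemented for two metrics:

* **euclidean** — squared distance; centroids are member means; the
  objective is the classical within-cluster SSE.
* **abscorrelation** — d(x, c) = 1 − |Pearson r(x, c)|, with r defined as
  0 against a zero-variance vector so flat trends remain clusterable.
  Centroid update: members negatively correlated with the current centroid
  are sign-flipped before averaging, making the centroid the
  orientation-representative mean. This update is a declared design
  choice, validated by its invariances (affine invariance of the distance;
  mirrored trends at distance 0) rather than by matching any particular
  legacy implementation.

Initialization is k-means++ (D² seeding) under the active metric, the
standard smart seeding of mainstream k-means implementations; 25 restarts
by default with the best objective kept. Empty clusters are re-seeded at
the farthest probe. Cluster spread is summarized by point-wise percentile
bands (central 95%/99% intervals of member values per grid age; clusters
under 3 members fall back to min/max with a warning). Stability is scored
by re-clustering along a descending k schedule (24, 16, 12, 8, 6, 4) and
reporting, per k, the fraction of restarts whose final partition equals
the best one up to label permutation; the recommended k is the smallest
with fraction ≥ 0.5.

## Age-position estimation

Within an absolute-correlation cluster, probes are split by the sign of
their correlation with the centroid into two reciprocal subgroups. The
age-position is the age where the two subgroup mean trends cross (linear
interpolation between grid points of the sign change of their
difference). With several crossings, the one with the narrowest
95th-percentile band wins, ties to the earliest age. If no crossing
exists — one-signed clusters, for instance — the fallback is the grid age
minimizing the band half-width, and the result records which rule fired.
A flat cluster raises an error rather than inventing a position.

The ± range comes from re-clustering at k = 2, 3, 4: positions at higher k
are matched to the nearest k = 2 reference, and the range is
ceil((max − min)/2) of the matched estimates. Up/down counts classify each
member probe by whether its centered trend at the oldest grid age exceeds
its value at the position age — one concrete reification of "rising vs
falling past the bend"; alternatives (sign over the whole range) would
differ for non-monotone trends.

**Resolution limit.** The intersection estimator finds where the *smoothed*
trend crosses its own mean. Two systematic offsets follow for a sigmoid
bend that sits off-center in the age range: the sigmoid itself crosses its
mean hw·logit(S̄) years from the bend (≈ 2.7 y for a bend 20 years from
the range edge, half-width 3), and the quadratic projection drags the
crossing several more years toward the range center (a line crosses its
mean exactly at the mean age; a parabola only partially corrects). In the
standard simulation (bends at 45 and 75 in a 25–95 cohort) the combined
displacement is ≈ 6 years inward, stable across noise realizations — the
estimator is precise (sd ≈ 0.7 y) but biased for off-center sharp bends,
and effectively unbiased for mid-range bends. Narrower cohort windows
around a suspected bend reduce the bias; this is also why detected
positions shift when the cohort's age range is trimmed.

## Enrichment

Age-position gene lists (probes collapsed to unique gene ids; a gene is in
the list if any of its probes is) are tested per gene set with a one-sided
Fisher's exact test (upper hypergeometric tail) against a user-stated
background. Sets are intersected with the background first; sets smaller
than 10 or larger than 1000 members are discarded as too specific/generic,
and exact-duplicate member sets collapse to the lexicographically first
id. Benjamini–Hochberg q-values are optional (`fdr=True`), with
significance then judged on q. Significant ontology terms are grouped by
shared ancestry in the OBO is_a DAG: two terms group together when they
share a non-root common ancestor (a term counting as its own ancestor);
groups are connected components of that relation, labelled by their
lexicographically smallest member. Roots are excluded as uninformative.
Connecting terms directly to shared ancestors (rather than inducing a
subgraph on the DAG) keeps terms whose common ancestor is a grandparent in
one group even when intermediate nodes are not themselves significant.

## Synthetic data

`simulate.simulate_dataset` draws ages evenly per decade (equal counts,
remainder to the oldest decades, uniform within a decade), balanced sexes,
per-probe Gaussian baselines (mean 8, sd 1.5 log2 units), and builds
signal trends as baseline + direction·Δ·S((t − bend)/hw) with S the
logistic sigmoid — a smooth bend rather than a hard change-point, matching
how expression trends actually turn. Defaults define the package's
standard study conditions: 60 samples aged 25–95, 2000 probes, bends at 45
and 75 years with 300 reciprocal signal probes each (half up, half down),
Δ = 1 log2 unit total change, half-width 3 years, residual sd 0.5. A sex
offset (sd 0.5) is added to a random 30% of probes — enough to matter if
left uncorrected, realistic in magnitude. All randomness flows from one
master seed in a fixed draw order, so identical configs are bit-identical.

What the generator does *not* emulate: probe–probe correlation (co-
expression), batch and spatial array artifacts, heavy-tailed noise,
age-dependent variance, survivorship effects in the oldest decades, and
cell-composition drift. Passing recovery tests on this generator therefore
demonstrates the statistical machinery works as specified under clean
additive-noise conditions; it does not certify performance against the
full messiness of real cohorts.

## Problem sizes and numerical choices

Validation runs use the standard 2000 × 60 simulation (20 seeds) for
pipeline recovery, 2000 × 30 noise panels for type-I checks (200 runs for
the uniformity test with B = 999 permutations), a 100-probe × 40-sample
panel for the LOOCV model comparison, and 100 permutations per
permutation-summary run — sizes chosen so the entire validation executes
in minutes on a single core while keeping binomial/KS error bars tight
enough to be meaningful. Other defaults: p-value floor at the smallest
positive double; Lloyd capped at 300 iterations (convergence is flagged);
percentile bands via linear-interpolation empirical quantiles; all
correlation computations clip to [−1, 1] before the distance transform.
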