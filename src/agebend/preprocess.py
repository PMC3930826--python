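"""Normalization, sex-effect removal and the dataset-level age-association test.

The screening question — "does this dataset carry any age signal at all?" —
is answered by a permutation score test: the observed statistic Q averages,
over probes, the squared covariance between the standardized probe profile
and the centered age vector; its null distribution comes from shuffling the
age labels. Datasets failing the screen (p >= 0.05 by default) are expected
to yield unstable downstream trends.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .dataio import ExpressionDataset

__all__ = [
    "GlobalTestResult",
    "normalize_glog",
    "correct_sex",
    "global_age_test",
    "DEFAULT_SCREEN_ALPHA",
]

logger = logging.getLogger(__name__)

#: Dataset-level screening threshold for calling a dataset age-regulated.
DEFAULT_SCREEN_ALPHA = 0.05


@dataclass
class GlobalTestResult:
    """Dataset-level age-association statistic and its permutation p-value."""

    statistic: float
    n_permutations: int
    p_value: float
    permuted_statistics: np.ndarray
    n_probes_dropped: int = 0

    def __post_init__(self):
        self.permuted_statistics = np.asarray(self.permuted_statistics, float)


def normalize_glog(dataset: ExpressionDataset, offset: float = 1.0) -> ExpressionDataset:
    """Median-scale arrays in raw space, then apply a shifted log2.

    Each array (column) is rescaled multiplicatively so all column medians
    equal the median of the original column medians, then every value x is
    replaced by log2(x + offset). The shifted log stabilizes the variance of
    high-intensity probes while keeping low intensities finite.
    """
    if dataset.normalized:
        raise ValueError("dataset is already normalized; refusing to re-normalize")
    if offset < 0:
        raise ValueError("offset must be non-negative")
    x = dataset.values
    if np.any(x < 0):
        raise ValueError("raw intensities must be non-negative")
    col_medians = np.median(x, axis=0)
    if np.any(col_medians <= 0):
        raise ValueError("per-array median must be positive for median scaling")
    target = float(np.median(col_medians))
    scaled = x * (target / col_medians)
    values = np.log2(scaled + offset)
    return replace(dataset, values=values, normalized=True)


def correct_sex(dataset: ExpressionDataset) -> ExpressionDataset:
    """Remove the additive per-probe sex effect.

    For every probe, each sex group's mean is subtracted and the probe's
    grand mean added back, equalizing within-probe sex-group means while
    leaving the probe's overall level untouched. Idempotent; a single-sex
    dataset is returned unchanged with a warning.
    """
    sexes = np.asarray(dataset.sex)
    present = set(sexes)
    if len(present) < 2:
        warnings.warn("single-sex dataset: sex correction skipped", stacklevel=2)
        return dataset
    values = dataset.values.copy()
    grand = values.mean(axis=1, keepdims=True)
    for s in present:
        mask = sexes == s
        group_mean = values[:, mask].mean(axis=1, keepdims=True)
        values[:, mask] += grand - group_mean
    return replace(dataset, values=values)


def _score_statistic(z: np.ndarray, centered_ages: np.ndarray) -> float:
    n = z.shape[1]
    proj = z @ centered_ages
    return float(np.mean(proj**2) / (n - 1))


def global_age_test(
    dataset: ExpressionDataset,
    n_permutations: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
) -> GlobalTestResult:
    """Permutation test of dataset-wide association between expression and age.

    Q = mean over probes of (standardized probe row . centered ages)^2/(n-1);
    the null distribution permutes the age labels. With ``exhaustive=True``
    all n! - 1 non-identity orderings are enumerated instead of sampled
    (only sensible for very small n).

    The p-value is (1 + #{permuted Q >= observed Q}) / (B + 1), so it never
    drops below 1/(B+1). Zero-variance probe rows are dropped (standardization
    undefined) with a logged count.
    """
    ages = dataset.ages.astype(float)
    n = len(ages)
    if np.ptp(ages) == 0:
        raise ValueError("age vector has zero variance")
    if not exhaustive and n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")

    x = dataset.values
    sd = x.std(axis=1, ddof=1)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("global_age_test: dropped %d zero-variance probes", n_dropped)
    x = x[keep]
    if x.shape[0] == 0:
        raise ValueError("no probes with non-zero variance")
    z = (x - x.mean(axis=1, keepdims=True)) / sd[keep][:, None]
    a_c = ages - ages.mean()
    observed = _score_statistic(z, a_c)

    if exhaustive:
        perms = [p for p in itertools.permutations(range(n))
                 if p != tuple(range(n))]
        perm_matrix = np.array([a_c[list(p)] for p in perms]).T  # n x B
    else:
        rng = np.random.default_rng(seed)
        perm_matrix = np.empty((n, n_permutations))
        for b in range(n_permutations):
            perm_matrix[:, b] = a_c[rng.permutation(n)]
    proj = z @ perm_matrix  # probes x B
    permuted = np.mean(proj**2, axis=0) / (n - 1)
    b_eff = perm_matrix.shape[1]
    p = (1 + int(np.sum(permuted >= observed))) / (b_eff + 1)
    return GlobalTestResult(
        statistic=observed,
        n_permutations=b_eff,
        p_value=p,
        permuted_statistics=permuted,
        n_probes_dropped=n_dropped,
    )
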