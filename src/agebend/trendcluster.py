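"""Clustering of centered expression trends.

Smoothed per-probe trends are evaluated on a one-year age grid and centered
(row mean subtracted), so clustering groups by trend *shape* rather than
expression level. Two k-means variants are provided: classical Euclidean
Lloyd iteration, and an absolute-correlation variant with distance
d(x, c) = 1 - |Pearson r(x, c)| that treats a trend and its mirror image as
identical — this is what merges reciprocal up/down trend pairs into one
cluster whose internal crossing defines the age-position. Cluster spread is
summarized by point-wise 95th/99th percentile reference bands, and cluster
stability by the fraction of random restarts converging to the same
partition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .trendfit import TrendFit

__all__ = [
    "TrendMatrix",
    "ClusterResult",
    "center_trends",
    "trend_matrix_from_table",
    "kmeans_trends",
    "percentile_bands",
    "stability_scan",
    "abscorrelation_distance",
]

logger = logging.getLogger(__name__)

MAX_ITER = 300


@dataclass
class TrendMatrix:
    """Centered smoothed trends on a common age grid (rows mean-zero)."""

    probe_ids: list
    age_grid: np.ndarray
    trends: np.ndarray  # probes x grid, log2 fold change about probe mean

    def __post_init__(self):
        self.probe_ids = list(self.probe_ids)
        self.age_grid = np.asarray(self.age_grid, dtype=float)
        self.trends = np.asarray(self.trends, dtype=float)
        if np.any(np.diff(self.age_grid) <= 0):
            raise ValueError("age grid must be strictly increasing")
        if self.trends.shape != (len(self.probe_ids), len(self.age_grid)):
            raise ValueError("trend matrix shape mismatch")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


@dataclass
class ClusterResult:
    """k-means output: assignments, centroid trends, percentile bands."""

    k: int
    metric: str
    assignments: np.ndarray  # probe -> cluster index
    centroids: np.ndarray  # k x grid
    within_sse: np.ndarray  # per-cluster within-distance
    total_within_sse: float
    bands: dict = field(default_factory=dict)  # q -> {cluster: (lower, upper)}
    converged: bool = True
    n_iterations: int = 0

    def members(self, cluster: int) -> np.ndarray:
        return np.nonzero(self.assignments == cluster)[0]


def default_age_grid(age_min: float, age_max: float, step: float = 1.0) -> np.ndarray:
    """One-year evaluation grid spanning the observed age range."""
    n = int(np.floor((age_max - age_min) / step))
    grid = age_min + step * np.arange(n + 1)
    if grid[-1] < age_max - 1e-9:
        grid = np.append(grid, age_max)
    return grid


def center_trends(fits: dict, age_grid) -> TrendMatrix:
    """Evaluate fitted trends on a grid and subtract each probe's mean.

    ``fits`` maps probe id -> :class:`~agebend.trendfit.TrendFit`. The grid
    must lie inside every fit's age range (no extrapolation).
    """
    age_grid = np.asarray(age_grid, dtype=float)
    probe_ids = list(fits)
    rows = np.empty((len(probe_ids), len(age_grid)))
    for i, pid in enumerate(probe_ids):
        fit: TrendFit = fits[pid]
        rows[i] = fit.predict(age_grid)  # raises outside fitted range
    rows -= rows.mean(axis=1, keepdims=True)
    return TrendMatrix(probe_ids=probe_ids, age_grid=age_grid, trends=rows)


def trend_matrix_from_table(table, age_grid, probe_ids=None) -> TrendMatrix:
    """Centered trends straight from a quadratic fit table.

    Vectorized counterpart of :func:`center_trends` for the output of
    :func:`agebend.trendfit.filter_probes`: evaluates beta0 + beta1*t +
    beta2*t^2 on the grid for the selected probes and centers rows.
    """
    age_grid = np.asarray(age_grid, dtype=float)
    if probe_ids is not None:
        table = table.loc[list(probe_ids)]
    betas = table[["beta0", "beta1", "beta2"]].to_numpy()
    V = np.vander(age_grid, 3, increasing=True)  # grid x 3
    rows = betas @ V.T
    rows -= rows.mean(axis=1, keepdims=True)
    return TrendMatrix(probe_ids=list(table.index), age_grid=age_grid, trends=rows)


# -- distances ---------------------------------------------------------------

def _pearson_rows(x: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Pearson r of each row of x against vector c; 0 if either has no variance."""
    xc = x - x.mean(axis=1, keepdims=True)
    cc = c - c.mean()
    xn = np.linalg.norm(xc, axis=1)
    cn = np.linalg.norm(cc)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ cc) / (xn * cn)
    r[~np.isfinite(r)] = 0.0
    if cn == 0:
        r[:] = 0.0
    return np.clip(r, -1.0, 1.0)


def abscorrelation_distance(x, c) -> float:
    """1 - |Pearson r|; a trend and any affine image of it are at distance 0."""
    x = np.atleast_2d(np.asarray(x, float))
    return float(1.0 - np.abs(_pearson_rows(x, np.asarray(c, float)))[0])


def _distances(x: np.ndarray, centroids: np.ndarray, metric: str) -> np.ndarray:
    """probes x k distance matrix under the clustering metric."""
    if metric == "euclidean":
        # squared Euclidean: the quantity Lloyd iteration minimizes
        d = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    elif metric == "abscorrelation":
        d = np.column_stack(
            [1.0 - np.abs(_pearson_rows(x, c)) for c in centroids]
        )
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return d


def _update_centroids(x, assignments, centroids, metric):
    k = centroids.shape[0]
    new = centroids.copy()
    for j in range(k):
        members = x[assignments == j]
        if len(members) == 0:
            continue
        if metric == "euclidean":
            new[j] = members.mean(axis=0)
        else:
            # sign-aligned mean: flip members negatively correlated with the
            # current centroid so the average represents one orientation
            r = _pearson_rows(members, centroids[j])
            signs = np.where(r < 0, -1.0, 1.0)
            new[j] = (members * signs[:, None]).mean(axis=0)
    return new


def _init_plusplus(x, k, metric, rng):
    """k-means++ (D^2) seeding under the clustering metric."""
    n = x.shape[0]
    chosen = [int(rng.integers(n))]
    while len(chosen) < k:
        d = _distances(x, x[chosen], metric).min(axis=1)
        d[chosen] = 0.0
        total = d.sum()
        if total <= 0:  # duplicate-heavy input: fall back to uniform draw
            candidates = [i for i in range(n) if i not in chosen]
            chosen.append(int(rng.choice(candidates)))
        else:
            chosen.append(int(rng.choice(n, p=d / total)))
    return x[chosen].copy()


def _kmeans_once(x: np.ndarray, k: int, metric: str, rng: np.random.Generator):
    n = x.shape[0]
    centroids = _init_plusplus(x, k, metric, rng)
    assignments = np.full(n, -1)
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        d = _distances(x, centroids, metric)
        new_assign = d.argmin(axis=1)
        # re-seed empty clusters at the farthest probe from its centroid
        for j in range(k):
            if not np.any(new_assign == j):
                far = d[np.arange(n), new_assign].argmax()
                logger.debug("re-seeding empty cluster %d at probe %d", j, far)
                centroids[j] = x[far]
                d = _distances(x, centroids, metric)
                new_assign = d.argmin(axis=1)
        if np.array_equal(new_assign, assignments):
            converged = True
            break
        assignments = new_assign
        centroids = _update_centroids(x, assignments, centroids, metric)
    d = _distances(x, centroids, metric)
    assignments = d.argmin(axis=1)
    per_cluster = np.array(
        [d[assignments == j, j].sum() for j in range(k)]
    )
    return assignments, centroids, per_cluster, converged, it


def kmeans_trends(
    trends: TrendMatrix,
    k: int,
    metric: str = "euclidean",
    restarts: int = 25,
    seed: int = 0,
    compute_bands: bool = True,
) -> ClusterResult:
    """Best-of-restarts Lloyd k-means on centered trends.

    Under ``euclidean`` the objective is the total within-cluster squared
    distance to centroids; under ``abscorrelation`` it is the total
    1 - |r| distance, with centroids updated as the sign-aligned member
    mean. Random initialization draws k distinct trend rows per restart; the
    restart with the lowest objective wins.
    """
    if k < 2 or k >= trends.n_probes:
        raise ValueError("require 2 <= k < n_probes")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(restarts):
        out = _kmeans_once(trends.trends, k, metric, rng)
        if best is None or out[2].sum() < best[2].sum():
            best = out
    assignments, centroids, per_cluster, converged, it = best
    result = ClusterResult(
        k=k,
        metric=metric,
        assignments=assignments,
        centroids=centroids,
        within_sse=per_cluster,
        total_within_sse=float(per_cluster.sum()),
        converged=converged,
        n_iterations=it,
    )
    if compute_bands:
        result.bands = {
            q: percentile_bands(trends, assignments, q) for q in (95, 99)
        }
    return result


def percentile_bands(trends: TrendMatrix, assignments, q: int) -> dict:
    """Point-wise central q% reference interval per cluster.

    At each grid age the member values' empirical quantiles at (100-q)/2 and
    100-(100-q)/2 bound the band. Clusters smaller than 3 fall back to
    min/max with a warning.
    """
    if q not in (95, 99):
        raise ValueError("q must be 95 or 99")
    assignments = np.asarray(assignments)
    lo_q, hi_q = (100 - q) / 2, 100 - (100 - q) / 2
    bands = {}
    for j in np.unique(assignments):
        rows = trends.trends[assignments == j]
        if rows.shape[0] < 3:
            warnings.warn(
                f"cluster {j} has {rows.shape[0]} members; band equals min/max",
                stacklevel=2,
            )
            bands[int(j)] = (rows.min(axis=0), rows.max(axis=0))
        else:
            bands[int(j)] = (
                np.percentile(rows, lo_q, axis=0),
                np.percentile(rows, hi_q, axis=0),
            )
    return bands


def _canonical_partition(assignments: np.ndarray) -> tuple:
    """Relabel clusters by first appearance so partitions compare as sets."""
    mapping, out = {}, []
    for a in assignments:
        if a not in mapping:
            mapping[a] = len(mapping)
        out.append(mapping[a])
    return tuple(out)


def stability_scan(
    trends: TrendMatrix,
    k_sequence=(24, 16, 12, 8, 6, 4),
    metric: str = "euclidean",
    restarts: int = 25,
    seed: int = 0,
) -> dict:
    """Re-cluster along a descending k schedule and score restart consistency.

    For each k the fraction of restarts whose final partition equals the
    best-objective partition (up to label permutation) measures stability;
    the recommended k is the smallest one reaching a convergence fraction of
    at least 0.5.
    """
    rng = np.random.default_rng(seed)
    report = {"k_sequence": list(k_sequence), "per_k": {}, "recommended_k": None}
    for k in k_sequence:
        runs = [_kmeans_once(trends.trends, k, metric, rng) for _ in range(restarts)]
        objectives = [r[2].sum() for r in runs]
        best_idx = int(np.argmin(objectives))
        best_part = _canonical_partition(runs[best_idx][0])
        frac = np.mean(
            [_canonical_partition(r[0]) == best_part for r in runs]
        )
        report["per_k"][k] = {
            "total_within_sse": float(objectives[best_idx]),
            "convergence_fraction": float(frac),
        }
    eligible = [
        k for k in k_sequence
        if report["per_k"][k]["convergence_fraction"] >= 0.5
    ]
    if eligible:
        report["recommended_k"] = min(eligible)
    return report
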