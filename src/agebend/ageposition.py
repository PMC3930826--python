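"""Age-position estimation from absolute-correlation clusters.

An absolute-correlation cluster bundles two reciprocal (mirror-image) trend
subgroups; the chronological age at which the subgroup mean trends intersect
is the *age-position* — the point where the dominant expression trend bends.
The crossing also coincides with the age where the cluster's 95th-percentile
band pinches closest around the centroid, which serves as a fallback
estimator when no clean crossing exists. The +/- range of a position is the
half-spread of matched estimates across k = 2, 3 and 4 clusters.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .trendcluster import (
    ClusterResult,
    TrendMatrix,
    _pearson_rows,
    kmeans_trends,
)

__all__ = [
    "AgePosition",
    "split_reciprocal",
    "detect_age_position",
    "position_range",
    "classify_directions",
    "NoAgePositionError",
]

logger = logging.getLogger(__name__)

_FLAT_TOL = 1e-12


class NoAgePositionError(ValueError):
    """Raised when a cluster carries no detectable trend bend."""


@dataclass
class AgePosition:
    """An estimated bend age with its cross-k range and member directions."""

    age: float
    range: float
    cluster_id: int
    method: str  # "intersection" or "band_minimum"
    probe_ids: list
    n_up: int
    n_down: int
    directions: dict = field(default_factory=dict)  # probe id -> "up"/"down"


def split_reciprocal(cluster: int, result: ClusterResult, trends: TrendMatrix):
    """Partition a cluster's probes by sign of correlation with its centroid.

    Returns ``(subgroup_a_ids, subgroup_b_ids)``: positively correlated
    probes (and, with a warning, zero-correlation ones) in A, negatively
    correlated in B. An all-one-sign cluster yields an empty B with a
    warning — no internal crossing is then possible.
    """
    members = result.members(cluster)
    if len(members) < 2:
        raise ValueError("cluster must have at least 2 members")
    r = _pearson_rows(trends.trends[members], result.centroids[cluster])
    if np.any(r == 0):
        warnings.warn(
            "probes uncorrelated with the centroid assigned to subgroup A",
            stacklevel=2,
        )
    a = [trends.probe_ids[i] for i, ri in zip(members, r) if ri >= 0]
    b = [trends.probe_ids[i] for i, ri in zip(members, r) if ri < 0]
    if not a or not b:
        warnings.warn(
            f"cluster {cluster} has one-sign trends only; no reciprocal split",
            stacklevel=2,
        )
    return a, b


def _interp_at(grid: np.ndarray, values: np.ndarray, age: float) -> float:
    return float(np.interp(age, grid, values))


def _crossings(grid: np.ndarray, diff: np.ndarray):
    """Ages where ``diff`` changes sign, linearly interpolated."""
    ages = []
    for i in range(len(grid) - 1):
        d0, d1 = diff[i], diff[i + 1]
        if d0 == 0.0:
            ages.append(float(grid[i]))
        elif d0 * d1 < 0:
            frac = d0 / (d0 - d1)
            ages.append(float(grid[i] + frac * (grid[i + 1] - grid[i])))
    if len(diff) and diff[-1] == 0.0:
        ages.append(float(grid[-1]))
    # collapse duplicates from exact-zero grid points
    out = []
    for a in ages:
        if not out or a - out[-1] > 1e-9:
            out.append(a)
    return out


def detect_age_position(
    cluster: int, result: ClusterResult, trends: TrendMatrix
) -> AgePosition:
    """Estimate the bend age of one absolute-correlation cluster.

    Primary rule: the age where the two reciprocal subgroup mean trends
    cross (sign change of their difference, linearly interpolated between
    grid points); among multiple crossings the one with the narrowest
    95th-percentile band wins, ties resolved to the earliest age. Fallback
    when no crossing exists: the grid age minimizing the 95th-percentile
    band half-width. A flat cluster (no crossing, no band relief) raises
    :class:`NoAgePositionError`.
    """
    grid = trends.age_grid
    members = result.members(cluster)
    member_ids = [trends.probe_ids[i] for i in members]
    bands95 = result.bands.get(95)
    if bands95 is None:
        from .trendcluster import percentile_bands

        bands95 = percentile_bands(trends, result.assignments, 95)
    lower, upper = bands95[int(cluster)]
    half_width = (upper - lower) / 2.0

    a_ids, b_ids = split_reciprocal(cluster, result, trends)
    crossings = []
    if a_ids and b_ids:
        idx = {pid: i for i, pid in enumerate(trends.probe_ids)}
        mean_a = trends.trends[[idx[p] for p in a_ids]].mean(axis=0)
        mean_b = trends.trends[[idx[p] for p in b_ids]].mean(axis=0)
        diff = mean_a - mean_b
        if np.max(np.abs(diff)) > _FLAT_TOL:
            crossings = _crossings(grid, diff)

    if crossings:
        widths = [_interp_at(grid, half_width, a) for a in crossings]
        best = int(np.argmin(widths))  # argmin returns the earliest on ties
        age, method = crossings[best], "intersection"
    else:
        if float(np.ptp(half_width)) <= _FLAT_TOL and np.max(half_width) <= _FLAT_TOL:
            raise NoAgePositionError(
                f"cluster {cluster}: flat trends, no age-position"
            )
        age, method = float(grid[int(np.argmin(half_width))]), "band_minimum"

    position = AgePosition(
        age=age,
        range=0.0,
        cluster_id=int(cluster),
        method=method,
        probe_ids=member_ids,
        n_up=0,
        n_down=0,
    )
    position.n_up, position.n_down = classify_directions(position, trends)
    return position


def classify_directions(position: AgePosition, trends: TrendMatrix):
    """Count member probes trending up vs down after the bend.

    A probe is "up" when its centered trend at the oldest grid age exceeds
    its value at the position age, "down" otherwise; per-probe labels are
    stored on the position.
    """
    grid = trends.age_grid
    idx = {pid: i for i, pid in enumerate(trends.probe_ids)}
    n_up = 0
    directions = {}
    for pid in position.probe_ids:
        row = trends.trends[idx[pid]]
        at_pos = _interp_at(grid, row, position.age)
        up = row[-1] > at_pos
        directions[pid] = "up" if up else "down"
        n_up += int(up)
    position.directions = directions
    return n_up, len(position.probe_ids) - n_up


def detect_all_positions(result: ClusterResult, trends: TrendMatrix):
    """Age-positions for every cluster in a result; undetectable ones skipped."""
    positions = []
    for j in range(result.k):
        try:
            positions.append(detect_age_position(j, result, trends))
        except NoAgePositionError:
            logger.info("cluster %d: no age-position detected", j)
    return positions


def position_range(
    trends: TrendMatrix,
    k_values=(2, 3, 4),
    metric: str = "abscorrelation",
    restarts: int = 25,
    seed: int = 0,
):
    """Age-positions with +/- ranges from a small k scan.

    Positions detected at the first (reference, typically k=2) clustering
    anchor the estimate; positions found at the other k values attach to
    their nearest reference age. Each reference position's range is
    (max - min)/2 of its matched estimates, rounded up to whole years.
    Unmatched reference positions keep range 0; extra positions at higher k
    are logged and excluded.
    """
    k_values = list(k_values)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=len(k_values))
    reference = None
    matched: list[list[float]] = []
    ref_positions: list[AgePosition] = []
    for k, s in zip(k_values, seeds):
        result = kmeans_trends(trends, k=k, metric=metric, restarts=restarts,
                               seed=int(s))
        positions = detect_all_positions(result, trends)
        if not positions:
            logger.info("k=%d yielded no detectable positions; skipped", k)
            continue
        if reference is None:
            reference = [p.age for p in positions]
            ref_positions = positions
            matched = [[p.age] for p in positions]
        else:
            for p in positions:
                j = int(np.argmin([abs(p.age - r) for r in reference]))
                matched[j].append(p.age)
    if reference is None:
        return []
    for p, ests in zip(ref_positions, matched):
        p.range = float(math.ceil((max(ests) - min(ests)) / 2.0))
        p.matched_estimates = ests  # type: ignore[attr-defined]
    return ref_positions
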