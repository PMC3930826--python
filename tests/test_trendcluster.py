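import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agebend.trendcluster import (
    TrendMatrix,
    abscorrelation_distance,
    center_trends,
    default_age_grid,
    kmeans_trends,
    percentile_bands,
    stability_scan,
    trend_matrix_from_table,
)
from agebend.trendfit import fit_trend


def make_trends(rows, grid=None):
    rows = np.asarray(rows, dtype=float)
    rows = rows - rows.mean(axis=1, keepdims=True)
    if grid is None:
        grid = np.arange(rows.shape[1], dtype=float)
    return TrendMatrix(probe_ids=[f"p{i}" for i in range(rows.shape[0])],
                       age_grid=grid, trends=rows)


def two_family_trends(n_per=10, seed=0, scale=1.0):
    """Two well-separated centered trend shapes plus small jitter."""
    rng = np.random.default_rng(seed)
    grid = np.arange(0.0, 50.0)
    shape_a = np.sin(grid / 8.0)
    shape_b = (grid - 25.0) ** 2 / 300.0
    rows = np.vstack(
        [shape_a + rng.normal(0, 0.02 * scale, len(grid)) for _ in range(n_per)]
        + [shape_b + rng.normal(0, 0.02 * scale, len(grid)) for _ in range(n_per)]
    )
    return make_trends(rows, grid)


class TestCenterTrends:
    def test_constant_fit_row_is_zero(self):
        fit = fit_trend(np.linspace(0, 10, 6), np.full(6, 4.0), "linear")
        tm = center_trends({"p": fit}, np.linspace(0, 10, 11))
        np.testing.assert_allclose(tm.trends, 0.0, atol=1e-12)

    def test_shift_invariance(self):
        t = np.linspace(0, 10, 8)
        y = np.sin(t)
        f1 = fit_trend(t, y, "quadratic")
        f2 = fit_trend(t, y + 10.0, "quadratic")
        tm = center_trends({"a": f1, "b": f2}, t)
        np.testing.assert_allclose(tm.trends[0], tm.trends[1], atol=1e-9)

    def test_hand_computed_quadratic(self):
        fit = fit_trend([0.0, 1.0, 2.0], [1.0, 0.0, 1.0], "quadratic")
        tm = center_trends({"p": fit}, [0.0, 1.0, 2.0])
        np.testing.assert_allclose(tm.trends[0], [1 / 3, -2 / 3, 1 / 3], atol=1e-9)

    def test_rows_mean_zero(self, two_bend_dataset):
        from agebend.trendfit import filter_probes

        ds, _ = two_bend_dataset
        _, table = filter_probes(ds)
        grid = default_age_grid(ds.ages.min(), ds.ages.max())
        tm = trend_matrix_from_table(table.iloc[:50], grid)
        assert np.max(np.abs(tm.trends.mean(axis=1))) < 1e-10

    def test_no_extrapolation(self):
        fit = fit_trend(np.linspace(30, 60, 6), np.arange(6.0), "quadratic")
        with pytest.raises(ValueError, match="outside fitted range"):
            center_trends({"p": fit}, np.linspace(20, 60, 5))


class TestAbsCorrelationDistance:
    def test_mirror_distance_zero(self):
        x = np.sin(np.linspace(0, 3, 20))
        assert abscorrelation_distance(x, -x) == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_defined(self):
        x = np.zeros(10)
        c = np.arange(10.0)
        assert abscorrelation_distance(x, c) == 1.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(a=st.floats(-5, 5).filter(lambda v: abs(v) > 1e-3),
           b=st.floats(-10, 10))
    def test_affine_invariance(self, a, b):
        x = np.sin(np.linspace(0, 3, 25))
        c = np.cos(np.linspace(0, 3, 25))
        d0 = abscorrelation_distance(x, c)
        d1 = abscorrelation_distance(a * x + b, c)
        assert d1 == pytest.approx(d0, abs=1e-9)


def brute_force_kmeans_objective(x, k):
    """Exhaustive minimum of the Euclidean k-means objective (small n only)."""
    n = x.shape[0]
    best = np.inf
    for labels in itertools.product(range(k), repeat=n):
        if len(set(labels)) != k:
            continue
        labels = np.array(labels)
        obj = 0.0
        for j in range(k):
            mem = x[labels == j]
            obj += ((mem - mem.mean(axis=0)) ** 2).sum()
        best = min(best, obj)
    return best


class TestKmeans:
    def test_mirrored_probes_cocluster(self):
        rng = np.random.default_rng(1)
        shape = np.sin(np.linspace(0, 4, 30))
        other = np.linspace(-1, 1, 30)
        rows = [shape, -shape, 2 * shape, other + rng.normal(0, 0.01, 30),
                -3 * other, other]
        tm = make_trends(rows, np.arange(30.0))
        res = kmeans_trends(tm, 2, metric="abscorrelation", restarts=10, seed=0)
        a = res.assignments
        assert a[0] == a[1] == a[2]
        assert a[3] == a[4] == a[5]
        assert a[0] != a[3]

    def test_two_families_exact_partition(self):
        tm = two_family_trends(n_per=10, seed=2)
        res = kmeans_trends(tm, 2, metric="euclidean", restarts=10, seed=1)
        a = res.assignments
        assert len(set(a[:10])) == 1 and len(set(a[10:])) == 1
        assert a[0] != a[10]

    def test_euclidean_matches_exhaustive_optimum(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(10, 4))
        tm = make_trends(x)
        for k in (2, 3):
            res = kmeans_trends(tm, k, metric="euclidean", restarts=60,
                                seed=3, compute_bands=False)
            oracle = brute_force_kmeans_objective(tm.trends, k)
            assert res.total_within_sse == pytest.approx(oracle, rel=1e-9)

    def test_assignments_are_nearest_centroid(self):
        tm = two_family_trends(n_per=8, seed=4)
        for metric in ("euclidean", "abscorrelation"):
            res = kmeans_trends(tm, 2, metric=metric, restarts=5, seed=5)
            from agebend.trendcluster import _distances

            d = _distances(tm.trends, res.centroids, metric)
            np.testing.assert_array_equal(res.assignments, d.argmin(axis=1))
            assert np.all(np.bincount(res.assignments, minlength=2) >= 1)

    def test_reciprocal_pairs_merge_under_abscorrelation(self, two_bend_dataset):
        from agebend.trendfit import filter_probes

        ds, truth = two_bend_dataset
        sig, table = filter_probes(ds)
        grid = default_age_grid(ds.ages.min(), ds.ages.max())
        true_sig = [p for p in sig if p in truth.signal]
        tm = trend_matrix_from_table(table, grid, probe_ids=true_sig)
        res4 = kmeans_trends(tm, 4, metric="euclidean", restarts=10, seed=6)
        res2 = kmeans_trends(tm, 2, metric="abscorrelation", restarts=10, seed=6)
        # euclidean k=4 separates the four (bend, direction) shapes...
        bend_dir = np.array([
            (truth.signal[p]["bend"], truth.signal[p]["direction"])
            for p in true_sig
        ], dtype=object)
        for j in range(4):
            labels = bend_dir[res4.assignments == j]
            kinds = {tuple(x) for x in labels}
            assert len(kinds) <= 2  # dominated by one shape (plus strays)
        # ...while abscorrelation k=2 merges each reciprocal pair by bend age
        # (a stray noisy probe or two may cross over)
        for j in range(2):
            bends = [b for b, _ in bend_dir[res2.assignments == j]]
            dominant = max(set(bends), key=bends.count)
            assert bends.count(dominant) / len(bends) >= 0.95
        doms = {
            max(set([b for b, _ in bend_dir[res2.assignments == j]]),
                key=[b for b, _ in bend_dir[res2.assignments == j]].count)
            for j in range(2)
        }
        assert doms == {45.0, 75.0}

    def test_invalid_k(self):
        tm = two_family_trends(n_per=3)
        with pytest.raises(ValueError):
            kmeans_trends(tm, 1)
        with pytest.raises(ValueError):
            kmeans_trends(tm, 6)


class TestPercentileBands:
    def test_identical_rows_zero_width(self):
        rows = np.tile(np.sin(np.linspace(0, 3, 20)), (5, 1))
        tm = make_trends(rows)
        bands = percentile_bands(tm, np.zeros(5, dtype=int), 95)
        lo, hi = bands[0]
        np.testing.assert_allclose(hi - lo, 0.0, atol=1e-12)

    def test_99_encloses_95(self):
        rng = np.random.default_rng(9)
        tm = make_trends(rng.normal(size=(60, 15)))
        assign = np.zeros(60, dtype=int)
        b95 = percentile_bands(tm, assign, 95)[0]
        b99 = percentile_bands(tm, assign, 99)[0]
        assert np.all(b99[0] <= b95[0] + 1e-12)
        assert np.all(b99[1] >= b95[1] - 1e-12)

    def test_matches_order_statistic_oracle(self):
        rng = np.random.default_rng(10)
        rows = rng.normal(size=(100, 5))
        tm = make_trends(rows)
        bands = percentile_bands(tm, np.zeros(100, dtype=int), 95)
        centered = rows - rows.mean(axis=1, keepdims=True)
        col = centered[:, 2]
        np.testing.assert_allclose(bands[0][0][2], np.percentile(col, 2.5))
        np.testing.assert_allclose(bands[0][1][2], np.percentile(col, 97.5))

    def test_small_cluster_minmax_warning(self):
        tm = make_trends(np.random.default_rng(0).normal(size=(2, 6)))
        with pytest.warns(UserWarning, match="min/max"):
            bands = percentile_bands(tm, np.zeros(2, dtype=int), 95)
        np.testing.assert_allclose(bands[0][0], tm.trends.min(axis=0))


class TestStabilityScan:
    def test_separated_families_converge_at_true_k(self):
        rng = np.random.default_rng(13)
        grid = np.arange(0.0, 40.0)
        shapes = [np.sin(grid / 6), np.cos(grid / 9), (grid - 20) ** 2 / 200,
                  grid / 20.0]
        rows = np.vstack([
            s + rng.normal(0, 0.02, len(grid)) for s in shapes for _ in range(8)
        ])
        tm = make_trends(rows, grid)
        report = stability_scan(tm, k_sequence=(8, 6, 4), restarts=20, seed=1)
        assert report["per_k"][4]["convergence_fraction"] >= 0.9
        assert report["recommended_k"] == 4
        # within-SSE non-increasing in k along the descending scan
        sses = [report["per_k"][k]["total_within_sse"] for k in (8, 6, 4)]
        assert sses[0] <= sses[1] <= sses[2]

    def test_consistent_with_sklearn_objective(self):
        # independent route: sklearn KMeans on the same matrix should reach
        # (at least) the same Euclidean objective
        sklearn = pytest.importorskip("sklearn.cluster")
        tm = two_family_trends(n_per=6, seed=3)
        res = kmeans_trends(tm, 2, metric="euclidean", restarts=20, seed=2,
                            compute_bands=False)
        km = sklearn.KMeans(n_clusters=2, n_init=20, random_state=0).fit(tm.trends)
        assert res.total_within_sse == pytest.approx(km.inertia_, rel=1e-6)
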