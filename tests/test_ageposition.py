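import numpy as np
import pytest

from agebend.ageposition import (
    NoAgePositionError,
    classify_directions,
    detect_age_position,
    detect_all_positions,
    position_range,
    split_reciprocal,
)
from agebend.trendcluster import TrendMatrix, kmeans_trends, percentile_bands
from agebend.trendfit import filter_probes
from agebend.trendcluster import default_age_grid, trend_matrix_from_table


def make_trends(rows, grid=None, center=True):
    rows = np.asarray(rows, dtype=float)
    if center:
        rows = rows - rows.mean(axis=1, keepdims=True)
    if grid is None:
        grid = np.arange(rows.shape[1], dtype=float)
    return TrendMatrix(probe_ids=[f"p{i}" for i in range(rows.shape[0])],
                       age_grid=grid, trends=rows)


def mirrored_cluster(n_per=10, bend=60.0, grid=None, noise=0.0, seed=0):
    """Reciprocal sigmoid trends bending at `bend`, clustered with k=2
    abscorrelation against a decoy family."""
    if grid is None:
        grid = np.arange(30.0, 91.0)
    rng = np.random.default_rng(seed)
    g = 1 / (1 + np.exp(-(grid - bend) / 3.0))
    decoy = np.sin(grid / 5.0)
    rows = (
        [g + rng.normal(0, noise, len(grid)) for _ in range(n_per)]
        + [-g + rng.normal(0, noise, len(grid)) for _ in range(n_per)]
        + [decoy + rng.normal(0, noise, len(grid)) for _ in range(4)]
    )
    tm = make_trends(rows, grid)
    res = kmeans_trends(tm, 2, metric="abscorrelation", restarts=10, seed=seed)
    target = res.assignments[0]
    return tm, res, int(target)


class TestSplitReciprocal:
    def test_mirror_pair_split(self):
        tm, res, cl = mirrored_cluster(n_per=1)
        a, b = split_reciprocal(cl, res, tm)
        assert len(a) == 1 and len(b) == 1
        assert {a[0], b[0]} == {"p0", "p1"}

    def test_balanced_mirror_split_matches_truth(self):
        tm, res, cl = mirrored_cluster(n_per=10, noise=0.02, seed=3)
        a, b = split_reciprocal(cl, res, tm)
        up = {f"p{i}" for i in range(10)}
        down = {f"p{i}" for i in range(10, 20)}
        assert {frozenset(a), frozenset(b)} == {frozenset(up), frozenset(down)}

    def test_one_sign_cluster_flagged(self):
        grid = np.arange(20.0, 60.0)
        rows = [np.sin(grid / 7) * s for s in (1.0, 1.1, 0.9)] + [grid / 40]
        tm = make_trends(rows, grid)
        res = kmeans_trends(tm, 2, metric="abscorrelation", restarts=5, seed=1)
        cl = int(res.assignments[0])
        with pytest.warns(UserWarning, match="one-sign"):
            a, b = split_reciprocal(cl, res, tm)
        assert len(b) == 0


class TestDetectAgePosition:
    def test_symmetric_zero_crossing(self):
        grid = np.arange(30.0, 91.0)
        g = (grid - 60.0) / 30.0  # strictly increasing, zero at 60
        rows = [g, g, -g, -g, np.sin(grid / 4)]
        tm = make_trends(rows, grid, center=False)
        res = kmeans_trends(tm, 2, metric="abscorrelation", restarts=10, seed=2)
        cl = int(res.assignments[0])
        pos = detect_age_position(cl, res, tm)
        assert pos.method == "intersection"
        assert pos.age == pytest.approx(60.0, abs=1e-9)

    def test_intersection_and_band_minimum_agree_on_mirrors(self):
        tm, res, cl = mirrored_cluster(n_per=8, bend=55.0, noise=0.01, seed=5)
        pos = detect_age_position(cl, res, tm)
        assert pos.method == "intersection"
        lo, hi = res.bands[95][cl]
        band_min_age = tm.age_grid[np.argmin(hi - lo)]
        assert abs(pos.age - band_min_age) <= 1.0 + 1e-9

    def test_scale_and_label_invariance(self):
        tm, res, cl = mirrored_cluster(n_per=5, bend=70.0, noise=0.01, seed=8)
        pos = detect_age_position(cl, res, tm)
        tm2 = TrendMatrix(tm.probe_ids, tm.age_grid, 3.5 * tm.trends)
        res2 = kmeans_trends(tm2, 2, metric="abscorrelation", restarts=10, seed=8)
        # same partition up to labels; find the matching cluster
        cl2 = int(res2.assignments[list(tm.probe_ids).index("p0")])
        pos2 = detect_age_position(cl2, res2, tm2)
        assert pos2.age == pytest.approx(pos.age, abs=1e-6)

    def test_flat_cluster_no_position(self):
        grid = np.arange(10.0)
        rows = np.zeros((4, 10))
        tm = make_trends(rows, grid)
        from agebend.trendcluster import ClusterResult

        res = ClusterResult(k=1, metric="abscorrelation",
                            assignments=np.zeros(4, dtype=int),
                            centroids=np.zeros((1, 10)),
                            within_sse=np.zeros(1), total_within_sse=0.0)
        res.bands = {95: percentile_bands(tm, res.assignments, 95)}
        with pytest.raises(NoAgePositionError):
            detect_age_position(0, res, tm)

    def test_matches_noiseless_projection_oracle(self, two_bend_dataset):
        """Detected crossings equal the quadratic projection of the noiseless
        sigmoid — the estimator's analytic target — to within ~1 year."""
        ds, truth = two_bend_dataset
        from agebend.preprocess import correct_sex

        sig, table = filter_probes(correct_sex(ds))
        grid = default_age_grid(ds.ages.min(), ds.ages.max())
        tm = trend_matrix_from_table(table, grid, probe_ids=sig)
        res = kmeans_trends(tm, 2, metric="abscorrelation", restarts=10, seed=1)
        detected = sorted(p.age for p in detect_all_positions(res, tm))

        # oracle: fit the quadratic to the pure sigmoid, find its mean-crossing
        oracle = []
        t = ds.ages
        for bend in truth.bend_ages:
            s = 1 / (1 + np.exp(-(t - bend) / 3.0))
            X = np.vander((t - t.mean()) / t.std(), 3, increasing=True)
            beta, *_ = np.linalg.lstsq(X, s, rcond=None)
            gfit = np.vander((grid - t.mean()) / t.std(), 3, increasing=True) @ beta
            gc = gfit - gfit.mean()
            i = np.where(np.diff(np.sign(gc)))[0][0]
            oracle.append(grid[i] + gc[i] / (gc[i] - gc[i + 1]))
        oracle = sorted(oracle)
        for d, o in zip(detected, oracle):
            assert d == pytest.approx(o, abs=1.0)


class TestClassifyDirections:
    def test_monotone_up(self):
        grid = np.arange(30.0, 80.0)
        rows = [grid / 20.0, -grid / 20.0, np.sin(grid / 4)]
        tm = make_trends(rows, grid)
        from agebend.ageposition import AgePosition

        pos = AgePosition(age=50.0, range=0, cluster_id=0, method="intersection",
                          probe_ids=["p0", "p1"], n_up=0, n_down=0)
        n_up, n_down = classify_directions(pos, tm)
        assert (n_up, n_down) == (1, 1)
        assert pos.directions == {"p0": "up", "p1": "down"}

    def test_direction_fractions_at_zero_noise(self):
        from agebend.simulate import SimulationConfig, simulate_dataset
        from agebend.preprocess import correct_sex

        cfg = SimulationConfig(n_probes=200, n_samples=40, bend_ages=(60.0,),
                               signal_probes_per_bend=50, fraction_down=0.6,
                               noise_sd=0.0, sex_effect_fraction=0.0, seed=4)
        ds, truth = simulate_dataset(cfg)
        sig, table = filter_probes(correct_sex(ds))
        true_sig = [p for p in sig if p in truth.signal]
        grid = default_age_grid(ds.ages.min(), ds.ages.max())
        tm = trend_matrix_from_table(table, grid, probe_ids=true_sig)
        res = kmeans_trends(tm, 2, metric="abscorrelation", restarts=10, seed=2)
        counts = np.bincount(res.assignments)
        pos = detect_age_position(int(np.argmax(counts)), res, tm)
        assert pos.n_down / (pos.n_up + pos.n_down) == pytest.approx(0.6)


class TestPositionRange:
    def test_identical_estimates_zero_range(self):
        tm, _, _ = mirrored_cluster(n_per=10, bend=58.0, noise=0.0, seed=6)
        positions = position_range(tm, k_values=(2, 2, 2), restarts=10, seed=3)
        main = min(positions, key=lambda p: abs(p.age - 58))
        assert main.range == 0.0

    def test_two_bend_recovery_structure(self, two_bend_dataset):
        ds, truth = two_bend_dataset
        from agebend.preprocess import correct_sex

        sig, table = filter_probes(correct_sex(ds))
        grid = default_age_grid(ds.ages.min(), ds.ages.max())
        tm = trend_matrix_from_table(table, grid, probe_ids=sig)
        positions = position_range(tm, k_values=(2, 3, 4), restarts=10, seed=9)
        assert len(positions) == 2
        ages = sorted(p.age for p in positions)
        # one matched group per true bend, in chronological order
        assert ages[0] < 60 < ages[1]
        for p in positions:
            assert p.range >= 0
            assert p.n_up + p.n_down == len(p.probe_ids)
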