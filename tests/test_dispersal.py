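import numpy as np
import pandas as pd
import pytest
from scipy import stats

from morphoflow import synthdata
from morphoflow.dispersal import (
    CellCluster,
    DispersalSeries,
    TrajectorySet,
    adjust_fdr,
    collect_dispersal_series,
    compare_slopes_ancova,
    compare_slopes_per_cluster,
    detect_rosettes,
    dispersal_series,
    fit_linear_trend,
    fit_quadratic_trend,
    hotelling_t2,
    identify_clusters,
    normalize_series,
    standard_distance,
    track_speed,
)
from morphoflow.pipeline import _clusters_from_truth

from conftest import wedge_labels


def tracks_from_positions(positions, dt=1.0):
    """positions: {track_id: [(frame, x, y), ...]}"""
    rows = [(tid, f, x, y, 0.0)
            for tid, samples in positions.items() for f, x, y in samples]
    df = pd.DataFrame(rows, columns=["track_id", "frame", "x", "y", "z"])
    return TrajectorySet(data=df, dt=dt)


def series(times, values, **kw):
    return DispersalSeries(times=np.asarray(times, float),
                           values=np.asarray(values, float), **kw)


class TestStandardDistance:
    def test_coincident_points(self):
        assert standard_distance([[2.0, 3.0]] * 4) == 0.0

    def test_unit_square_corners(self):
        pts = [[1, 1], [1, -1], [-1, 1], [-1, -1]]
        assert standard_distance(pts) == pytest.approx(np.sqrt(2), rel=1e-12)

    def test_matches_brute_force_formula(self, rng):
        for _ in range(20):
            pts = rng.normal(size=(6, 2)) * 10
            xbar, ybar = pts.mean(axis=0)
            brute = np.sqrt(sum((x - xbar) ** 2 for x, _ in pts) / 6
                            + sum((y - ybar) ** 2 for _, y in pts) / 6)
            assert standard_distance(pts) == pytest.approx(brute, rel=1e-12)

    def test_rejects_single_point(self):
        with pytest.raises(ValueError, match="at least 2"):
            standard_distance([[0.0, 0.0]])

    def test_translation_rotation_invariance(self, rng):
        pts = rng.normal(size=(7, 2))
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = pts @ rot.T + [100.0, -40.0]
        assert standard_distance(moved) == pytest.approx(standard_distance(pts),
                                                         rel=1e-12)

    def test_linear_scaling(self, rng):
        pts = rng.normal(size=(5, 2))
        assert standard_distance(3.0 * pts) == pytest.approx(
            3.0 * standard_distance(pts), rel=1e-12)


class TestIdentifyClusters:
    def test_single_obvious_cluster(self):
        pos = {i: [(0, float(i), 0.0)] for i in range(5)}  # 5 cells within 15 px
        pos.update({i: [(0, 1000.0 + 100 * i, 0.0)] for i in range(10, 14)})
        clusters = identify_clusters(tracks_from_positions(pos), t0=0)
        assert len(clusters) == 1
        assert clusters[0].members == (0, 1, 2, 3, 4)

    def test_three_cells_insufficient(self):
        pos = {i: [(0, float(i), 0.0)] for i in range(3)}
        pos[50] = [(0, 500.0, 500.0)]
        assert identify_clusters(tracks_from_positions(pos), t0=0) == []

    def test_membership_capped_at_max_size(self):
        pos = {i: [(0, float(i) * 0.5, 0.0)] for i in range(12)}
        clusters = identify_clusters(tracks_from_positions(pos), t0=0, seed=1)
        assert clusters
        assert all(len(c.members) <= 8 for c in clusters)

    def test_no_track_reuse_by_default(self):
        pos = {i: [(0, float(i), 0.0)] for i in range(16)}
        clusters = identify_clusters(tracks_from_positions(pos), t0=0, seed=2)
        all_members = [m for c in clusters for m in c.members]
        assert len(all_members) == len(set(all_members))

    def test_deterministic_and_subset_of_brute_force_candidates(self, rng):
        pos = {i: [(0, float(x), float(y))]
               for i, (x, y) in enumerate(rng.uniform(0, 200, size=(60, 2)))}
        tracks = tracks_from_positions(pos)
        c1 = identify_clusters(tracks, t0=0, seed=7)
        c2 = identify_clusters(tracks, t0=0, seed=7)
        assert [c.members for c in c1] == [c.members for c in c2]
        # brute-force candidate enumeration: all radius-neighbourhoods with >= 4 cells
        xy = np.array([pos[i][0][1:] for i in sorted(pos)])
        for c in c1:
            centre = np.array(c.convergent_point)
            dist = np.linalg.norm(xy[list(c.members)] - centre, axis=1)
            assert np.all(dist <= 15.0 + 1e-9)
            assert (np.linalg.norm(xy - centre, axis=1) <= 15.0).sum() >= 4


class TestDispersalSeries:
    def test_generated_linear_series_exact(self, linear_cluster_tracks):
        tracks, _ = linear_cluster_tracks
        cluster = _clusters_from_truth(tracks)[0]
        s = dispersal_series(cluster, tracks)
        np.testing.assert_allclose(s.values, 2.0 * s.times + 1.0, atol=1e-9)

    def test_stationary_cells_constant_series(self):
        pos = {i: [(f, float(i), 0.0) for f in range(4)] for i in range(4)}
        tracks = tracks_from_positions(pos)
        cluster = CellCluster(members=(0, 1, 2, 3), t0=0, convergent_point=(1.5, 0.0))
        s = dispersal_series(cluster, tracks, t_end=3)
        assert np.ptp(s.values) == 0.0

    def test_framewise_oracle(self, rng):
        spec = synthdata.ClusterDynamicsSpec(
            n_clusters=1, cells_per_cluster=5, model=("linear", 1.0, 5.0),
            jitter_sigma=1.0, dt=2.0, n_frames=6, seed=9)
        tracks, _ = synthdata.generate_cluster_trajectories(spec)
        cluster = _clusters_from_truth(tracks)[0]
        s = dispersal_series(cluster, tracks)
        for k, f in enumerate(range(6)):
            pts = tracks.positions_of(cluster.members, f)
            assert s.values[k] == pytest.approx(standard_distance(pts), rel=1e-12)
        np.testing.assert_allclose(s.times, np.arange(6) * 2.0)

    def test_short_track_cluster_dropped_with_log(self, caplog):
        pos = {i: [(f, float(i), 0.0) for f in range(4)] for i in range(4)}
        pos[3] = pos[3][:2]  # track 3 ends early
        tracks = tracks_from_positions(pos)
        cluster = CellCluster(members=(0, 1, 2, 3), t0=0, convergent_point=(1.5, 0.0))
        with pytest.raises(KeyError):
            dispersal_series(cluster, tracks, t_end=3)
        out, dropped = collect_dispersal_series([cluster], tracks, t_end=3)
        assert out == [] and dropped == 1


class TestNormalizeSeries:
    def test_simple(self):
        s = normalize_series(series([0, 1, 2], [2, 4, 6]))
        np.testing.assert_allclose(s.values, [1, 2, 3])
        assert s.normalized

    def test_constant(self):
        s = normalize_series(series([0, 1], [5, 5]))
        np.testing.assert_allclose(s.values, [1, 1])

    def test_elementwise_ratio_oracle(self, rng):
        vals = rng.uniform(1, 10, size=12)
        s = normalize_series(series(np.arange(12), vals))
        np.testing.assert_allclose(s.values, vals / vals[0], rtol=1e-12)

    def test_rejects_zero_first_value(self):
        with pytest.raises(ValueError, match="first value"):
            normalize_series(series([0, 1], [0, 3]))


class TestTrendFits:
    def test_linear_noiseless_exact(self):
        t = np.arange(10, dtype=float)
        fit = fit_linear_trend(series(t, 2.0 * t + 1.0))
        np.testing.assert_allclose(fit.coefficients, (2.0, 1.0), atol=1e-9)
        assert fit.residual_variance == pytest.approx(0.0, abs=1e-18)

    def test_constant_series_zero_slope(self):
        fit = fit_linear_trend(series([0, 1, 2], [4, 4, 4]))
        assert fit.coefficients[0] == pytest.approx(0.0, abs=1e-12)

    def test_quadratic_noiseless_exact(self):
        t = np.arange(8, dtype=float)
        fit = fit_quadratic_trend(series(t, t ** 2 - 2 * t + 3))
        np.testing.assert_allclose(fit.coefficients, (1.0, -2.0, 3.0), atol=1e-9)

    def test_quadratic_on_linear_data_zero_curvature(self):
        t = np.arange(8, dtype=float)
        fit = fit_quadratic_trend(series(t, 5 * t + 1))
        assert fit.coefficients[0] == pytest.approx(0.0, abs=1e-10)

    def test_rejects_identical_times(self):
        with pytest.raises(ValueError):
            fit_linear_trend(series([1, 1, 1], [1, 2, 3]))

    def test_rejects_too_few_points(self):
        with pytest.raises(ValueError, match="at least"):
            fit_quadratic_trend(series([0, 1, 2], [1, 2, 3]))

    def test_monte_carlo_slope_recovery(self, rng):
        t = np.arange(40, dtype=float)
        slopes = [fit_linear_trend(series(t, 1.5 * t + 3 + rng.normal(0, 0.5, 40))).coefficients[0]
                  for _ in range(50)]
        se = np.std(slopes, ddof=1) / np.sqrt(50)
        assert abs(np.mean(slopes) - 1.5) < 2 * se + 1e-3


class TestAncova:
    @staticmethod
    def two_groups(slope_a, slope_b, noise, rng, n_series=3, n_t=10):
        t = np.arange(n_t, dtype=float)
        ga = [series(t, slope_a * t + 5 + rng.normal(0, noise, n_t)) for _ in range(n_series)]
        gb = [series(t, slope_b * t + 5 + rng.normal(0, noise, n_t)) for _ in range(n_series)]
        return ga, gb

    def test_noiseless_different_slopes_tiny_p(self, rng):
        ga, gb = self.two_groups(2.0, 3.0, 0.0, rng)
        _f, p = compare_slopes_ancova(ga, gb)
        assert p < 1e-10

    def test_matches_nested_model_oracle(self, rng):
        ga, gb = self.two_groups(1.0, 1.4, 0.8, rng)
        f_stat, p = compare_slopes_ancova(ga, gb)
        t = np.concatenate([s.times for s in ga + gb])
        y = np.concatenate([s.values for s in ga + gb])
        g = np.repeat([0.0, 1.0], len(t) // 2)
        x_full = np.column_stack([np.ones_like(t), g, t, g * t])
        x_red = x_full[:, :3]
        rss = lambda x: float(((y - x @ np.linalg.lstsq(x, y, rcond=None)[0]) ** 2).sum())
        f_oracle = (rss(x_red) - rss(x_full)) / (rss(x_full) / (len(t) - 4))
        assert f_stat == pytest.approx(f_oracle, rel=1e-9)
        assert p == pytest.approx(stats.f.sf(f_oracle, 1, len(t) - 4), rel=1e-9)

    def test_type_one_error_near_nominal(self, rng):
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            ga, gb = self.two_groups(1.5, 1.5, 1.0, rng, n_series=2, n_t=8)
            _f, p = compare_slopes_ancova(ga, gb)
            rejections += p < 0.05
        assert 0.02 <= rejections / n_rep <= 0.09

    def test_rejects_single_series_group(self, rng):
        ga, gb = self.two_groups(1, 1, 0.1, rng)
        with pytest.raises(ValueError, match="at least 2 series"):
            compare_slopes_ancova(ga[:1], gb)

    def test_per_cluster_alternative_runs(self, rng):
        ga, gb = self.two_groups(1.0, 3.0, 0.2, rng, n_series=4)
        _t, p = compare_slopes_per_cluster(ga, gb)
        assert p < 0.01


class TestHotelling:
    def test_identical_means_t2_zero_p_one(self, rng):
        a = rng.normal(size=(5, 3))
        b = a[::-1].copy()  # same sample mean vector, full-rank covariance
        res = hotelling_t2(a, b)
        assert res.t2 == pytest.approx(0.0, abs=1e-9)
        assert res.pvalue == pytest.approx(1.0)

    def test_p1_reduces_to_pooled_t_squared(self, rng):
        a = rng.normal(size=(7, 1))
        b = rng.normal(loc=0.8, size=(5, 1))
        res = hotelling_t2(a, b)
        t_stat = stats.ttest_ind(a.ravel(), b.ravel()).statistic
        assert res.t2 == pytest.approx(t_stat ** 2, rel=1e-9)

    def test_agrees_with_permutation_oracle(self, rng):
        a = rng.normal(size=(6, 3))
        b = rng.normal(loc=0.9, size=(5, 3))
        res = hotelling_t2(a, b)
        pooled = np.vstack([a, b])
        n1 = len(a)
        n_draw = 4000
        count = 0
        for _ in range(n_draw):
            perm = rng.permutation(len(pooled))
            t2 = hotelling_t2(pooled[perm[:n1]], pooled[perm[n1:]]).t2
            count += t2 >= res.t2 - 1e-12
        p_perm = count / n_draw
        se = np.sqrt(p_perm * (1 - p_perm) / n_draw)
        assert abs(res.pvalue - p_perm) < 3 * se + 0.01

    def test_rejects_singular_covariance(self):
        a = np.array([[1.0, 2.0, 3.0]] * 4)  # zero variance in every dim
        b = np.array([[2.0, 3.0, 4.0]] * 4)
        with pytest.raises(ValueError, match="singular"):
            hotelling_t2(a, b)

    def test_rejects_tiny_samples(self):
        with pytest.raises(ValueError):
            hotelling_t2([[1.0, 2, 3]], [[1.0, 2, 3], [2, 3, 4]])


class TestFdr:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_fdr([0.03]), [0.03])

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(adjust_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_matches_brute_force_loop(self, rng):
        def brute(p):
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            prev = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                val = min(p[i] * m / rank, prev)
                adj[i] = val
                prev = val
            return adj

        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 15))
            np.testing.assert_allclose(adjust_fdr(p), brute(p), rtol=1e-12)

    def test_never_decreases_and_caps_at_one(self, rng):
        p = rng.uniform(size=20)
        adj = adjust_fdr(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.2])


class TestRosettes:
    def test_five_wedges_one_rosette(self):
        rosettes = detect_rosettes(wedge_labels(5))
        assert len(rosettes) == 1
        assert rosettes[0]["labels"] == (1, 2, 3, 4, 5)

    def test_four_wedges_no_rosette(self):
        assert detect_rosettes(wedge_labels(4)) == []

    def test_empty_labeling(self):
        assert detect_rosettes(np.zeros((10, 10), dtype=int)) == []

    def test_matches_exhaustive_pixel_oracle(self, rng):
        # random Voronoi labeling from seed points
        seeds = rng.uniform(0, 60, size=(12, 2))
        yy, xx = np.mgrid[0:60, 0:60]
        d2 = (yy[..., None] - seeds[:, 0]) ** 2 + (xx[..., None] - seeds[:, 1]) ** 2
        labels = d2.argmin(axis=-1) + 1
        radius = 2
        hot_oracle = np.zeros((60, 60), dtype=bool)
        for y in range(60):
            for x in range(60):
                window = labels[max(y - radius, 0):y + radius + 1,
                                max(x - radius, 0):x + radius + 1]
                hot_oracle[y, x] = len(np.unique(window)) >= 5
        found = detect_rosettes(labels, radius=radius)
        # every oracle junction pixel must fall inside a reported rosette's label set
        from skimage import measure

        n_regions = measure.label(hot_oracle, connectivity=2).max()
        assert len(found) == n_regions


class TestTrackSpeed:
    def test_stationary_track(self):
        assert track_speed(np.tile([1.0, 2.0], (5, 1)), dt=1.0) == 0.0

    def test_straight_track(self):
        pts = np.column_stack([np.arange(5) * 2.0, np.zeros(5)])
        assert track_speed(pts, dt=10.0) == pytest.approx(0.2)

    def test_matches_brute_force_step_sum(self, rng):
        pts = rng.normal(size=(20, 2)).cumsum(axis=0)
        brute = sum(np.hypot(*(pts[i + 1] - pts[i])) for i in range(19)) / (19 * 2.5)
        assert track_speed(pts, dt=2.5) == pytest.approx(brute, rel=1e-12)

    def test_accepts_dataframe(self):
        df = pd.DataFrame({"frame": [0, 1, 2], "x": [0.0, 3.0, 3.0],
                           "y": [0.0, 4.0, 4.0]})
        assert track_speed(df, dt=1.0) == pytest.approx(2.5)

    def test_rejects_single_sample(self):
        with pytest.raises(ValueError):
            track_speed(np.array([[0.0, 0.0]]), dt=1.0)


class TestTrajectorySetValidation:
    def test_rejects_missing_columns(self):
        with pytest.raises(ValueError, match="missing columns"):
            TrajectorySet(data=pd.DataFrame({"track_id": [1], "frame": [0]}))

    def test_rejects_nonfinite_coordinates(self):
        df = pd.DataFrame({"track_id": [1], "frame": [0], "x": [np.nan], "y": [0.0]})
        with pytest.raises(ValueError, match="finite"):
            TrajectorySet(data=df)

    def test_rejects_duplicate_frames_in_track(self):
        df = pd.DataFrame({"track_id": [1, 1], "frame": [0, 0],
                           "x": [0.0, 1.0], "y": [0.0, 1.0]})
        with pytest.raises(ValueError, match="strictly increasing"):
            TrajectorySet(data=df)
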