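"""Geometric metrics against brute-force oracles and worked examples."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import cdist

import canopyqa as cq
from canopyqa import PointCloud, ValidationError


# ------------------------------------------------------------- oracles

def brute_neighbor_counts(coords, radius):
    d = cdist(coords, coords)
    return (d <= radius).sum(axis=1) - 1


def brute_density(coords, radius):
    counts = brute_neighbor_counts(coords, radius)
    return (3.0 * counts / (4.0 * np.pi * radius**3)).mean()


def brute_nearest(source, target):
    return cdist(source, target).min(axis=1)


def brute_precision(c1, c2, c3):
    d12 = brute_nearest(c1, c2)
    d13 = brute_nearest(c1, c3)
    d23 = brute_nearest(c2, c3)
    denom = 2 * len(c1) + len(c2)
    pr = (d12.sum() + d13.sum() + d23.sum()) / denom
    sq = sum(((d - pr) ** 2).sum() for d in (d12, d13, d23))
    return pr * 1000.0, np.sqrt(sq / denom) * 1000.0


# ------------------------------------------------- density / resolution

class TestNeighborCounts:
    def test_lone_point_has_no_neighbours(self):
        np.testing.assert_array_equal(
            cq.neighbor_counts(PointCloud([[1, 2, 3]]), 10.0), [0]
        )

    def test_sphere_boundary_is_inclusive(self):
        pair = PointCloud([[0, 0, 0], [1, 0, 0]])
        np.testing.assert_array_equal(cq.neighbor_counts(pair, 0.5), [0, 0])
        np.testing.assert_array_equal(cq.neighbor_counts(pair, 1.0), [1, 1])

    def test_unit_grid_matches_all_pairs_oracle(self):
        g = np.arange(5.0)
        coords = np.array(np.meshgrid(g, g, g)).reshape(3, -1).T
        counts = cq.neighbor_counts(PointCloud(coords), 1.05)
        np.testing.assert_array_equal(counts, brute_neighbor_counts(coords, 1.05))
        assert counts.max() == 6  # interior points: the six face neighbours

    def test_neighbour_relation_is_symmetric(self, random_cloud):
        counts = cq.neighbor_counts(random_cloud(300), 0.4)
        assert counts.sum() % 2 == 0  # every pair counted from both ends

    def test_non_positive_radius_rejected(self, random_cloud):
        with pytest.raises(ValidationError):
            cq.neighbor_counts(random_cloud(5), 0.0)


class TestPointDensity:
    def test_single_point_has_zero_density(self):
        assert cq.point_density(PointCloud([[0, 0, 0]]), 0.1).mean_density == 0.0

    def test_two_coincident_points_hand_value(self):
        # each point sees one neighbour: delta = 3/(4*pi*0.001)
        res = cq.point_density(PointCloud([[1, 1, 1], [1, 1, 1]]), 0.1)
        assert res.mean_density == pytest.approx(3 / (4 * np.pi * 1e-3))
        assert res.mean_density == pytest.approx(238.732, abs=1e-3)

    @pytest.mark.parametrize("n", [100, 1000, 2000])
    def test_matches_brute_force_exactly(self, n, random_cloud):
        cloud = random_cloud(n, scale=0.5, seed=n)
        res = cq.point_density(cloud, 0.1)
        np.testing.assert_array_equal(
            res.neighbor_counts, brute_neighbor_counts(cloud.coords, 0.1)
        )
        assert res.mean_density == brute_density(cloud.coords, 0.1)

    def test_empty_cloud_rejected(self):
        with pytest.raises(ValidationError):
            cq.point_density(PointCloud(np.empty((0, 3))), 0.1)


# ------------------------------------------------------------ accuracy

class TestAccuracyMetrics:
    def test_perfect_measurements(self):
        res = cq.accuracy_metrics([500, 500, 500], 500)
        assert res.accuracy == 0.0 and res.rmse == 0.0

    def test_hand_worked_example(self):
        res = cq.accuracy_metrics([498, 502, 500, 504], 500)
        assert res.accuracy == pytest.approx(2.0)
        assert res.rmse == pytest.approx(np.sqrt(6))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(1, 1000), min_size=1, max_size=30),
        st.floats(1, 1000),
    )
    def test_rmse_never_below_accuracy(self, measurements, reference):
        res = cq.accuracy_metrics(measurements, reference)
        assert res.rmse >= res.accuracy - 1e-9

    def test_empty_measurements_rejected(self):
        with pytest.raises(ValidationError):
            cq.accuracy_metrics([], 500)


# -------------------------------------------------------- repeatability

class TestCloudToCloudDistances:
    def test_identical_clouds_give_zero(self, random_cloud):
        cloud = random_cloud(50)
        np.testing.assert_array_equal(
            cq.cloud_to_cloud_distances(cloud, cloud), np.zeros(50)
        )

    def test_nearest_of_two_targets(self):
        src = PointCloud([[0, 0, 0]])
        tgt = PointCloud([[1, 0, 0], [0, 2, 0]])
        np.testing.assert_allclose(cq.cloud_to_cloud_distances(src, tgt), [1.0])

    def test_matches_exhaustive_search(self, random_cloud):
        src, tgt = random_cloud(200, seed=1), random_cloud(300, seed=2)
        got = cq.cloud_to_cloud_distances(src, tgt)
        np.testing.assert_allclose(
            got, brute_nearest(src.coords, tgt.coords), rtol=0, atol=1e-12
        )

    def test_invariant_under_target_permutation(self, random_cloud, rng):
        src, tgt = random_cloud(100, seed=3), random_cloud(150, seed=4)
        perm = rng.permutation(150)
        shuffled = PointCloud(tgt.coords[perm])
        np.testing.assert_allclose(
            cq.cloud_to_cloud_distances(src, tgt),
            cq.cloud_to_cloud_distances(src, shuffled),
        )


class TestPrecisionMetrics:
    def test_identical_replicates_are_perfectly_repeatable(self, random_cloud):
        cloud = random_cloud(100)
        res = cq.precision_metrics([cloud, cloud, cloud])
        assert res.precision_error == 0.0 and res.std_dev == 0.0

    def test_single_point_worked_example(self):
        """Three one-point replicates: Pr = (2 + sqrt(2))/3 m."""
        reps = [
            PointCloud([[0, 0, 0]]),
            PointCloud([[1, 0, 0]]),
            PointCloud([[1, 1, 0]]),
        ]
        res = cq.precision_metrics(reps)
        assert res.precision_error == pytest.approx((2 + np.sqrt(2)) / 3 * 1000)
        sigma = np.sqrt(
            (2 * (1 - (2 + np.sqrt(2)) / 3) ** 2
             + (np.sqrt(2) - (2 + np.sqrt(2)) / 3) ** 2) / 3
        )
        assert res.std_dev == pytest.approx(sigma * 1000)
        assert res.std_dev == pytest.approx(195.26, abs=0.01)

    @pytest.mark.parametrize("sizes", [(300, 250, 280), (50, 300, 120)])
    def test_matches_independent_brute_force(self, sizes, random_cloud):
        reps = [random_cloud(n, seed=10 + k) for k, n in enumerate(sizes)]
        res = cq.precision_metrics(reps)
        pr, sigma = brute_precision(*(r.coords for r in reps))
        assert res.precision_error == pytest.approx(pr, rel=1e-12)
        assert res.std_dev == pytest.approx(sigma, rel=1e-12)

    def test_scale_covariance(self, random_cloud):
        reps = [random_cloud(80, seed=20 + k) for k in range(3)]
        base = cq.precision_metrics(reps)
        scaled = cq.precision_metrics(
            [PointCloud(r.coords * 2.5) for r in reps]
        )
        assert scaled.precision_error == pytest.approx(2.5 * base.precision_error)
        assert scaled.std_dev == pytest.approx(2.5 * base.std_dev)

    def test_exactly_three_replicates_required(self, random_cloud):
        with pytest.raises(ValidationError, match="exactly 3"):
            cq.precision_metrics([random_cloud(5), random_cloud(5)])

    def test_symmetric_variant_accepts_two_and_is_order_free(self, random_cloud):
        reps = [random_cloud(40, seed=30 + k) for k in range(2)]
        a = cq.precision_metrics_symmetric(reps)
        b = cq.precision_metrics_symmetric(reps[::-1])
        assert a.precision_error == pytest.approx(b.precision_error)


# ------------------------------------------------------- penetrability

class TestPenetrabilityProfile:
    def test_single_depth_degenerate(self):
        cloud = PointCloud([[0, 0.3, 0], [1, 0.3, 0], [2, 0.3, 0]])
        prof = cq.penetrability_profile(cloud, "y")
        assert prof.percentages.tolist() == [100.0]
        assert prof.std_depth == 0.0

    def test_three_section_worked_example(self):
        cloud = PointCloud([[0, 0.05, 0], [0, 0.15, 0], [0, 0.25, 0]])
        prof = cq.penetrability_profile(cloud, "y", bin_width=0.1, origin=0.0)
        np.testing.assert_allclose(prof.percentages, [100 / 3] * 3)
        assert prof.mean_depth == pytest.approx(0.15)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(1, 500))
    def test_percentages_conserve_mass_and_mean_in_range(self, seed, n):
        coords = np.random.default_rng(seed).uniform(0, 2, (n, 3))
        prof = cq.penetrability_profile(PointCloud(coords), "y")
        assert prof.percentages.sum() == pytest.approx(100.0, abs=1e-6)
        rel = coords[:, 1] - coords[:, 1].min()
        assert prof.mean_depth == pytest.approx(rel.mean())
        assert 0 <= prof.mean_depth <= rel.max() + 1e-12

    def test_shared_origin_for_two_station_comparison(self):
        a = PointCloud([[0, 0.5, 0], [0, 0.7, 0]])
        prof = cq.penetrability_profile(a, "y", origin=0.2)
        assert prof.mean_depth == pytest.approx(0.4)
        assert prof.bin_edges[0] == pytest.approx(0.2)


# ----------------------------------------------------------- trend fit

class TestTrendFit:
    def test_recovers_exact_line(self):
        x = np.arange(10.0)
        slope, intercept, r2 = cq.trend_fit(x, -2.4 * x + 100)
        assert slope == pytest.approx(-2.4)
        assert intercept == pytest.approx(100)
        assert r2 == pytest.approx(1.0)

    def test_constant_response_explains_nothing(self):
        slope, _, r2 = cq.trend_fit([1, 2, 3, 4], [7, 7, 7, 7])
        assert slope == 0.0 and r2 == 0.0

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.uniform(0, 60000, 10)
        y = -1.7 * x + 2e5 + rng.normal(0, 1e4, 10)
        slope, intercept, r2 = cq.trend_fit(x, y)
        # closed-form OLS
        A = np.vstack([x, np.ones_like(x)]).T
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        resid = y - A @ beta
        r2_oracle = 1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()
        assert slope == pytest.approx(beta[0])
        assert intercept == pytest.approx(beta[1])
        assert r2 == pytest.approx(r2_oracle)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValidationError):
            cq.trend_fit([5, 5, 5], [1, 2, 3])
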