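import numpy as np
import pytest

from spatialcv import (
    empirical_variogram,
    estimate_range,
    pairwise_distances,
    residual_variogram,
    simulate_grf,
    theoretical_semivariance,
)


def brute_force_variogram(values, coords, bin_width, max_lag):
    """Independent oracle: enumerate every pair with a double loop."""
    n = len(values)
    n_bins = int(np.ceil(max_lag / bin_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = np.hypot(*(np.asarray(coords[i]) - np.asarray(coords[j])))
            b = int(d // bin_width)
            if b < n_bins:
                sums[b] += (values[i] - values[j]) ** 2
                counts[b] += 1
    gamma = np.where(counts > 0, sums / np.maximum(2 * counts, 1), np.nan)
    return gamma, counts


class TestPairwiseDistances:
    def test_three_four_five(self):
        d = pairwise_distances([(0, 0), (3, 4)])
        assert d[0, 1] == pytest.approx(5.0)
        assert d[1, 0] == pytest.approx(5.0)
        assert d[0, 0] == 0.0

    def test_matches_brute_force(self, rng):
        pts = rng.uniform(0, 50, size=(10, 2))
        d = pairwise_distances(pts)
        for i in range(10):
            for j in range(10):
                assert d[i, j] == pytest.approx(np.hypot(*(pts[i] - pts[j])))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            pairwise_distances([(0, 0), (np.nan, 1)])


class TestEmpiricalVariogram:
    def test_constant_field_zero_everywhere(self, rng):
        coords = rng.uniform(0, 100, size=(30, 2))
        vg = empirical_variogram(np.full(30, 7.0), coords)
        assert np.all(vg.semivariance[vg.pair_counts > 0] == 0.0)

    def test_collinear_hand_enumeration(self):
        coords = [(0, 0), (1, 0), (2, 0), (3, 0)]
        values = [0.0, 1.0, 0.0, 1.0]
        vg = empirical_variogram(values, coords, bin_width=1.0, max_lag=4.0)
        # lag-1 pairs: (0,1),(1,2),(2,3) -> mean sq diff 1, gamma 0.5
        assert vg.semivariance[1] == pytest.approx(0.5)
        assert vg.pair_counts[1] == 3
        # lag-2 pairs: (0,2),(1,3) -> identical values
        assert vg.semivariance[2] == 0.0
        assert vg.pair_counts[2] == 2
        # lag-3 pair: (0,3)
        assert vg.semivariance[3] == pytest.approx(0.5)
        assert vg.pair_counts[3] == 1

    def test_matches_brute_force_enumeration(self, rng):
        coords = rng.uniform(0, 200, size=(50, 2))
        values = rng.normal(size=50)
        vg = empirical_variogram(values, coords, bin_width=15.0, max_lag=120.0)
        gamma, counts = brute_force_variogram(values, coords, 15.0, 120.0)
        np.testing.assert_array_equal(vg.pair_counts, counts)
        np.testing.assert_allclose(
            vg.semivariance[counts > 0], gamma[counts > 0], rtol=1e-12
        )

    def test_empty_bins_are_nan_not_zero(self):
        coords = [(0, 0), (1, 0), (100, 0), (101, 0)]
        vg = empirical_variogram([0, 1, 2, 3], coords, bin_width=10.0, max_lag=60.0)
        assert vg.pair_counts[2] == 0
        assert np.isnan(vg.semivariance[2])

    def test_permutation_invariance(self, rng):
        coords = rng.uniform(0, 100, size=(25, 2))
        values = rng.normal(size=25)
        perm = rng.permutation(25)
        vg1 = empirical_variogram(values, coords, bin_width=10.0, max_lag=50.0)
        vg2 = empirical_variogram(values[perm], coords[perm],
                                  bin_width=10.0, max_lag=50.0)
        np.testing.assert_allclose(vg1.semivariance, vg2.semivariance)
        np.testing.assert_array_equal(vg1.pair_counts, vg2.pair_counts)

    def test_doubling_values_quadruples_gamma(self, rng):
        coords = rng.uniform(0, 100, size=(20, 2))
        values = rng.normal(size=20)
        vg1 = empirical_variogram(values, coords, bin_width=10.0, max_lag=50.0)
        vg2 = empirical_variogram(2 * values, coords, bin_width=10.0, max_lag=50.0)
        ok = vg1.pair_counts > 0
        np.testing.assert_allclose(vg2.semivariance[ok], 4 * vg1.semivariance[ok])

    def test_tracks_theoretical_curve(self):
        """Average empirical variogram of simulated fields matches theory."""
        gammas = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            coords = rng.uniform(0, 1000, size=(800, 2))
            z = simulate_grf(coords, "exponential", 120.0, 1.0, seed=seed)
            vg = empirical_variogram(z, coords, bin_width=20.0, max_lag=300.0)
            gammas.append(vg.semivariance)
        mean_gamma = np.nanmean(gammas, axis=0)
        centers = vg.bin_centers
        theory = theoretical_semivariance(centers, "exponential", 120.0, 1.0)
        np.testing.assert_allclose(mean_gamma, theory, atol=0.12)

    def test_rejects_single_sample(self):
        with pytest.raises(ValueError):
            empirical_variogram([1.0], [(0, 0)])


class TestEstimateRange:
    def test_noiseless_exponential_recovery(self):
        centers = np.arange(5.0, 400.0, 10.0)
        gamma = theoretical_semivariance(centers, "exponential", 120.0, 1.0)
        from spatialcv.variogram import VariogramEstimate

        est = estimate_range(
            VariogramEstimate(
                bin_edges=np.arange(0.0, 401.0, 10.0),
                bin_centers=centers,
                semivariance=gamma,
                pair_counts=np.full(len(centers), 100),
                n_samples=1000,
            ),
            "exponential",
        )
        assert est.spatial_structure
        assert est.range_km == pytest.approx(120.0, abs=1.0)
        assert est.sill == pytest.approx(1.0, abs=0.01)

    def test_flat_variogram_flags_no_structure(self):
        from spatialcv.variogram import VariogramEstimate

        centers = np.arange(5.0, 200.0, 10.0)
        est = estimate_range(
            VariogramEstimate(
                bin_edges=np.arange(0.0, 201.0, 10.0),
                bin_centers=centers,
                semivariance=np.full(len(centers), 2.0),
                pair_counts=np.full(len(centers), 50),
                n_samples=500,
            ),
            "exponential",
        )
        assert not est.spatial_structure
        assert np.isnan(est.range_km)

    def test_spherical_practical_range_below_model_range(self):
        centers = np.arange(5.0, 400.0, 10.0)
        gamma = theoretical_semivariance(centers, "spherical", 200.0, 1.0)
        from spatialcv.variogram import VariogramEstimate

        est = estimate_range(
            VariogramEstimate(
                bin_edges=np.arange(0.0, 401.0, 10.0),
                bin_centers=centers,
                semivariance=gamma,
                pair_counts=np.full(len(centers), 100),
                n_samples=1000,
            ),
            "spherical",
        )
        assert est.spatial_structure
        # γ reaches 95% of the sill before the spherical model range
        assert 100.0 < est.range_km <= 200.0

    def test_too_few_bins_raise(self):
        from spatialcv.variogram import VariogramEstimate

        vg = VariogramEstimate(
            bin_edges=np.arange(0.0, 31.0, 10.0),
            bin_centers=np.array([5.0, 15.0, 25.0]),
            semivariance=np.array([0.1, 0.2, 0.3]),
            pair_counts=np.array([5, 5, 5]),
            n_samples=10,
        )
        with pytest.raises(ValueError):
            estimate_range(vg)


class TestResidualVariogram:
    def test_perfect_predictions_all_zero(self, rng):
        coords = rng.uniform(0, 100, size=(20, 2))
        y = rng.normal(size=20)
        vg = residual_variogram(y, y, coords)
        assert np.all(vg.semivariance[vg.pair_counts > 0] == 0.0)

    def test_missing_predictions_rejected(self, rng):
        coords = rng.uniform(0, 100, size=(10, 2))
        y = rng.normal(size=10)
        pred = y.copy()
        pred[3] = np.nan
        with pytest.raises(ValueError):
            residual_variogram(y, pred, coords)
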