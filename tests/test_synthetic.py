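import numpy as np
import pytest

from spatialcv import (
    FieldSpec,
    ScenarioConfig,
    SampleSet,
    build_scenario,
    empirical_variogram,
    estimate_range,
    sample_clustered_layout,
    simulate_grf,
    spurious_skill_scenario,
)


class TestSimulateGrf:
    def test_degenerate_process_is_constant(self, rng):
        coords = rng.uniform(0, 100, size=(15, 2))
        z = simulate_grf(coords, "exponential", 120.0, sill=0.0, nugget=0.0,
                         mean=7.0, seed=0)
        np.testing.assert_array_equal(z, np.full(15, 7.0))

    def test_nugget_only_variance(self):
        """Monte-Carlo check: a pure-nugget field has the stated variance."""
        variances = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            coords = rng.uniform(0, 100, size=(10_000, 2))
            z = simulate_grf(coords, "nugget", sill=0.0, nugget=2.0, seed=seed)
            variances.append(z.var())
        assert np.mean(variances) == pytest.approx(2.0, rel=0.10)

    def test_seed_determinism(self, rng):
        coords = rng.uniform(0, 500, size=(50, 2))
        z1 = simulate_grf(coords, "exponential", 120.0, 1.0, seed=42)
        z2 = simulate_grf(coords, "exponential", 120.0, 1.0, seed=42)
        np.testing.assert_array_equal(z1, z2)

    def test_nonpositive_range_rejected(self, rng):
        coords = rng.uniform(0, 100, size=(5, 2))
        with pytest.raises(ValueError):
            simulate_grf(coords, "exponential", range_km=0.0, sill=1.0)

    def test_cap_enforced(self):
        coords = np.zeros((6001, 2))
        with pytest.raises(ValueError, match="cap"):
            simulate_grf(coords, "exponential", 120.0, 1.0)

    def test_spherical_model_runs(self, rng):
        coords = rng.uniform(0, 500, size=(100, 2))
        z = simulate_grf(coords, "spherical", 200.0, 1.5, seed=1)
        assert np.isfinite(z).all()


class TestClusteredLayout:
    def test_zero_radius_collapses_to_center(self):
        pts = sample_clustered_layout((100, 100), 1, 5, 0.0, seed=0)
        assert pts.shape == (5, 2)
        assert np.all(pts == pts[0])

    def test_counts_and_bounds(self):
        pts = sample_clustered_layout((1000, 1000), 44, 50, 20.0, seed=3)
        assert pts.shape == (2200, 2)
        assert pts.min() >= 0.0
        assert pts.max() <= 1000.0

    def test_nearest_neighbor_bimodality(self):
        """Within-cluster spacing is far below between-cluster spacing."""
        from scipy.spatial.distance import pdist, squareform

        pts = sample_clustered_layout((1000, 1000), 10, 20, 5.0, seed=7)
        d = squareform(pdist(pts))
        np.fill_diagonal(d, np.inf)
        nn = d.min(axis=0)
        # cluster centers are ~hundreds of km apart, members a few km
        assert np.median(nn) < 10.0
        centers = pts.reshape(10, 20, 2).mean(axis=1)
        dc = squareform(pdist(centers))
        np.fill_diagonal(dc, np.inf)
        assert dc.min(axis=0).min() > 30.0

    def test_invalid_extent(self):
        with pytest.raises(ValueError):
            sample_clustered_layout((0, 100), 2, 5, 1.0, seed=0)


class TestBuildScenario:
    def test_identity_effect(self):
        """β=(1,0,0) with no noise reproduces the first covariate exactly."""
        cfg = ScenarioConfig(
            extent=(500, 500), n_samples=100, layout="uniform",
            field_specs=(FieldSpec("a", "exponential", 100, 1.0),
                         FieldSpec("b", "exponential", 100, 1.0),
                         FieldSpec("c", "exponential", 100, 1.0)),
            effect_coefficients=(1.0, 0.0, 0.0),
            response_spatial=FieldSpec("rs", "exponential", 120, 0.0),
            iid_noise_sd=0.0, seed=5,
        )
        ss = build_scenario(cfg)
        np.testing.assert_allclose(ss.response, ss.frame["a"])

    def test_zero_effect_independence(self):
        """With β=0 the response is uncorrelated with every covariate."""
        rs = []
        for seed in range(10):
            cfg = ScenarioConfig(
                extent=(1000, 1000), n_samples=2000, layout="uniform",
                field_specs=(FieldSpec("a", "nugget", 1.0, 0.0, 1.0),),
                effect_coefficients=(0.0,),
                response_spatial=FieldSpec("rs", "nugget", 1.0, 0.0, 0.0),
                iid_noise_sd=1.0, seed=seed,
            )
            ss = build_scenario(cfg)
            rs.append(abs(np.corrcoef(ss.response, ss.frame["a"])[0, 1]))
        assert np.mean(rs) < 0.1

    def test_byte_identical_regeneration(self):
        cfg = spurious_skill_scenario(seed=9, n_samples=200)
        s1, s2 = build_scenario(cfg), build_scenario(cfg)
        assert s1.frame.equals(s2.frame)
        assert s1.frame.to_csv() == s2.frame.to_csv()

    def test_mismatched_beta_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(
                field_specs=(FieldSpec("a"),),
                effect_coefficients=(1.0, 2.0),
            )

    def test_provenance_carries_truth(self):
        cfg = spurious_skill_scenario(seed=2, n_samples=200)
        ss = build_scenario(cfg)
        assert ss.provenance["true_beta"] == [0.0] * 5
        assert ss.provenance["response_range_km"] == 120.0

    def test_variance_decomposition(self):
        """β=0: total response variance ≈ spatial sill + iid noise variance."""
        totals = []
        for seed in range(10):
            cfg = ScenarioConfig(
                extent=(1000, 1000), n_samples=2000, layout="uniform",
                field_specs=(), effect_coefficients=(),
                response_spatial=FieldSpec("rs", "exponential", 120.0, 1.0),
                iid_noise_sd=0.5, seed=seed,
            )
            totals.append(build_scenario(cfg).response.var())
        assert np.mean(totals) == pytest.approx(1.0 + 0.25, rel=0.15)

    def test_range_recovery_from_variogram(self):
        """Variogram range estimate recovers the generating range within 25%."""
        estimates = []
        for seed in range(10):
            cfg = ScenarioConfig(
                extent=(1000, 1000), n_samples=1000, layout="uniform",
                field_specs=(), effect_coefficients=(),
                response_spatial=FieldSpec("rs", "exponential", 120.0, 1.0),
                iid_noise_sd=0.0, seed=100 + seed,
            )
            ss = build_scenario(cfg)
            vg = empirical_variogram(ss.response, ss.coords, bin_width=20.0,
                                     max_lag=400.0)
            est = estimate_range(vg, "exponential")
            assert est.spatial_structure
            estimates.append(est.range_km)
        assert np.mean(estimates) == pytest.approx(120.0, rel=0.25)


class TestSampleSetValidation:
    def test_duplicate_ids_rejected(self):
        import pandas as pd

        frame = pd.DataFrame({"id": [1, 1], "x_km": [0.0, 1.0],
                              "y_km": [0.0, 1.0], "response": [1.0, 2.0]})
        with pytest.raises(ValueError, match="unique"):
            SampleSet(frame)

    def test_duplicate_coordinates_flagged(self):
        import pandas as pd

        frame = pd.DataFrame({"id": [0, 1], "x_km": [1.0, 1.0],
                              "y_km": [2.0, 2.0], "response": [1.0, 2.0]})
        with pytest.raises(ValueError, match="duplicated"):
            SampleSet(frame)
        SampleSet(frame, allow_duplicate_coordinates=True)  # explicit opt-in

    def test_csv_roundtrip(self, tmp_path, toy_sample_set):
        path = tmp_path / "s.csv"
        toy_sample_set.to_csv(path)
        back = SampleSet.from_csv(path)
        np.testing.assert_allclose(back.response, toy_sample_set.response)
        assert back.covariate_names == toy_sample_set.covariate_names
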