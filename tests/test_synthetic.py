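"""Synthetic survey generator: determinism, sampling design, latent field,
outcomes and GPS-style displacement."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import geoprev as gp
from geoprev.matern import MaternParams
from geoprev.synthetic import (
    SyntheticConfig,
    displace_coordinates,
    generate_covariate_fields,
    generate_survey,
    sample_clusters,
    simulate_outcomes,
    simulate_spatial_field,
)


def small_config(**kw):
    defaults = dict(domain_extent=(0.0, 0.0, 50.0, 50.0), n_clusters=60,
                    grid_cellsize=2.5, seed=5)
    defaults.update(kw)
    return SyntheticConfig(**defaults)


class TestCovariateFields:
    def test_deterministic_given_seed(self):
        cfg = small_config()
        a = generate_covariate_fields(cfg, 2)
        b = generate_covariate_fields(cfg, 2)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.values, rb.values)

    def test_standardized_to_zero_mean_unit_sd(self):
        for ras in generate_covariate_fields(small_config(), 3):
            assert abs(ras.values.mean()) < 1e-10
            assert abs(ras.values.std() - 1.0) < 1e-10

    def test_positive_lag_one_autocorrelation(self):
        # empirical correlogram oracle at one-cell lag, horizontally and
        # vertically, on a grid fine relative to the field wavelengths
        for ras in generate_covariate_fields(small_config(seed=9, grid_cellsize=1.0), 3):
            v = ras.values
            for a, b in [(v[:, :-1], v[:, 1:]), (v[:-1, :], v[1:, :])]:
                r = np.corrcoef(a.ravel(), b.ravel())[0, 1]
                assert r > 0.2

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            generate_covariate_fields(small_config(), 0)
        with pytest.raises(ValueError):
            small_config(grid_cellsize=-1.0)


class TestSampleClusters:
    def test_exact_urban_rounding(self):
        cfg = small_config(n_clusters=10, urban_fraction=0.5)
        assert sample_clusters(cfg)["urban"].sum() == 5

    def test_zero_weight_cv_gives_equal_weights(self):
        tbl = sample_clusters(small_config(weight_cv=0.0))
        np.testing.assert_allclose(tbl["weight"], 1.0)

    def test_empirical_weight_cv_near_configured(self):
        cfg = small_config(n_clusters=400, weight_cv=0.5, seed=21)
        w = sample_clusters(cfg)["weight"]
        cv = w.std() / w.mean()
        assert abs(cv - 0.5) / 0.5 < 0.2

    def test_points_inside_domain(self):
        cfg = small_config(n_clusters=200, urban_fraction=0.4)
        tbl = sample_clusters(cfg)
        assert tbl["x"].between(0, 50).all() and tbl["y"].between(0, 50).all()

    def test_invalid_urban_fraction_rejected(self):
        with pytest.raises(ValueError):
            small_config(urban_fraction=1.5)


class TestSpatialField:
    def test_zero_variance_gives_zero_field(self):
        S = simulate_spatial_field(np.random.default_rng(0).uniform(0, 10, (30, 2)),
                                   MaternParams(0.0, 1.0, 1.0), seed=1)
        np.testing.assert_array_equal(S, 0.0)

    def test_single_location_is_standard_normal(self):
        draws = np.array([
            simulate_spatial_field([[0.0, 0.0]], MaternParams(1.0, 1.0, 1.0), seed=s)[0]
            for s in range(10000)])
        assert abs(draws.var() - 1.0) < 0.05
        assert abs(draws.mean()) < 0.05

    def test_near_coincident_points_nearly_equal(self):
        locs = [[0.0, 0.0], [1e-7, 0.0]]
        params = MaternParams(1.0, 0.01, 1.0)  # practical range >> spacing
        diffs = [np.diff(simulate_spatial_field(locs, params, seed=s))[0]
                 for s in range(500)]
        assert np.std(diffs) < 0.05 * np.sqrt(params.sigma2)

    def test_variogram_monotone_up_to_practical_range(self):
        # moments over replicate draws at fixed sites: mean squared increment
        # must rise with distance bin below the practical range
        rng = np.random.default_rng(3)
        sites = rng.uniform(0, 10, (400, 2))
        params = MaternParams(1.0, 1.0, 1.0)  # practical range ~ 2.8
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(sites))
        iu = np.triu_indices_from(d, k=1)
        bins = np.array([0.0, 0.7, 1.4, 2.1, 2.8])
        which = np.digitize(d[iu], bins) - 1
        acc = np.zeros(4)
        cnt = np.zeros(4)
        for rep in range(20):
            S = simulate_spatial_field(sites, params, seed=100 + rep)
            sq = (S[iu[0]] - S[iu[1]]) ** 2
            for b in range(4):
                sel = which == b
                acc[b] += sq[sel].sum()
                cnt[b] += sel.sum()
        gamma = acc / cnt
        assert np.all(np.diff(gamma) > 0)


class TestOutcomes:
    def test_symmetric_null_prevalence(self):
        cfg = small_config(n_clusters=500, children_mean=20.0, seed=2)
        tbl = sample_clusters(cfg)
        tbl["cov_1"] = 0.0
        out = simulate_outcomes(tbl, 0.0, [0.0], np.zeros(len(tbl)), cfg)
        total_n = out["n"].sum()
        pooled = out["y_stunted"].sum() / total_n
        se = np.sqrt(0.25 / total_n)
        assert abs(pooled - 0.5) < 2 * se

    def test_empty_cluster_has_zero_cases(self):
        cfg = small_config(children_mean=0.2, children_dispersion=0.5, seed=3)
        tbl = sample_clusters(cfg)
        out = simulate_outcomes(tbl, 0.0, [], np.zeros(len(tbl)), cfg)
        assert ((out["n"] > 0) | (out["y_stunted"] == 0)).all()
        assert (out.loc[out["n"] == 0, "y_stunted"] == 0).all()

    def test_pooled_prevalence_tracks_inverse_logit_of_intercept(self):
        # intercept matching the reported spatial-model posterior mean
        cfg = small_config(n_clusters=800, children_mean=20.0, seed=4)
        tbl = sample_clusters(cfg)
        out = simulate_outcomes(tbl, -0.3007, [], np.zeros(len(tbl)), cfg)
        expected = expit(-0.3007)  # = 0.425399... by direct logistic evaluation
        pooled = out["y_stunted"].sum() / out["n"].sum()
        se = np.sqrt(expected * (1 - expected) / out["n"].sum())
        assert expected == pytest.approx(0.4253863713, abs=1e-9)
        assert abs(pooled - expected) < 3 * se

    def test_nonfinite_predictor_rejected(self):
        cfg = small_config()
        tbl = sample_clusters(cfg)
        tbl["cov_1"] = np.nan
        with pytest.raises(ValueError):
            simulate_outcomes(tbl, 0.0, [1.0], np.zeros(len(tbl)), cfg)


class TestDisplacement:
    def test_radii_respected_by_strata(self):
        cfg = small_config(n_clusters=300, urban_fraction=0.5, seed=6)
        tbl = sample_clusters(cfg)
        moved = displace_coordinates(tbl, seed=13)
        d = np.hypot(moved["x"] - tbl["x"], moved["y"] - tbl["y"])
        assert (d[tbl["urban"]] <= 2.0).all()
        assert (d[~tbl["urban"]] <= 5.0).all()

    def test_deterministic_given_seed(self):
        tbl = sample_clusters(small_config(seed=7))
        a = displace_coordinates(tbl, seed=99)
        b = displace_coordinates(tbl, seed=99)
        pd.testing.assert_frame_equal(a, b)


class TestFullGenerator:
    def test_bit_reproducible(self):
        cfg = small_config(seed=8)
        ta, tra = generate_survey(cfg)
        tb, trb = generate_survey(cfg)
        pd.testing.assert_frame_equal(ta, tb)
        np.testing.assert_array_equal(tra.p_surface.values, trb.p_surface.values)

    def test_truth_surface_consistent_with_linear_predictor(self):
        _, truth = generate_survey(small_config(seed=10))
        truth.check_consistency(atol=1e-8)

    def test_truth_prevalence_in_open_unit_interval(self):
        _, truth = generate_survey(small_config(seed=12))
        assert np.all(truth.p_surface.values > 0) and np.all(truth.p_surface.values < 1)

    def test_displacement_flag_keeps_truth_coordinates(self):
        cfg = small_config(seed=14)
        tbl, truth = generate_survey(cfg, displace=True)
        d = np.hypot(tbl["x"] - truth.true_coords[:, 0], tbl["y"] - truth.true_coords[:, 1])
        assert (d <= 5.0 + 1e-9).all() and d.max() > 0
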