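"""Kriging prediction, prevalence/exceedance surfaces and validation."""

import numpy as np
import pandas as pd
import pytest

import geoprev as gp
from geoprev.matern import MaternParams, matern_correlation
from geoprev.predict import (
    exceedance_surface,
    kriging_moments,
    observed_vs_predicted,
    predict_latent_field,
    prevalence_surface,
)
from geoprev.raster import RasterGrid

from .helpers import degenerate_spatial_fit


def toy_sites_and_field(seed=0, n=3):
    rng = np.random.default_rng(seed)
    sites = rng.uniform(0, 4, (n, 2))
    S = rng.normal(0, 0.5, n)
    return sites, S


class TestKrigingMoments:
    def test_matches_closed_form_conditional_mvn(self):
        # brute-force conditional-normal oracle on a 3-cluster toy
        sites, S = toy_sites_and_field(seed=1)
        sigma2, kappa, nu, jit = 0.8, 1.2, 1.0, 1e-8
        new = np.array([[1.0, 2.0], [3.3, 0.4]])
        mean, var = kriging_moments(sites, S, sigma2, kappa, nu, new, jit)
        from scipy.spatial.distance import cdist

        K = sigma2 * (matern_correlation(cdist(sites, sites), kappa, nu) + jit * np.eye(3))
        c = sigma2 * matern_correlation(cdist(new, sites), kappa, nu)
        Kinv = np.linalg.inv(K)
        np.testing.assert_allclose(mean, c @ Kinv @ S, atol=1e-8)
        np.testing.assert_allclose(
            var, sigma2 * (1 + jit) - np.einsum("ij,jk,ik->i", c, Kinv, c), atol=1e-8)

    def test_exact_at_observed_site(self):
        sites, S = toy_sites_and_field(seed=2, n=5)
        mean, var = kriging_moments(sites, S, 1.0, 0.8, 1.0, sites[[2]], 1e-8)
        assert mean[0] == pytest.approx(S[2], abs=1e-5)
        assert var[0] < 1e-6

    def test_reverts_to_prior_far_away(self):
        sites, S = toy_sites_and_field(seed=3, n=4)
        far = np.array([[500.0, 500.0]])
        mean, var = kriging_moments(sites, S, 0.7, 1.0, 1.0, far)
        assert abs(mean[0]) < 1e-8
        assert var[0] == pytest.approx(0.7, rel=1e-6)


class TestPredictLatentField:
    def test_site_draws_reproduced_at_cluster_locations(self):
        sites, _ = toy_sites_and_field(seed=4, n=6)
        rng = np.random.default_rng(5)
        latent = rng.normal(0, 0.6, (20, 6))
        fit = degenerate_spatial_fit(sites, latent, sigma2=0.5, kappa=1.0)
        pred = predict_latent_field(fit, sites, seed=0)
        np.testing.assert_allclose(pred, latent, atol=1e-3)

    def test_deterministic_given_seed(self):
        sites, S = toy_sites_and_field(seed=6, n=5)
        fit = degenerate_spatial_fit(sites, np.tile(S, (10, 1)), 0.4, 1.0)
        new = np.array([[2.0, 2.0], [0.5, 3.0]])
        a = predict_latent_field(fit, new, seed=11)
        b = predict_latent_field(fit, new, seed=11)
        np.testing.assert_array_equal(a, b)

    def test_far_field_draw_moments_revert_to_prior(self):
        sites, S = toy_sites_and_field(seed=7, n=4)
        fit = degenerate_spatial_fit(sites, np.tile(S, (4000, 1)), sigma2=0.9, kappa=2.0)
        draws = predict_latent_field(fit, [[900.0, 900.0]], seed=3)
        assert abs(draws.mean()) < 0.05
        assert draws.var() == pytest.approx(0.9, rel=0.1)


def surface_inputs(fit_draws=60, grid_n=8, seed=8):
    rng = np.random.default_rng(seed)
    sites = rng.uniform(0, 10, (12, 2))
    latent = rng.normal(0, 0.5, (fit_draws, 12))
    fit = degenerate_spatial_fit(sites, latent, sigma2=0.25, kappa=0.5, alpha=-0.5)
    grid = RasterGrid(np.full((grid_n, grid_n), np.nan), xll=0.0, yll=0.0,
                      cellsize=10.0 / grid_n)
    return fit, grid


class TestSurfaces:
    def test_ci_width_definitional_and_ordering(self):
        fit, grid = surface_inputs()
        surf = prevalence_surface(fit, grid, {}, thresholds=(0.25,), seed=1)
        np.testing.assert_allclose(surf.ci_width.values,
                                   surf.ci_upper.values - surf.ci_lower.values,
                                   atol=1e-12)
        assert np.all(surf.ci_lower.values <= surf.mean_prev.values + 1e-9)
        assert np.all(surf.mean_prev.values <= surf.ci_upper.values + 1e-9)
        assert np.all((surf.mean_prev.values > 0) & (surf.mean_prev.values < 1))

    def test_exceedance_equals_direct_draw_count(self):
        fit, grid = surface_inputs()
        surf = prevalence_surface(fit, grid, {}, thresholds=(0.25,), seed=2,
                                  keep_draws=True)
        recount = (surf.draws > 0.25).mean(axis=0)
        got = surf.exceedance[0.25].values.ravel()[surf.valid_mask]
        np.testing.assert_allclose(got, recount, atol=1e-12)

    def test_exceedance_limits_and_monotonicity(self):
        fit, grid = surface_inputs()
        surf = prevalence_surface(fit, grid, {}, thresholds=(1e-9, 0.2, 0.5, 1 - 1e-9),
                                  seed=3)
        np.testing.assert_allclose(surf.exceedance[1e-9].values, 1.0)
        np.testing.assert_allclose(surf.exceedance[1 - 1e-9].values, 0.0)
        assert np.all(surf.exceedance[0.2].values >= surf.exceedance[0.5].values)

    def test_exceedance_threshold_validated(self):
        fit, grid = surface_inputs()
        with pytest.raises(ValueError):
            exceedance_surface(fit, grid, {}, threshold=1.5)

    def test_missing_covariate_raster_is_configuration_error(self):
        fit, grid = surface_inputs()
        fit.covariate_names = ["aridity"]
        fit.beta = np.zeros((fit.n_samples, 1))
        with pytest.raises(ValueError):
            prevalence_surface(fit, grid, {}, thresholds=(0.25,))

    def test_surface_io_roundtrip(self, tmp_path):
        fit, grid = surface_inputs()
        surf = prevalence_surface(fit, grid, {}, thresholds=(0.25,), seed=4)
        written = surf.write(tmp_path, prefix="prev")
        assert any(p.endswith("prev_mean.asc") for p in written)
        back = RasterGrid.read_ascii(tmp_path / "prev_mean.asc")
        np.testing.assert_allclose(back.values, surf.mean_prev.values, atol=1e-6)
        df = pd.read_csv(tmp_path / "prev_surface.csv")
        assert {"x", "y", "mean", "sd", "ci_width"} <= set(df.columns)


class TestObservedVsPredicted:
    def _table(self, n, y):
        return pd.DataFrame({"cluster_id": range(len(n)), "n": n, "y_stunted": y})

    def test_perfect_fit_gives_unit_correlation(self):
        n = np.array([10, 20, 10, 40, 25])
        y = np.array([2, 10, 7, 12, 5])
        prev = np.tile(y / n, (30, 1))
        fit = degenerate_spatial_fit(np.random.default_rng(0).uniform(0, 1, (5, 2)),
                                     np.zeros((30, 5)), 0.1, 1.0)
        fit.prevalence = prev
        df, r, p, excl = observed_vs_predicted(fit, self._table(n, y))
        assert r == pytest.approx(1.0, abs=1e-12)
        assert excl == 0

    def test_constant_observed_flagged_not_crashed(self):
        n = np.array([10, 10, 10, 10])
        y = np.array([5, 5, 5, 5])
        fit = degenerate_spatial_fit(np.random.default_rng(1).uniform(0, 1, (4, 2)),
                                     np.random.default_rng(2).normal(0, 1, (20, 4)),
                                     0.3, 1.0)
        df, r, p, excl = observed_vs_predicted(fit, self._table(n, y))
        assert np.isnan(r) and np.isnan(p)

    def test_zero_n_clusters_excluded_and_counted(self):
        n = np.array([10, 0, 10, 0, 15])
        y = np.array([3, 0, 7, 0, 6])
        fit = degenerate_spatial_fit(np.random.default_rng(3).uniform(0, 1, (5, 2)),
                                     np.random.default_rng(4).normal(0, 1, (40, 5)),
                                     0.3, 1.0)
        df, r, p, excl = observed_vs_predicted(fit, self._table(n, y))
        assert excl == 2
        assert np.isnan(df.loc[1, "observed"])

    def test_positive_correlation_on_spatial_simulation(self, recovery_fit):
        table, _, fit, _ = recovery_fit
        df, r, p, _ = observed_vs_predicted(fit, table)
        assert r > 0
        assert p < 1e-3
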