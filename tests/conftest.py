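import pytest

import geoprev as gp


@pytest.fixture(scope="session")
def recovery_fit():
    """One seeded 400-cluster survey with a moderate latent field, fitted with
    the spatial model; shared by prediction and validation tests."""
    cfg = gp.SyntheticConfig(
        seed=7, domain_extent=(0, 0, 8, 8), n_clusters=400,
        matern=gp.MaternParams(0.3, 1.355, 1.0),
        true_alpha=-0.3, true_beta=(0.32,), grid_cellsize=0.4)
    table, truth = gp.generate_survey(cfg, displace=False)
    spec = gp.ModelSpec(covariates=["cov_1"], spatial=True, n_burn=400, n_samples=400)
    fit = gp.fit_spatial(table, spec, random_state=2)
    return table, truth, fit, cfg
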