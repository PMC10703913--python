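"""Shared independent oracles and toy-object builders for the test suite."""

import numpy as np
import pandas as pd

import geoprev as gp


def bessel_k_quadrature(nu: float, x: float) -> float:
    """Independent modified-Bessel-K oracle via the integral representation
    K_nu(x) = int_0^inf exp(-x cosh t) cosh(nu t) dt (adaptive quadrature)."""
    from scipy.integrate import quad

    val, _ = quad(lambda t: np.exp(-x * np.cosh(t)) * np.cosh(nu * t),
                  0.0, 30.0, limit=400, epsabs=1e-13, epsrel=1e-13)
    return val


def matern_oracle(u: float, kappa: float, nu: float) -> float:
    """Matérn correlation from the quadrature Bessel oracle."""
    from scipy.special import gamma

    if u == 0:
        return 1.0
    x = kappa * u
    return x ** nu * bessel_k_quadrature(nu, x) / (2 ** (nu - 1) * gamma(nu))


def naive_waic(loglik: np.ndarray) -> float:
    """Brute-force WAIC with explicit python loops over clusters and draws."""
    S, D = loglik.shape
    lppd = 0.0
    p_waic = 0.0
    for d in range(D):
        col = [loglik[s, d] for s in range(S)]
        lppd += np.log(sum(np.exp(v) for v in col) / S)
        mean = sum(col) / S
        p_waic += sum((v - mean) ** 2 for v in col) / S
    return -2.0 * (lppd - p_waic)


def toy_cluster_table(n=20, seed=0):
    rng = np.random.default_rng(seed)
    tbl = pd.DataFrame({
        "cluster_id": [f"c{i}" for i in range(n)],
        "x": rng.uniform(0, 10, n),
        "y": rng.uniform(0, 10, n),
        "urban": rng.uniform(size=n) < 0.3,
        "n": rng.integers(5, 20, n),
        "weight": rng.uniform(0.5, 2.0, n),
    })
    tbl["y_stunted"] = rng.binomial(tbl["n"], 0.3)
    return tbl


def degenerate_spatial_fit(coords, latent_draws, sigma2, kappa, nu=1.0,
                           alpha=0.0, beta=None):
    """Hand-built PosteriorFit with fully controlled draws, for oracle tests."""
    latent_draws = np.atleast_2d(np.asarray(latent_draws, float))
    S, D = latent_draws.shape
    beta = np.zeros((S, 0)) if beta is None else np.asarray(beta, float)
    prev = 1.0 / (1.0 + np.exp(-(alpha + latent_draws)))
    return gp.PosteriorFit(
        model="spatial", covariate_names=[], alpha=np.full(S, float(alpha)),
        beta=beta, prevalence=prev, loglik=np.zeros((S, D)), waic=0.0,
        diagnostics=pd.DataFrame({"parameter": [], "rhat": [], "ess_bulk": []}),
        converged=True, fingerprint="toy", nu=nu,
        sigma2=np.full(S, float(sigma2)), kappa=np.full(S, float(kappa)),
        latent=latent_draws, coords=np.asarray(coords, float), jitter=1e-8)
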