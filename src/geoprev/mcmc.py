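"""MCMC building blocks for the latent-Gaussian binomial models.

The samplers work in a *whitened* parameterization: every Gaussian unknown
(intercept, regression coefficients, latent spatial field) is represented by
standard-normal coordinates z, mapped linearly to the model scale.  This makes
elliptical slice sampling (ESS) applicable to the whole Gaussian block with no
tuning, and makes the hyperparameter updates (which change the map, not z)
well behaved even when the field is strongly informed by the data.
"""

from __future__ import annotations

import numpy as np


def binom_loglik(eta: np.ndarray, y: np.ndarray, n: np.ndarray) -> float:
    """Binomial log likelihood (up to the binomial coefficient) at logits eta."""
    return float(np.sum(y * eta - n * np.logaddexp(0.0, eta)))


def binom_loglik_pointwise(eta: np.ndarray, y: np.ndarray, n: np.ndarray, log_binom_coef: np.ndarray) -> np.ndarray:
    """Full per-cluster binomial log pmf at logits eta."""
    return log_binom_coef + y * eta - n * np.logaddexp(0.0, eta)


def ess_update(z: np.ndarray, loglik, cur_ll: float, rng: np.random.Generator,
               max_shrink: int = 100):
    """One elliptical slice sampling update of z ~ N(0, I) with likelihood
    ``loglik(z)``.  Returns (z_new, ll_new).  Murray, Adams & MacKay (2010)."""
    nu = rng.standard_normal(z.shape)
    log_u = cur_ll + np.log(rng.uniform())
    theta = rng.uniform(0.0, 2.0 * np.pi)
    lo, hi = theta - 2.0 * np.pi, theta
    for _ in range(max_shrink):
        z_prop = z * np.cos(theta) + nu * np.sin(theta)
        ll_prop = loglik(z_prop)
        if ll_prop > log_u:
            return z_prop, ll_prop
        if theta < 0:
            lo = theta
        else:
            hi = theta
        theta = rng.uniform(lo, hi)
    # bracket collapsed to numerical zero: keep current state
    return z, cur_ll


class AdaptiveScale:
    """Robbins–Monro adaptation of a scalar proposal scale toward a target
    acceptance rate.  Adaptation is active only while ``adapting`` is True."""

    def __init__(self, scale: float = 0.1, target: float = 0.3, rate: float = 0.66):
        self.scale = scale
        self.target = target
        self.rate = rate
        self.count = 0
        self.accepted = 0
        self.adapting = True

    def update(self, accepted: bool) -> None:
        self.count += 1
        self.accepted += int(accepted)
        if self.adapting:
            step = self.count ** (-self.rate)
            self.scale *= np.exp(step * ((1.0 if accepted else 0.0) - self.target))

    @property
    def acceptance_rate(self) -> float:
        return self.accepted / max(self.count, 1)


class AdaptiveMVN:
    """Adaptive multivariate random-walk proposal: running empirical covariance
    (Haario-style) times an adapted scalar scale."""

    def __init__(self, dim: int, target: float = 0.234):
        self.dim = dim
        self.scale = AdaptiveScale(scale=2.38 / np.sqrt(dim), target=target)
        self.mean = np.zeros(dim)
        self.m2 = np.eye(dim) * 1e-6
        self.count = 0
        self._chol = np.eye(dim)
        self._chol_stale = False

    def observe(self, x: np.ndarray) -> None:
        self.count += 1
        delta = x - self.mean
        self.mean += delta / self.count
        self.m2 += np.outer(delta, x - self.mean)
        self._chol_stale = True

    def propose(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self._chol_stale and self.count > 2 * self.dim and self.scale.adapting:
            cov = self.m2 / (self.count - 1) + 1e-9 * np.eye(self.dim)
            try:
                self._chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                pass
            self._chol_stale = False
        return x + self.scale.scale * (self._chol @ rng.standard_normal(self.dim))

    def update(self, accepted: bool) -> None:
        self.scale.update(accepted)

    def freeze(self) -> None:
        self.scale.adapting = False


def split_chain_diagnostics(samples: dict[str, np.ndarray]) -> "pandas.DataFrame":
    """Split-chain R-hat and bulk ESS per scalar parameter via arviz.

    Each entry of ``samples`` is a 1-D array of post-burn-in draws from a
    single chain; it is split into two halves to form pseudo-chains.
    """
    import arviz as az
    import pandas as pd

    rows = []
    for name, draws in samples.items():
        draws = np.asarray(draws, dtype=float)
        half = len(draws) // 2
        if half < 4 or np.allclose(draws, draws[0]):
            rows.append({"parameter": name, "rhat": np.nan, "ess_bulk": np.nan})
            continue
        arr = np.stack([draws[:half], draws[half:2 * half]])
        rows.append({
            "parameter": name,
            "rhat": float(az.rhat(arr)),
            "ess_bulk": float(az.ess(arr)),
        })
    return pd.DataFrame(rows)
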