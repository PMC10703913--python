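"""Bayesian binomial prevalence models, non-spatial and geostatistical.

Model
-----
For cluster d with ``n_d`` sampled children of which ``y_d`` are stunted,

    y_d | P(x_d) ~ Binomial(n_d, P(x_d))
    logit(P(x_d)) = alpha + d(x_d)' beta + S(x_d)

where ``d(x_d)`` are covariates at the cluster location and ``S`` is a
zero-mean Matérn Gaussian process (omitted in the non-spatial model).
Priors: a vague Gaussian on the intercept, N(0, precision 0.001) on each
coefficient, Gamma(1, 0.00005) on the GP precision tau = 1/sigma2, and a
log-uniform prior on the Matérn scale kappa; the smoothness nu is fixed.

Inference is by MCMC on the exact (dense-covariance) likelihood: elliptical
slice sampling over the whitened Gaussian block (intercept, coefficients,
latent field), an adaptive Metropolis block on the fixed effects, and
adaptive random-walk Metropolis on (log sigma2, log kappa) with the whitened
field held fixed.  Model comparison uses WAIC.

The estimators follow scikit-learn conventions (``get_params``/``set_params``,
fitted attributes with trailing underscores) so they compose with sklearn
tooling; ``fit_nonspatial``/``fit_spatial`` are thin functional wrappers.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.special import expit, gammaln, logsumexp
from sklearn.base import BaseEstimator
from sklearn.utils import check_array, check_random_state

from .matern import MaternTable, chol_with_jitter
from .mcmc import (
    AdaptiveMVN,
    AdaptiveScale,
    binom_loglik,
    binom_loglik_pointwise,
    ess_update,
    split_chain_diagnostics,
)

__all__ = [
    "PriorSpec",
    "ModelSpec",
    "PosteriorFit",
    "NonSpatialBinomialModel",
    "SpatialBinomialModel",
    "compute_waic",
    "fit_nonspatial",
    "fit_spatial",
]


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyperparameters (defaults as used throughout the package)."""

    alpha_sd: float = 100.0            # vague Gaussian on the intercept
    beta_precision: float = 0.001      # N(0, precision 0.001) on coefficients
    tau_shape: float = 1.0             # Gamma(shape, rate) on tau = 1/sigma2
    tau_rate: float = 0.00005
    log_kappa_bounds: tuple[float, float] | None = None  # None: derived from extent


@dataclass
class ModelSpec:
    """Declarative description of one model run (used by the pipeline)."""

    covariates: list[str] = field(default_factory=list)
    spatial: bool = False
    nu: float = 1.0
    priors: PriorSpec = field(default_factory=PriorSpec)
    n_burn: int = 500
    n_samples: int = 1000
    thin: int = 1
    strict_convergence: bool = False


def compute_waic(pointwise_loglik: np.ndarray) -> float:
    """Watanabe–Akaike information criterion from an (S samples x D clusters)
    pointwise log-likelihood matrix.

    WAIC = -2 (lppd - p_waic) with
    lppd  = sum_d log mean_s exp(ll[s, d])   (log-sum-exp stabilized)
    p_waic = sum_d var_s(ll[s, d])           (population variance over draws)
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2 or ll.shape[1] < 1:
        raise ValueError("need a 2-D matrix with >= 2 samples and >= 1 cluster")
    if not np.all(np.isfinite(ll)):
        raise ValueError("pointwise log-likelihood contains non-finite entries")
    S = ll.shape[0]
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(S)))
    p_waic = float(np.sum(np.var(ll, axis=0)))
    return -2.0 * (lppd - p_waic)


@dataclass
class PosteriorFit:
    """Posterior draws and derived quantities from one fitted model."""

    model: str                       # "nonspatial" | "spatial"
    covariate_names: list[str]
    alpha: np.ndarray                # (S,)
    beta: np.ndarray                 # (S, p), original covariate scale
    prevalence: np.ndarray           # (S, D) fitted P(x_d) per draw
    loglik: np.ndarray               # (S, D) pointwise log likelihood
    waic: float
    diagnostics: pd.DataFrame
    converged: bool
    fingerprint: str
    nu: float | None = None
    sigma2: np.ndarray | None = None  # (S,)
    kappa: np.ndarray | None = None   # (S,)
    latent: np.ndarray | None = None  # (S, D) draws of S at cluster sites
    coords: np.ndarray | None = None  # (D, 2)
    jitter: float = 1e-8

    @property
    def n_samples(self) -> int:
        return self.alpha.shape[0]

    @property
    def spatial(self) -> bool:
        return self.model == "spatial"

    def summary(self) -> pd.DataFrame:
        """Posterior mean and equal-tailed 95% credible interval per parameter,
        plus spatial hyperparameters and a WAIC row."""
        rows = []

        def _row(name, draws):
            lo, hi = np.percentile(draws, [2.5, 97.5])
            rows.append({"parameter": name, "mean": float(np.mean(draws)),
                         "sd": float(np.std(draws)), "q2.5": float(lo), "q97.5": float(hi)})

        _row("intercept", self.alpha)
        for j, name in enumerate(self.covariate_names):
            _row(name, self.beta[:, j])
        if self.spatial:
            _row("sigma2", self.sigma2)
            _row("kappa", self.kappa)
            _row("practical_range", np.sqrt(8.0 * self.nu) / self.kappa)
        rows.append({"parameter": "WAIC", "mean": self.waic,
                     "sd": np.nan, "q2.5": np.nan, "q97.5": np.nan})
        return pd.DataFrame(rows)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        draws = {"alpha": self.alpha}
        for j, name in enumerate(self.covariate_names):
            draws[f"beta_{name}"] = self.beta[:, j]
        if self.spatial:
            draws["sigma2"] = self.sigma2
            draws["kappa"] = self.kappa
        pd.DataFrame(draws).to_csv(outdir / f"{self.model}_draws.csv", index=False)
        self.diagnostics.to_csv(outdir / f"{self.model}_diagnostics.csv", index=False)
        self.summary().to_csv(outdir / f"{self.model}_summary.csv", index=False)


def _data_fingerprint(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        if a is not None:
            h.update(np.ascontiguousarray(np.asarray(a, dtype=float)).tobytes())
    return h.hexdigest()[:16]


def _validate_counts(y, trials):
    y = np.asarray(y, dtype=float).ravel()
    if trials is None:
        raise ValueError("binomial trial counts are required (trials=...)")
    n = np.asarray(trials, dtype=float).ravel()
    if y.shape != n.shape:
        raise ValueError("y and trials must have the same length")
    if np.any(y < 0) or np.any(n < 0) or np.any(y > n):
        raise ValueError("need 0 <= y <= trials elementwise")
    return y, n


class _BinomialMCMCBase(BaseEstimator):
    """Shared machinery for the binomial MCMC estimators."""

    def _check_convergence(self, diag: pd.DataFrame, strict: bool) -> bool:
        ok = True
        sub = diag.dropna()
        if len(sub):
            ok = bool((sub["rhat"] < self.rhat_threshold).all()
                      and (sub["ess_bulk"] > self.ess_threshold).all())
        if strict and not ok:
            raise RuntimeError(
                "MCMC convergence diagnostics failed:\n" + diag.to_string(index=False))
        return ok

    def predict(self, X, coords=None):
        """Posterior-mean prevalence at new covariate values (and, for the
        spatial model, new locations)."""
        raise NotImplementedError


class NonSpatialBinomialModel(_BinomialMCMCBase):
    """Bayesian binomial logistic regression without a spatial term.

    Parameters
    ----------
    alpha_prior_sd : float
        SD of the vague Gaussian prior on the intercept (logit scale).
    beta_prior_precision : float
        Precision of the N(0, .) prior on each regression coefficient.
    n_burn, n_samples, thin : int
        Burn-in iterations, retained draws, and thinning interval.
    n_ess_sweeps : int
        Elliptical-slice sweeps per iteration.
    random_state : int, Generator or None
        Seed for the sampler.
    """

    def __init__(self, *, alpha_prior_sd=100.0, beta_prior_precision=0.001,
                 n_burn=500, n_samples=1000, thin=1, n_ess_sweeps=2,
                 rhat_threshold=1.05, ess_threshold=100.0,
                 strict_convergence=False, random_state=None):
        self.alpha_prior_sd = alpha_prior_sd
        self.beta_prior_precision = beta_prior_precision
        self.n_burn = n_burn
        self.n_samples = n_samples
        self.thin = thin
        self.n_ess_sweeps = n_ess_sweeps
        self.rhat_threshold = rhat_threshold
        self.ess_threshold = ess_threshold
        self.strict_convergence = strict_convergence
        self.random_state = random_state

    def fit(self, X, y, trials=None, covariate_names=None):
        X = check_array(np.asarray(X, dtype=float), ensure_min_features=0,
                        ensure_all_finite=True) if np.size(X) else np.empty((len(y), 0))
        y, n = _validate_counts(y, trials)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y must have the same number of rows")
        if y.shape[0] < 2:
            raise ValueError("need at least 2 clusters")
        rng = np.random.default_rng(check_random_state(self.random_state).randint(2**31))
        p = X.shape[1]
        names = list(covariate_names) if covariate_names is not None else [f"x{j}" for j in range(p)]

        xmean = X.mean(axis=0) if p else np.zeros(0)
        Xc = X - xmean
        a_sd = float(self.alpha_prior_sd)
        b_sd = float(np.sqrt(1.0 / self.beta_prior_precision))
        log_bc = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)

        def eta_of(z):
            return a_sd * z[0] + (Xc @ (b_sd * z[1:]) if p else 0.0)

        def ll_of(z):
            return binom_loglik(eta_of(z), y, n)

        pooled = (y.sum() + 0.5) / (n.sum() + 1.0)
        z = np.zeros(1 + p)
        z[0] = np.log(pooled / (1 - pooled)) / a_sd
        cur_ll = ll_of(z)
        mh = AdaptiveMVN(1 + p)

        S = self.n_samples
        keep_alpha = np.empty(S)
        keep_beta = np.empty((S, p))
        keep_prev = np.empty((S, len(y)))
        keep_ll = np.empty((S, len(y)))
        total = self.n_burn + S * self.thin
        k = 0
        for it in range(total):
            for _ in range(self.n_ess_sweeps):
                z, cur_ll = ess_update(z, ll_of, cur_ll, rng)
            # adaptive MH block
            z_prop = mh.propose(z, rng)
            ll_prop = ll_of(z_prop)
            log_acc = (ll_prop - cur_ll) - 0.5 * (z_prop @ z_prop - z @ z)
            acc = np.log(rng.uniform()) < log_acc
            if acc:
                z, cur_ll = z_prop, ll_prop
            mh.update(acc)
            mh.observe(z)
            if it == self.n_burn - 1:
                mh.freeze()
            if it >= self.n_burn and (it - self.n_burn) % self.thin == 0 and k < S:
                eta = eta_of(z)
                beta = b_sd * z[1:]
                keep_alpha[k] = a_sd * z[0] - (xmean @ beta if p else 0.0)
                keep_beta[k] = beta
                keep_prev[k] = expit(eta)
                keep_ll[k] = binom_loglik_pointwise(eta, y, n, log_bc)
                k += 1

        diag = split_chain_diagnostics(
            {"intercept": keep_alpha, **{names[j]: keep_beta[:, j] for j in range(p)}})
        converged = self._check_convergence(diag, self.strict_convergence)
        self.posterior_ = PosteriorFit(
            model="nonspatial", covariate_names=names, alpha=keep_alpha,
            beta=keep_beta, prevalence=keep_prev, loglik=keep_ll,
            waic=compute_waic(keep_ll), diagnostics=diag, converged=converged,
            fingerprint=_data_fingerprint(X, y, n))
        self.alpha_samples_ = keep_alpha
        self.beta_samples_ = keep_beta
        self.waic_ = self.posterior_.waic
        self.converged_ = converged
        self.n_features_in_ = p
        return self

    def predict(self, X, coords=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, self.n_features_in_)
        eta = self.alpha_samples_[:, None] + self.beta_samples_ @ X.T
        return expit(eta).mean(axis=0)


class SpatialBinomialModel(_BinomialMCMCBase):
    """Bayesian binomial geostatistical model with a Matérn Gaussian process.

    Adds to :class:`NonSpatialBinomialModel` a latent field S at the cluster
    locations with Matérn covariance (variance ``sigma2``, scale ``kappa``,
    smoothness ``nu`` fixed), a Gamma(tau_prior_shape, tau_prior_rate) prior
    on the precision 1/sigma2, and a log-uniform prior on kappa over
    ``log_kappa_bounds`` (derived from the data extent when None: practical
    range between 1/100 and 2x the coordinate-bounding-box diagonal).
    """

    def __init__(self, *, nu=1.0, alpha_prior_sd=100.0, beta_prior_precision=0.001,
                 tau_prior_shape=1.0, tau_prior_rate=0.00005, log_kappa_bounds=None,
                 init_sigma2=None, jitter=1e-8, n_burn=500, n_samples=1000, thin=1,
                 n_ess_sweeps=2, rhat_threshold=1.05, ess_threshold=100.0,
                 strict_convergence=False, random_state=None):
        self.nu = nu
        self.alpha_prior_sd = alpha_prior_sd
        self.beta_prior_precision = beta_prior_precision
        self.tau_prior_shape = tau_prior_shape
        self.tau_prior_rate = tau_prior_rate
        self.log_kappa_bounds = log_kappa_bounds
        self.init_sigma2 = init_sigma2
        self.jitter = jitter
        self.n_burn = n_burn
        self.n_samples = n_samples
        self.thin = thin
        self.n_ess_sweeps = n_ess_sweeps
        self.rhat_threshold = rhat_threshold
        self.ess_threshold = ess_threshold
        self.strict_convergence = strict_convergence
        self.random_state = random_state

    def fit(self, X, y, trials=None, coords=None, covariate_names=None):
        if coords is None:
            raise ValueError("the spatial model requires cluster coordinates (coords=...)")
        coords = check_array(np.asarray(coords, dtype=float))
        if coords.shape[1] != 2:
            raise ValueError("coords must be (n, 2)")
        X = check_array(np.asarray(X, dtype=float), ensure_min_features=0) \
            if np.size(X) else np.empty((len(y), 0))
        y, n = _validate_counts(y, trials)
        D = len(y)
        if X.shape[0] != D or coords.shape[0] != D:
            raise ValueError("X, y and coords must agree in length")
        rng = np.random.default_rng(check_random_state(self.random_state).randint(2**31))
        p = X.shape[1]
        names = list(covariate_names) if covariate_names is not None else [f"x{j}" for j in range(p)]

        xmean = X.mean(axis=0) if p else np.zeros(0)
        Xc = X - xmean
        a_sd = float(self.alpha_prior_sd)
        b_sd = float(np.sqrt(1.0 / self.beta_prior_precision))
        log_bc = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
        from scipy.spatial.distance import pdist, squareform

        dist_flat = pdist(coords)
        corr_table = MaternTable(self.nu)
        span = coords.max(axis=0) - coords.min(axis=0)
        diag_len = float(np.hypot(*span)) or 1.0
        if self.log_kappa_bounds is not None:
            lk_lo, lk_hi = map(float, self.log_kappa_bounds)
        else:
            # practical range restricted to [diag/20, 2*diag]: below ~1/20 of
            # the study extent a Matérn field is indistinguishable from
            # cluster-level noise and starts chasing binomial variability
            lk_lo = np.log(np.sqrt(8 * self.nu) / (2.0 * diag_len))
            lk_hi = np.log(np.sqrt(8 * self.nu) / (diag_len / 20.0))

        q = 1 + p  # fixed-effect block

        def chol_for(kappa):
            R = squareform(corr_table.corr_at(kappa * dist_flat))
            np.fill_diagonal(R, 1.0)
            return chol_with_jitter(R, self.jitter)

        log_kappa = np.clip(np.log(np.sqrt(8 * self.nu) / (diag_len / 4.0)), lk_lo, lk_hi)
        L_R, jit = chol_for(np.exp(log_kappa))

        # Initialize the fixed effects at a quick ridge-penalized IRLS
        # estimate and the field at kriging-smoothed residuals with a
        # method-of-moments variance.  Starting from sigma2 ~ 0 with an
        # uninformed field is a known trap of the non-centered
        # parameterization (the "funnel"): the chain cannot grow the field
        # because the likelihood is flat in it at small sigma2.  Starting the
        # field from pre-regression residuals is a slower trap: it hands the
        # covariate signal to the field.
        z = np.zeros(q + D)
        design = np.column_stack([np.ones(D), Xc])
        theta = np.zeros(q)
        pooled = (y.sum() + 0.5) / (n.sum() + 1.0)
        theta[0] = np.log(pooled / (1 - pooled))
        for _ in range(8):  # Newton steps, ridge-stabilized
            mu = expit(design @ theta)
            w_irls = np.maximum(n * mu * (1 - mu), 1e-8)
            grad = design.T @ (y - n * mu) - 1e-4 * theta
            hess = (design * w_irls[:, None]).T @ design + 1e-4 * np.eye(q)
            theta += np.linalg.solve(hess, grad)
        z[0] = theta[0] / a_sd
        z[1:q] = theta[1:] / b_sd
        p_hat = (y + 0.5) / (n + 1.0)
        resid = np.log(p_hat / (1 - p_hat)) - design @ theta
        samp_var = 1.0 / np.maximum((n + 1.0) * p_hat * (1 - p_hat), 1e-6)
        if self.init_sigma2 is not None:
            s2_init = float(self.init_sigma2)
        else:
            s2_init = float(np.clip(np.var(resid) - samp_var.mean(), 0.01, 10.0))
        log_s2 = np.log(s2_init)
        # kriging smoother of the residuals under a Gaussian noise
        # approximation: smooth w.r.t. the initial correlation, so the first
        # centered variance update sees a field of plausible roughness
        R_full = L_R @ L_R.T
        A = s2_init * R_full + np.diag(samp_var)
        s_init = s2_init * (R_full @ np.linalg.solve(A, resid))
        z[q:] = solve_triangular(L_R, s_init, lower=True) / np.sqrt(s2_init)

        def eta_of(z, log_s2=None, L=None):
            ls2 = log_s2 if log_s2 is not None else state["log_s2"]
            LL = L if L is not None else state["L_R"]
            fix = a_sd * z[0] + (Xc @ (b_sd * z[1:q]) if p else 0.0)
            return fix + np.exp(0.5 * ls2) * (LL @ z[q:])

        state = {"log_s2": log_s2, "L_R": L_R}

        def ll_of(z):
            return binom_loglik(eta_of(z), y, n)

        def fix_of(z):
            return a_sd * z[0] + (Xc @ (b_sd * z[1:q]) if p else 0.0)

        cur_ll = ll_of(z)
        mh_fix = AdaptiveMVN(q)
        sc_s2 = AdaptiveScale(scale=0.5, target=0.44)
        sc_kap = AdaptiveScale(scale=0.5, target=0.44)
        sc_kap2 = AdaptiveScale(scale=0.5, target=0.44)
        sc_dir = [AdaptiveScale(scale=0.2, target=0.44) for _ in range(q)]
        dir_cols = [np.ones(D)] + [Xc[:, j] for j in range(p)]
        prior_sds = np.array([a_sd] + [b_sd] * p)
        a_tau, b_tau = float(self.tau_prior_shape), float(self.tau_prior_rate)

        def log_prior_s2(t):  # Gamma(a, b) on tau = exp(-t), incl. Jacobian
            return -a_tau * t - b_tau * np.exp(-t)

        S = self.n_samples
        keep = {k: np.empty(S) for k in ("alpha", "sigma2", "kappa")}
        keep_beta = np.empty((S, p))
        keep_prev = np.empty((S, D))
        keep_ll = np.empty((S, D))
        keep_S = np.empty((S, D))
        total = self.n_burn + S * self.thin
        k = 0
        fix_cache = fix_of(z)
        for it in range(total):
            # field update: elliptical slice over the whitened field only
            # (fixed effects have their own moves; including them here would
            # throttle the slice angle through their wide priors)
            sigma_now = np.exp(0.5 * state["log_s2"])

            def ll_field(v):
                return binom_loglik(fix_cache + sigma_now * (state["L_R"] @ v), y, n)

            v_cur = z[q:]
            for _ in range(self.n_ess_sweeps):
                v_cur, cur_ll = ess_update(v_cur, ll_field, cur_ll, rng)
            z[q:] = v_cur

            # fixed-effect MH block
            z_prop = z.copy()
            z_prop[:q] = mh_fix.propose(z[:q], rng)
            ll_prop = ll_of(z_prop)
            log_acc = (ll_prop - cur_ll) - 0.5 * (z_prop[:q] @ z_prop[:q] - z[:q] @ z[:q])
            acc = np.log(rng.uniform()) < log_acc
            if acc:
                z, cur_ll = z_prop, ll_prop
                fix_cache = fix_of(z)
            mh_fix.update(acc)
            mh_fix.observe(z[:q])

            # Confounded-direction moves: each fixed effect is only weakly
            # identified from the field (the intercept trades off against the
            # field mean, a coefficient against the field's projection on its
            # covariate).  Shift the fixed effect by delta and subtract the
            # exact compensating field component, leaving the likelihood
            # unchanged; acceptance depends on the Gaussian priors alone.
            sigma_now = np.exp(0.5 * state["log_s2"])
            for jdir in range(q):
                w_dir = solve_triangular(state["L_R"], dir_cols[jdir], lower=True)
                delta = sc_dir[jdir].scale * rng.standard_normal()
                z_prop = z.copy()
                z_prop[jdir] += delta / prior_sds[jdir]
                z_prop[q:] -= (delta / sigma_now) * w_dir
                acc = np.log(rng.uniform()) < -0.5 * (z_prop @ z_prop - z @ z)
                if acc:
                    z = z_prop
                    fix_cache = fix_of(z)
                sc_dir[jdir].update(acc)

            # log sigma2, non-centered: no new Cholesky needed
            t_prop = state["log_s2"] + sc_s2.scale * rng.standard_normal()
            ll_prop = binom_loglik(eta_of(z, log_s2=t_prop), y, n)
            log_acc = (ll_prop + log_prior_s2(t_prop)) - (cur_ll + log_prior_s2(state["log_s2"]))
            acc = np.log(rng.uniform()) < log_acc
            if acc:
                state["log_s2"], cur_ll = t_prop, ll_prop
            sc_s2.update(acc)

            # sigma2, centered (interweaving): with S = sigma*L*v held fixed the
            # GP precision is conjugate, tau | S ~ Gamma(a + n/2, b + S'K^-1 S / 2)
            # with S'K^-1 S = sigma2 * v'v; then rewhiten v.  Breaks the funnel
            # between sigma2 and the field that traps the non-centered chain.
            vv = z[q:] @ z[q:]
            s2_old = np.exp(state["log_s2"])
            tau_new = rng.gamma(a_tau + 0.5 * D, 1.0 / (b_tau + 0.5 * s2_old * vv))
            s2_new = 1.0 / tau_new
            z[q:] *= np.sqrt(s2_old / s2_new)
            state["log_s2"] = np.log(s2_new)  # eta, cur_ll unchanged

            # log kappa, non-centered (field shape fixed in whitened space):
            # likelihood-only acceptance, needs one new Cholesky
            k_prop = log_kappa + sc_kap.scale * rng.standard_normal()
            if lk_lo <= k_prop <= lk_hi:
                L_prop, _ = chol_for(np.exp(k_prop))
                ll_prop = binom_loglik(eta_of(z, L=L_prop), y, n)
                acc = np.log(rng.uniform()) < (ll_prop - cur_ll)
                if acc:
                    log_kappa, cur_ll = k_prop, ll_prop
                    state["L_R"] = L_prop
            else:
                acc = False
            sc_kap.update(acc)

            # log kappa, centered (field values S fixed): acceptance from the
            # GP prior density ratio only; complements the non-centered move
            k_prop = log_kappa + sc_kap2.scale * rng.standard_normal()
            if lk_lo <= k_prop <= lk_hi:
                L_prop, _ = chol_for(np.exp(k_prop))
                v_new = solve_triangular(L_prop, state["L_R"] @ z[q:], lower=True)
                log_acc = (-0.5 * (v_new @ v_new - z[q:] @ z[q:])
                           - np.sum(np.log(np.diag(L_prop)))
                           + np.sum(np.log(np.diag(state["L_R"]))))
                acc = np.log(rng.uniform()) < log_acc
                if acc:
                    log_kappa = k_prop
                    state["L_R"] = L_prop
                    z[q:] = v_new  # eta, cur_ll unchanged
            else:
                acc = False
            sc_kap2.update(acc)

            if it == self.n_burn - 1:
                mh_fix.freeze()
                sc_s2.adapting = sc_kap.adapting = sc_kap2.adapting = False
                for sc in sc_dir:
                    sc.adapting = False
            if it >= self.n_burn and (it - self.n_burn) % self.thin == 0 and k < S:
                sigma = np.exp(0.5 * state["log_s2"])
                S_field = sigma * (state["L_R"] @ z[q:])
                beta = b_sd * z[1:q]
                eta = eta_of(z)
                keep["alpha"][k] = a_sd * z[0] - (xmean @ beta if p else 0.0)
                keep_beta[k] = beta
                keep["sigma2"][k] = sigma ** 2
                keep["kappa"][k] = np.exp(log_kappa)
                keep_S[k] = S_field
                keep_prev[k] = expit(eta)
                keep_ll[k] = binom_loglik_pointwise(eta, y, n, log_bc)
                k += 1

        diag = split_chain_diagnostics({
            "intercept": keep["alpha"],
            **{names[j]: keep_beta[:, j] for j in range(p)},
            "sigma2": keep["sigma2"], "kappa": keep["kappa"]})
        converged = self._check_convergence(diag, self.strict_convergence)
        self.posterior_ = PosteriorFit(
            model="spatial", covariate_names=names, alpha=keep["alpha"],
            beta=keep_beta, prevalence=keep_prev, loglik=keep_ll,
            waic=compute_waic(keep_ll), diagnostics=diag, converged=converged,
            fingerprint=_data_fingerprint(X, y, n, coords), nu=self.nu,
            sigma2=keep["sigma2"], kappa=keep["kappa"], latent=keep_S,
            coords=coords, jitter=jit)
        self.alpha_samples_ = keep["alpha"]
        self.beta_samples_ = keep_beta
        self.sigma2_samples_ = keep["sigma2"]
        self.kappa_samples_ = keep["kappa"]
        self.latent_samples_ = keep_S
        self.waic_ = self.posterior_.waic
        self.converged_ = converged
        self.n_features_in_ = p
        return self

    def predict(self, X, coords=None, random_state=0):
        """Posterior-mean prevalence at new locations by conditional kriging
        of the latent field under each posterior draw."""
        from .predict import predict_latent_field

        if coords is None:
            raise ValueError("coords required for spatial prediction")
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            X = np.empty((len(coords), 0))
        S_new = predict_latent_field(self.posterior_, coords, seed=random_state)
        eta = self.alpha_samples_[:, None] + self.beta_samples_ @ X.T + S_new
        return expit(eta).mean(axis=0)


def _design_from_table(table: pd.DataFrame, spec: ModelSpec):
    from .survey import validate_cluster_table

    validate_cluster_table(table, spec.covariates)
    X = table[spec.covariates].to_numpy(dtype=float) if spec.covariates else np.empty((len(table), 0))
    y = table["y_stunted"].to_numpy(dtype=float)
    n = table["n"].to_numpy(dtype=float)
    coords = table[["x", "y"]].to_numpy(dtype=float)
    return X, y, n, coords


def fit_nonspatial(table: pd.DataFrame, spec: ModelSpec, random_state=None) -> PosteriorFit:
    """Fit the non-spatial model to a cluster table; returns the posterior."""
    X, y, n, _ = _design_from_table(table, spec)
    est = NonSpatialBinomialModel(
        alpha_prior_sd=spec.priors.alpha_sd,
        beta_prior_precision=spec.priors.beta_precision,
        n_burn=spec.n_burn, n_samples=spec.n_samples, thin=spec.thin,
        strict_convergence=spec.strict_convergence, random_state=random_state)
    est.fit(X, y, trials=n, covariate_names=spec.covariates)
    return est.posterior_


def fit_spatial(table: pd.DataFrame, spec: ModelSpec, random_state=None) -> PosteriorFit:
    """Fit the Matérn geostatistical model to a cluster table."""
    X, y, n, coords = _design_from_table(table, spec)
    est = SpatialBinomialModel(
        nu=spec.nu, alpha_prior_sd=spec.priors.alpha_sd,
        beta_prior_precision=spec.priors.beta_precision,
        tau_prior_shape=spec.priors.tau_shape, tau_prior_rate=spec.priors.tau_rate,
        log_kappa_bounds=spec.priors.log_kappa_bounds,
        n_burn=spec.n_burn, n_samples=spec.n_samples, thin=spec.thin,
        strict_convergence=spec.strict_convergence, random_state=random_state)
    est.fit(X, y, trials=n, coords=coords, covariate_names=spec.covariates)
    return est.posterior_
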