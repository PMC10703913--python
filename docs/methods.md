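# Methods

## Model

Cluster counts are binomial given the local prevalence, with a logit-linear
predictor: intercept α, covariate effects β, and a latent spatially
structured effect S following a zero-mean stationary Gaussian process with
Matérn covariance (variance σ², inverse-scale κ, smoothness ν). The Matérn
correlation is `(2^{1−ν}/Γ(ν)) (κu)^ν K_ν(κu)` with `u` the Euclidean
distance in the working (planar-km) coordinate system; its practical range
√(8ν)/κ is the distance at which correlation falls to about 0.1. ν is fixed
at 1 by default — the standard choice for two-dimensional prevalence mapping
(one-times mean-square differentiable fields) — and is configurable.

Priors follow the non-informative convention for this class of model:
N(0, sd 100) on α (an effectively flat prior on the logit scale; a proper
Gaussian is used rather than a truly improper one so the intercept can be
handled by the same whitened Gaussian machinery as the rest of the model —
at posterior scales of ~0.1 the shrinkage is on the order of 10⁻⁶),
N(0, precision 0.001) on each β, Gamma(shape 1, rate 5·10⁻⁵) on the GP
precision τ = 1/σ², and log-uniform on κ. The κ prior is bounded so the
practical range lies between 1/20 and 2× the diagonal of the cluster
bounding box: below ~1/20 of the study extent a Matérn field is statistically
indistinguishable from independent cluster-level noise and begins chasing
binomial sampling variability. The Gamma prior on τ applies to the spatial
precision only (its scope for other scaled hyperparameters being ambiguous,
and there are none here). Note this prior is "non-informative" on the τ
scale but corresponds to a density ∝ σ⁻⁴ on the variance scale, so it
mildly favours small σ²; parameter-recovery experiments show a slight
downward pull on σ² and credible-interval coverage for cluster prevalence
near 0.9 rather than 0.95 under a fixed generating truth. That is a property
of the stated prior, not of the sampler.

## Survey weighting

Design weights enter through cluster-specific weighted counts: with child
microdata, the weighted prevalence p̂_d = Σ wᵢ·stuntedᵢ / Σ wᵢ is computed per
cluster, the denominator stays at the observed child count n_d, and the
effective numerator is round(p̂_d·n_d) — the binomial likelihood needs
integer counts, and only relative weights within a cluster matter. With one
weight per cluster the weights cancel and counts pass through unchanged.
The national summary is 100·Σy_eff/Σn_eff.

## Inference

Inference is MCMC on the exact dense-covariance likelihood (no mesh or
Laplace approximation); at ≤ ~1000 clusters a Cholesky factorization per
hyperparameter proposal is affordable (~2 ms at 400 clusters). The state is
whitened: α, β and the field are represented by standard-normal coordinates
mapped linearly to the model scale. One iteration combines six update types,
each individually a valid kernel:

1. **Elliptical slice sampling of the whitened field** (default 2 sweeps;
   the replicate-based recovery experiments use 4). ESS runs over the field
   only: including the wide-prior fixed effects in the ellipse throttles the
   accepted angle to the fixed effects' posterior scale divided by their
   prior scale and effectively freezes the field.
2. **Adaptive-Metropolis block on (α, β)** (Haario-style running covariance,
   Robbins–Monro scale targeting 0.234, frozen after burn-in).
3. **Confounded-direction moves**: the intercept trades off against the
   field mean, and each coefficient against the field's projection on its
   covariate. A move shifts one fixed effect by δ and subtracts the exact
   compensating field component (δ·L⁻¹u in whitened coordinates), leaving
   the likelihood invariant; acceptance depends on the Gaussian priors only.
   Without these moves the chain cannot mix along these ridges and reports
   spuriously precise intercepts and attenuated coefficients.
4. **Non-centered random-walk Metropolis on log σ²** (no new factorization).
5. **Interweaved centered Gibbs for σ²**: with S = σLv held fixed, τ is
   conjugate, τ | S ~ Gamma(a + n/2, b + S'K⁻¹S/2) with S'K⁻¹S = σ²‖v‖²;
   the whitened field is then rescaled. This ancillarity–sufficiency
   interweaving breaks the funnel that otherwise traps the non-centered
   chain at σ² ≈ 0.
6. **Paired non-centered and centered moves on log κ**: the non-centered
   move keeps the whitened field (likelihood-ratio acceptance, one new
   Cholesky); the centered move keeps the field *values* (GP prior density
   ratio, likelihood invariant).

Initialization matters for the variance updates: the fixed effects start at
a ridge-stabilized IRLS estimate, σ² at a method-of-moments value from
empirical-logit residuals (sampling variance subtracted, clipped to
[0.01, 10]), and the field at a kriging smoother of the post-regression
residuals — a field of plausible roughness under the initial correlation.
Starting from rough raw residuals launches the first centered variance draw
to absurd values; starting from zero strands the chain in the σ² ≈ 0 funnel.

Hot-path Matérn evaluations use a cubic-spline table in log(κu) (~10⁻¹²
absolute error against the exact Bessel form, ~7× faster); the public
`matern_correlation` stays exact. Duplicate or near-coincident locations are
handled by diagonal jitter on the correlation matrix starting at 10⁻⁸ and
escalating tenfold to 10⁻⁴ before erroring. Convergence is summarized by
split-chain R-hat and bulk ESS (arviz) on the retained single chain, with
default thresholds 1.05 and 100; `strict_convergence` turns failures into
errors. Credible intervals are equal-tailed 2.5/97.5 posterior percentiles.
WAIC uses the log-sum-exp-stabilized pointwise form with population
(ddof 0) variances for the effective-parameter term, making it invariant
under duplication of draws.

## Prediction surfaces

Surfaces are produced by composition sampling: for each retained posterior
draw, S at prediction cells is drawn from its exact Gaussian conditional
given that draw's field and hyperparameters, so hyperparameter uncertainty
propagates into the credible-interval-width maps. Cells are summarized
marginally (mean, SD, 95 % interval, exceedance fraction), so the
conditional draws are taken cellwise; joint spatial structure across cells
within a draw is not preserved and is not needed for per-cell maps.
Prediction is batched over cells and thinned to a configurable number of
draws (pipeline default 200); results are independent of the batch size.
The reported "SE" layer is the posterior SD of the latent prevalence —
binomial sampling noise of a hypothetical new survey is not added. The
default prediction grid is 5 km resolution over the cluster bounding box
(plus configurable margin).

## Covariate extraction

Aridity is mean monthly precipitation / mean monthly PET (nodata where PET
is 0); annual precipitation is the monthly sum, annual temperature the
monthly mean; nodata propagates through all temporal aggregation. Layers are
resampled to a master grid (default 5 km) by bilinear interpolation of the
four surrounding cell centers. Cluster values are the mean of cell centers
within the displacement buffer — 2 km urban, 5 km rural, by cell-center
membership (standard zonal-statistics convention). Buffered extraction is
translation invariant and bounded by the raster range. In geographic mode,
lon/lat coordinates are projected to planar km with a local equirectangular
projection before buffering, which is adequate at km scales. GeoTIFF
libraries are deliberately not required: rasters are ESRI ASCII grids with a
JSON sidecar carrying CRS label, seed and configuration hash.

## Synthetic surveys

The generator emulates the data structure the model assumes, with truth
retained:

- **Domain**: planar km rectangle (default 100×100 km), so Euclidean
  distances are unambiguous.
- **Clusters**: default 400 (country surveys run 400–700); urban share 30 %,
  urban clusters Gaussian-scattered around ~√n_urban town centers, rural
  uniform — mimicking population-proportional sampling's spatial
  irregularity without census frames.
- **Cluster sizes**: negative binomial, mean 12, dispersion 4 (≈ the 11.7
  children/cluster of a recent national survey, with realistic spread
  including empty clusters).
- **Weights**: log-normal, CV 0.5, normalized to mean 1 — positive and
  right-skewed like DHS design weights; only relative weights matter.
- **Covariates**: standardized sums of random cosine plane waves with
  wavelengths from 1/16 to 1/2 of the extent. The fine-scale half of that
  spectrum is essential: a covariate smooth at the Matérn practical range is
  spatially confounded with the latent field and its coefficient is not
  identifiable — as with real 5 km remote-sensed layers, identifiability
  comes from sub-range variation.
- **Latent field**: one joint Matérn draw at cluster sites *and* grid nodes
  (default σ² = 0.3, κ = 0.1/km i.e. range ≈ 28 km, ν = 1), so the stored
  truth surface and site values are a single coherent realization and
  logit P = α + dᵀβ + S holds exactly at grid nodes.
- **Displacement**: uniform angle, uniform distance up to 2/5 km by stratum,
  applied to the released coordinates only; truth keeps the originals.

Everything is a deterministic function of the configuration seed (per-stage
independent substreams), so runs are bit-reproducible.

What passing tests on these surveys do **not** show: robustness to real-data
features the generator omits — covariate measurement error and nonlinear
effects, non-stationarity and anisotropy of the spatial process, informative
sampling (weights correlated with prevalence), household clustering within
PSUs, and geodesic-distance effects at continental scales. Recovery
experiments deliberately fit the *undisplaced* coordinates and the true-site
covariate values; displacement and buffered extraction add attenuation that
belongs to robustness studies, not to correctness checks of the estimator.

## Pipeline

`run_pipeline` chains simulate/load → buffered extraction → weighted counts
→ non-spatial and spatial fits → surfaces from the WAIC-preferred model →
report, logging each stage with timings to console and `run.log`, embedding
the seed and a configuration hash in every raster sidecar, and writing
draws, diagnostics, Table-style summaries, the validation table and the
report JSON. The CLI exposes `run-all`, `simulate` and `fit`; extraction,
prediction and reporting have no separate entry points — they are cheap
relative to fitting and always rerun as part of a pipeline invocation, whose
stages remain individually callable as library functions.

## Problem sizes and numerical choices

Replicate-based checks run at the sizes stated in their tests: 20 replicates
of 400 clusters for parameter recovery (chains of 500 burn-in + 600 retained
draws, 4 ESS sweeps), 20×300 for the WAIC model-comparison property
(250 + 300), 500 clusters ≈ 10,000 children for the MLE-agreement check.
The recovery experiments place the truth near the reported posterior for the
smaller of the two published country analyses (α = −0.3, β = 0.32,
σ² = 0.3, κ = 1.355, ν = 1) on a domain scaled so the practical range is
about a quarter of the extent. The acceptance script runs 8 recovery
replicates and 10 WAIC-comparison replicates — enough for stable rates at
about ten minutes of compute. Degenerate inputs: σ² = 0 yields an
identically-zero field; empty clusters (n_d = 0) are legal everywhere and
excluded only from the observed-vs-predicted correlation (constant observed
series return a flagged NaN rather than an error); clusters with missing
covariates after extraction are dropped with a log entry; zero-weight
clusters are dropped with a log entry.

## Known limitations

- Dense-covariance MCMC scales as O(n³) per hyperparameter proposal;
  beyond ~1000–2000 clusters a low-rank or sparse-precision approach would
  be needed.
- κ mixes slowly when the data barely identify the range (few clusters per
  correlation length); R-hat/ESS diagnostics expose this, and the paired
  centered/non-centered κ moves mitigate but do not eliminate it.
- WAIC is computed in-sample from MCMC draws; with short chains its
  Monte-Carlo error can reach tens of units, so model comparisons should use
  the default chain lengths or longer.
- Only latent-prevalence uncertainty is mapped; small-area aggregates and
  design-based variance estimation are out of scope.
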