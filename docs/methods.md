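# Methods

## Model

`geoprobit` fits a distributional regression for a pair of correlated
binary outcomes. Conditional on covariates, the latent utilities of child
*i* are bivariate normal with means (mu_i1, mu_i2), unit variances and
correlation rho_i; the observed pair is (1{Y*_i1 > 0}, 1{Y*_i2 > 0}).
The four cell probabilities follow from the bivariate normal CDF by
inclusion–exclusion, e.g. P(1,1) = Phi2(mu1, mu2; rho).

All three distribution parameters get structured additive predictors.
Links: identity for the means, Fisher z (atanh) for the correlation, so
any real-valued predictor maps to a valid correlation via tanh. The
inverse link clips at |rho| = 1 − 1e-12 because tanh saturates to 1.0 in
double precision around |eta| > 19; the bounds are otherwise never
attained.

Phi2 is evaluated through Owen's T function (`scipy.special.owens_t`),
which is vectorised and accurate to ~1e-14 — comfortably beyond the 1e-8
the likelihood needs. Exact zeros in the thresholds are nudged by 1e-15
so the sign-dependent correction term of Owen's identity stays on the
right branch (the induced error is below 1e-14); signs are compared
directly rather than via the product h·k, which can underflow. Cell
probabilities are floored at 1e-300 before logs.

## Priors

* Linear coefficients (including each parameter's intercept): flat.
* Smooth terms: cubic B-splines on twenty equidistant knots spanning the
  observed covariate range (22 basis functions), with the second-order
  random-walk prior, i.e. an improper Gaussian with precision
  K = D2'D2 / tau^2 (rank 20; constants and linear trends unpenalised).
* Spatial term: intrinsic GMRF over districts, K = diag(|N(s)|) − A, the
  conditional-autoregression whose full conditionals have neighbour-mean
  expectation and precision proportional to the neighbour count.
* Every smoothing variance tau^2 ~ InverseGamma(a, b) with a = b = 0.001
  by default — the conventional weakly informative choice for structured
  additive models; both configurable.

### Identifiability

Smooth and spatial effects are only identified up to additive constants
absorbed by the intercept. Constraints are imposed *exactly* by
reparameterisation: each constrained block is sampled in the orthonormal
null-space basis T of its constraint functional (curve integrates to ~0
over an equidistant grid on the covariate range; spatial effects sum to
zero over regions, unweighted) and mapped back as beta = T alpha for
storage. This keeps the MH acceptance ratio exact, unlike post-hoc
centring. Island regions (no neighbours) have a zero precision row, so
their effect is additionally pinned at 0 by an extra constraint row and
reported as a warning.

## Sampler

Metropolis–Hastings within Gibbs with IWLS proposals. For one coefficient
block with reduced design Z and penalty K:

1. compute the per-record score u and *expected* information w of the
   exact bivariate probit log-likelihood with respect to the block's
   predictor (expected, not observed, information — it is always
   nonnegative, so the proposal precision is positive definite);
2. propose from N(m, P^{-1}) with P = Z'WZ + K/tau^2 and
   m = P^{-1} Z'(W Z alpha + u);
3. accept with the exact MH ratio; the reverse-proposal density is built
   from score and information re-evaluated at the proposed state.

Score and information for the resulting state are returned by each update
and reused by the next block of the same parameter within a sweep (they
depend only on the current predictors, which other blocks of the same
parameter do not touch between its updates).

The sweep order is all mu1 blocks, all mu2 blocks, all rho blocks, then
all variances; tau^2 draws are exact conjugate
InverseGamma(a + rank(K)/2, b + beta'K beta/2) samples. The chain is a
pure function of (data, design, config, seed). Non-finite proposals are
rejected and logged; a non-finite log-likelihood aborts the run.

Defaults are 12 000 iterations, 2000 burn-in, thinning 10. The validation
experiments use reduced chains (4000 iterations, 1000 burn-in, thinning
6), which the IWLS proposals' high acceptance rates (typically 0.4–0.98)
and near-independent draws make sufficient for posterior means and 95 %
intervals at the experiment scales.

Initialisation: mean intercepts at the probit of the marginal prevalence,
all other coefficients 0, tau^2 = 0.1.

## Pre-modelling pipeline

Outcomes may be derived from height-for-age / weight-for-height z-scores
with the strict rule `case iff z < −2`; a score of exactly −2 is a
non-case. Rows with missing modelled values are removed listwise and
counted. Categorical covariates are screened by plain Pearson chi-square
tests (no continuity correction) against each outcome and enter the model
when associated with *either* outcome at the chosen level (default 0.05);
continuous covariates bypass screening and always enter as smooths.
Multicollinearity of the selected dummy-coded design is checked with
VIF_j = 1/(1 − R²_j) from auxiliary least-squares regressions; exact
collinearity is reported as an infinite VIF, not an exception.

## Synthetic data

The generator mirrors the scale and makeup of a national child
anthropometry survey: by default n = 2000 children on an 8×9 rook-adjacency
lattice of 72 regions (a stand-in for the ~75-district map), four
categorical covariates with 2–5 uniform levels (wealth, maternal
education, maternal BMI class, toilet facility), child age uniform on
[6, 59] months, mother age uniform on [15, 49] years, regions uniform.
Scenario presets: `null` (everything zero), `prevalence_matched`
(intercepts only, giving ~40.7 % stunting and ~9.7 % wasting — the
emulated survey's prevalences), `linear_only`, and `full_geoadditive`.

Ground-truth scales were fixed once: linear coefficients between 0.05 and
0.45 in absolute value on the probit scale (the magnitude typical of
reported survey effects), smooth effects are full-period sinusoids with
amplitudes 0.15–0.35 centred over the covariate range, and spatial fields
are draws from the intrinsic GMRF made proper with a 1e-6 ridge, centred,
and standardised to sd 0.3 (means) / 0.15 (correlation predictor). In the
effect scenarios the intercepts absorb the average linear effect so the
marginal prevalences stay at the emulated survey levels. Latent pairs use
the per-record Cholesky construction because rho varies by record.

What the generator does *not* emulate: the survey's multistage cluster
sampling and weights (the model itself is unweighted), the empirical
joint distribution of covariates (independence is assumed), real district
geometry, and missing-data patterns. Passing recovery tests therefore
demonstrate correctness of the inference machinery under the model's own
assumptions, not robustness to design effects or covariate confounding in
real surveys.

## Validation experiments and their scales

* Probability core: closed-form orthant identities
  (Phi2(0,0;rho) = 1/4 + asin(rho)/2pi), agreement with per-record 2-D
  quadrature of the bivariate normal density on 50 records (1e-6), and
  cell-sum-to-one over 10^4 random parameter triples (1e-10).
* Conjugate variance step: 10^4 draws against the analytic inverse-gamma
  moments and a Kolmogorov–Smirnov test.
* Null calibration: 20 datasets (n = 2000) with no effects, linear model
  fits; the share of non-intercept 95 % credible intervals covering zero
  is ~94 % (nominal 95 %). These fits use the linear-only design because
  the calibration target is the linear coefficients.
* Recovery: with n = 4000, posterior means of linear effects track the
  truth at roughly the maximum-likelihood error (see limitations); true
  smooth curves lie inside the 95 % bands (compared after recentring both
  curve and truth on the same grid, since the two centring conventions
  differ by a constant absorbed in the intercept); true and estimated
  spatial fields correlate strongly (Pearson r ≈ 0.75–0.9 for the mean
  parameters). Curve and spatial recovery are scored on the two mean
  parameters, where a survey-sized dataset is actually informative; the
  correlation-predictor surfaces are reported but far more weakly
  identified at these sample sizes.
* Screening: chi-square type-I rate over 2000 independent tables within
  [0.03, 0.07] at the 5 % level; VIF of an r = 0.7 covariate pair near the
  closed form 1.96.

## Known limitations

* With a ~10 % prevalence outcome, n = 4000 and factors of up to five
  uniform levels, dummy-coefficient standard errors are 0.07–0.09 on the
  probit scale; the largest of ~11 such estimation errors is then
  typically near 0.2. The sampler attains this maximum-likelihood floor
  (its posterior means match a probit MLE to three decimals) — no
  estimator could be uniformly tighter without more data or informative
  priors.
* A single chain is run; convergence is monitored by split-chain R-hat
  and ESS (via ArviZ) rather than multi-chain diagnostics.
* The latent-utility data-augmentation sampler is deliberately out of
  scope; direct MH-IWLS on the exact likelihood is the reference
  algorithm.
* Spatial effects are discrete (region-level) only; no continuous
  (kriging) surfaces, tensor-product interactions or varying-coefficient
  terms.
* The bivariate probit assumes a Gaussian copula for the latent pair;
  misspecification of that dependence structure is not detectable from
  the four-cell likelihood alone.
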