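# Methods

This note documents the models and algorithms implemented in `bgwr`, the
choices made where the design was genuinely open, and what the synthetic
studies do and do not demonstrate.

## Model

Geographically weighted regression (GWR) fits a separate linear model at
every focal region `s`, down-weighting observations by their distance from
`s`.  The Bayesian variant implemented here places, at each region,

    y_i | beta(s), sigma^2(s) ~ N(x_i' beta(s), sigma^2(s) / w_i(s)),

where `w_i(s) = f(d_i(s) | b)` is a kernel weight in [0, 1]: nearby
observations carry more precision.  Three kernels are provided —
exponential `exp(-d/b)`, Gaussian `exp(-(d/b)^2)` and bi-square
`(1-(d/b)^2)^2 1{d<b}` — over Euclidean, great-circle (haversine, mean
Earth radius 6371 km) or graph-hop distances.  Weights of exactly zero
(bi-square beyond its support) are floored at 1e-12 in likelihood
evaluations so the implied variances stay finite.

The hierarchy is completed with `beta_j(s) ~ N(0, sigma_beta^2)` (one
variance shared across all coefficients and regions),
`sigma_beta^2 ~ IG(a_beta, b_beta)`, `sigma^2(s) ~ IG(alpha1, alpha2)` and
`b ~ Uniform(0, D)`.  Defaults are weakly informative:
`alpha1 = alpha2 = a_beta = b_beta = 0.01`.  `D` sets the bandwidth prior's
upper bound and should be chosen relative to the map's distance scale; a
`D` much larger than the maximum pairwise distance makes the model behave
like a global, equally weighted regression.

A note on conventions: two readings of the weighted likelihood circulate —
weights as precisions (variance `sigma^2 / w`) and weights as likelihood
powers.  This package uses the precision convention, the standard GWR
reading under which nearby observations count more.

### Sampler

One sweep per iteration:

1. `beta(s)` from its conjugate multivariate-normal full conditional
   (precision `X'W(s)X / sigma^2(s) + I / sigma_beta^2`), batched across
   regions with a masked Cholesky solve so per-region active-covariate
   masks are respected.
2. `sigma^2(s)` from `IG(alpha1 + n/2, alpha2 + (1/2) sum_i w_i(s) r_i^2(s))`.
3. `sigma_beta^2` from its conjugate inverse gamma over all active
   coefficients.
4. A reflected random-walk Metropolis step on the single shared bandwidth
   (skipped when the bandwidth is fixed).  Step size defaults to `D/20`.

The bandwidth target is the product of all `S` region-wise weighted
likelihoods **tempered by 1/S**.  The untempered product reuses every
observation `S` times, and that duplication alone drives the bandwidth to a
prior boundary: on the constant-coefficient study the untempered chain
pins `b` near `D` although the data carry almost no bandwidth information.
With the 1/S tempering the data enter the shared-bandwidth update once
effectively, and the bandwidth posterior on that study is appropriately
diffuse (it retains a mild tilt toward the global limit, which is the
correct signal when the coefficients truly do not vary).  All other
updates are per-region conditionals and are unaffected.

Bandwidth estimation through any joint weighted pseudo-likelihood has a
structural limitation: the normalization term `(1/2) sum log w` always
grows with `b`, and with locally adapted `sigma^2(s)` it dominates, so the
pseudo-posterior prefers near-global bandwidths even when the coefficient
surface genuinely varies.  For analyses that need a localizing bandwidth
the package provides `select_bandwidth_cv`, the classic GWR leave-one-out
cross-validation selector on the weighted-least-squares surface, which
exhibits a clean interior optimum on the spatially varying study.  The
spatially varying pipeline therefore fixes the kernel scale at the CV
optimum and lets the MCMC estimate everything else.

Initialization: `beta(s)` from ridge-stabilized weighted least squares at
`b = D/2`, `sigma^2(s) = 1`, `b = D/2`.  Identical settings and seed give
bit-identical draws.

### Variable selection

Each (region, covariate) pair carries an indicator `gamma_j(s)` with the
linear predictor `x_i'(Gamma_s * beta(s))`; `gamma_j(s) ~ Bern(psi_j)` and
`psi_j ~ Beta(1, 1)` shared across regions per covariate.  Births propose
`beta_j(s)` from its prior `N(0, sigma_beta^2)`, so the reversible-jump
acceptance ratio reduces to the weighted-likelihood ratio times
`psi_j/(1-psi_j)`; deaths use the reciprocal.  With the prior as proposal
this scheme is equivalent in stationary distribution to Kuo–Mallick
indicator sampling.  `psi_j` then gets a conjugate
`Beta(1 + sum_s gamma_j(s), 1 + S - sum_s gamma_j(s))` update.  Intercept
columns (named `intercept` or constant) are exempt from selection by
default.  Excluded coefficients are stored as exact zeros; summaries
report both marginal means `E[gamma beta]` and conditional means
`E[beta | gamma = 1]` (absent, not zero, for pairs never included).

### Clustering of coefficient surfaces

At each retained iteration the sampler yields an `S x p` coefficient
matrix.  Two clusterers operate on such matrices:

- **GMM**: full-covariance EM with covariance diagonals floored at 1e-6,
  `restarts` seeded initializations (default 10), tolerance 1e-6, and the
  component count chosen by BIC (`-2 logL + q log S`,
  `q = K-1 + Kp + Kp(p+1)/2`) over `K = 1..10`.  Ties in BIC go to the
  smaller `K`.
- **DPMM**: truncated stick-breaking representation (`H = 20`) sampled by
  blocked Gibbs — categorical assignments, `V_k ~ Beta(1+n_k,
  alpha + sum_{l>k} n_l)`, and conjugate Normal–Inverse-Gamma updates of
  the per-dimension component means and variances.  `alpha = 1` by
  default, with an optional Gamma(2, 2) hyperprior.  The default base
  measure is empirical: mean at the data mean, `kappa0 = 0.01`, `a0 = 2`,
  and prior variance scale `b0` at the pooled per-dimension variance.

Consensus partitions come from Dahl's method (the sampled partition whose
coassignment matrix is closest in least squares to the posterior mean
coassignment; ties to the smallest draw index) or the per-region modal
label (ties to the smallest label).

The two-stage procedure draws `n_samples` posterior iterations without
replacement, clusters each iteration's coefficient matrix, aligns the
sample partitions, and takes the per-region mode across samples (missing
entries ignored).  Two alignment rules are provided: Hungarian matching of
each sample's clusters against the first sample's partition (default), and
canonical relabeling by order of first region appearance.  Hungarian
matching is the default because first-appearance relabeling demonstrably
misaligns partitions that differ near cluster boundaries, degrading the
consensus on the spatially varying study.

The DPMM base-measure scale matters: the pooled per-dimension variance
overstates within-cluster spread (it contains the between-cluster signal)
and can merge distinct clusters, while calibrating it to the posterior
uncertainty of the coefficients fragments the smooth boundary regions into
many micro-components.  Both were evaluated on the spatially varying
study; neither dominates after the across-sample mode, so the simple
pooled empirical default is kept, and `base_params` is exposed for
analyses that need a different scale.

Accuracy against a reference partition is the Rand index, the fraction of
region pairs on which two partitions agree.

### Model assessment

WAIC and DIC use each observation's own-region predictive density at zero
distance (self-weight exactly 1): `N(x_i' beta(s_i), sigma^2(s_i))` — the
only choice under which every observation has a single well-defined
density in a model where each datum otherwise enters every region's
weighted likelihood.  `WAIC = -2(lppd - p_waic)`;
`DIC = D(theta_bar) + 2 p_d` with `p_d` = mean deviance minus deviance at
the posterior means.  Because these are in-sample criteria they cannot be
used to select a localizing bandwidth (see above).

## Synthetic studies

Two seeded generators reproduce the structure of the validation designs.

**Constant-coefficient ("Louisiana-like")**: 64 regions on a regular 8x8
lattice rescaled so the maximum pairwise distance is 10; three
observations per region (192 rows); five i.i.d. N(0,1) covariates;
`y = X beta + eps`, `beta = (2, 0, 0, 4, 8)`, `eps ~ N(0, 1)`.  Fitting
uses the exponential kernel with `D = 100`, so weights never fall below
about 0.904 and the model approximates a global regression.

**Spatially varying ("Georgia-like")**: 159 regions on a jittered lattice
(rook adjacency, rescaled to maximum distance 10), partitioned into three
contiguous blocks of 51/49/59 regions by sorted coordinates.  Six
covariates are single draws of a Gaussian process with covariance
`exp(-(d/phi)^2)`; `phi` defaults to one-fifth of the maximum distance.
Each cluster has its own six-coefficient vector under three
signal-strength settings (setting 3 is the strongest, e.g. cluster 1 =
(9, 0, -4, 0, 2, 5)); the intercept is 0, one observation per region,
unit noise.  Coefficients are cluster-constant; an optional within-cluster
perturbation is deliberately not applied.

The spatially varying analysis pipeline fits the six covariates without an
intercept column (the generating model has none, and the extra
pure-noise coefficient dimension degrades both local identifiability and
the clustering input), with the bi-square kernel at the CV-selected
bandwidth.

What these generators do not emulate: real county/SA2 geographies,
non-Gaussian responses, covariate measurement error, and within-cluster
coefficient variation.  Passing recovery tests therefore demonstrates
correctness of the algorithms under the stated generating processes, not
performance on real areal data.

## Problem sizes used in the checks

The recovery checks run 10 replicates of 3000 iterations (1000 burn-in)
for the constant-coefficient study, a single 20000-iteration selection
chain, and a 2000-iteration fit with 50 posterior samples for the
spatially varying clustering study.  Clustering accuracy at these sizes
has visibly higher variance than at full scale; the acceptance bands used
in the tests reflect that.

## Numerical choices

- Weighted normal matrices are solved by Cholesky; the WLS initializer
  adds a ridge of `1e-8 x tr(X'X)/p` only if needed for stability.
- Reflected random-walk proposals keep the bandwidth inside `(0, D)`
  without breaking proposal symmetry.
- All tie-breaks (modal labels, BIC, Dahl argmin) go to the smallest
  index/label, making every consensus deterministic given the draws.
- Degenerate inputs: identical points collapse the GMM to one component
  with a warning; a DPMM whose occupied components ever hit the
  truncation emits a warning to enlarge it; regions with only missing
  labels, disconnected graphs, and unknown region ids raise informative
  errors.

## Known limitations

- The bandwidth posterior under the joint weighted pseudo-likelihood is
  only weakly identified when coefficients are near-constant and is
  biased toward global smoothing when they vary; use the CV selector for
  localizing analyses.
- The shared `sigma_beta^2` shrinks all coefficients toward zero on a
  single scale; covariates on very different scales should be
  standardized.
- Mode-based consensus depends on label alignment across samples; the
  Hungarian default is a heuristic and can be challenged by samples whose
  cluster counts differ greatly.
- DPMM cluster counts are sensitive to the base-measure scale; the
  posterior-variance calibration assumes the fitted model's posterior
  spread is a fair proxy for within-cluster spread.
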