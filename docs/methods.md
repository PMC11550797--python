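# Methods

## Model

For each emergency-department case `i` with binary ADR outcome `y_i` and
predictor row `x_i` (binary drug indicators plus covariates) the package
fits a Bayesian logistic regression

    y_i ~ Bernoulli(logit^-1(beta0 + x_i' beta)),

with one of two shrinkage priors on the coefficients and a wide
Normal(0, 10^2) prior on the intercept (the intercept is never shrunk; it
absorbs the outcome's base rate).

### Regularized horseshoe

    beta_j | lambda_j, tau, c ~ N(0, tau^2 * lt_j^2),
    lt_j^2 = c^2 lambda_j^2 / (c^2 + tau^2 lambda_j^2),
    lambda_j ~ half-Cauchy(0, 1),
    tau ~ half-Cauchy(0, tau0),
    c^2 ~ Inverse-Gamma(nu/2, nu s^2 / 2).

The half-Cauchy local scales give the coefficient marginals an infinite
spike at zero and heavy tails: noise coefficients are pulled to ~0 while
large effects escape almost unshrunk, up to the finite slab width `c`
which bounds how far escaped coefficients can grow (important with
separable binary predictors, where an unbounded prior lets coefficients
run away).

Two hyperparameters are calibrated from the data dimensions:

* **Global scale** `tau0 = (p0/(p - p0)) / sqrt(n)` — the ratio of the
  expected number of non-zero coefficients `p0` to the expected number of
  zero coefficients, divided by the square root of the number of
  observations. Smaller `p0` means more aggressive shrinkage.
* **Slab scale** `s = sqrt(c0/p0) * sd(y)` — the square root of a constant
  `c0` over `p0`, times the outcome's standard deviation. `sd(y)` is the
  *population* standard deviation `sqrt(q(1-q))` of the binary outcome
  (the sample-vs-population choice is not observable at these n; we fix
  population normalization). The default `c0 = 6.25 * p0` makes
  `s = 2.5 sd(y)` — a weakly informative slab on the logistic scale —
  while leaving `c0` fully configurable. Slab degrees of freedom default
  to `nu = 4`.

`p0` itself has no data-driven default; it encodes pharmacological
expectation about how many of the screened drugs truly drive the ADR. The
pipeline defaults to `p0 = 5` and emits a loud log line when the user has
not set it.

### Laplace (lasso)

`beta_j ~ Laplace(0, b)`, the Bayesian analogue of L1 penalization. A
fixed scale is supported, but the default (`learn_scale=True`) places a
conjugate Gamma(1, 1) hyperprior on the squared penalty `1/b^2` via the
scale-mixture representation (`beta_j ~ N(0, psi_j)`,
`psi_j ~ Exp(1/(2 b^2))`), so the overall penalty adapts to the data. A
fixed `b` of order 1 exerts almost no shrinkage at registry sample sizes,
which is why the adaptive variant is the default.

### Predictor scaling

Predictors enter as-is: drug indicators in {0,1}, CYP counts as small
integers, age in years. No standardization is applied — binary-indicator
coefficients then stay interpretable as per-drug log-odds — but because
age's scale is ~100x larger than the indicators', its coefficient is
shrunk on a different effective scale; users comparing covariate and drug
coefficients should keep this in mind (or standardize age upstream).

## Inference engine

Sampling uses Polya-Gamma data augmentation: with
`omega_i ~ PG(1, eta_i)` the Bernoulli-logistic likelihood becomes
conditionally Gaussian, so the full coefficient block (intercept included)
has an exact multivariate-normal conditional, drawn by Cholesky
factorization of the (p+1)x(p+1) precision. PG(1, z) variates are drawn
with the exact Devroye alternating-series rejection sampler, numba-
compiled (one draw per observation per sweep).

The shrinkage latents are updated by slice sampling on the log scale,
which is tuning-free and leaves the stationary distribution exact:

* the local scales `lambda_j` are conditionally independent given
  `(beta, tau, c)` and are updated in one vectorized sweep;
* the global scale `tau` and the slab width `c` are updated by
  **collapsed** slice sampling, with the whole coefficient block
  integrated out of the augmented Gaussian model analytically (ridge
  evidence formula, one Cholesky per density evaluation). This matters: in
  the centered parameterization tau's conditional is so tightly coupled to
  `beta` and `lambda` that its effective sample size was ~4 per 1000
  draws at n=4000, p=111 (an ancillarity-sufficiency interweaving update
  did not repair it); the collapsed update yields ESS of order 100+ per
  1000 draws at negligible cost.

Under the Laplace prior the mixture variances have conjugate
inverse-Gaussian conditionals (`1/psi_j | beta_j ~ IG(1/(b|beta_j|), 1/b^2)`)
and the learned squared penalty a conjugate Gamma update.

Chains are seeded deterministically from one master seed via
`SeedSequence.spawn`; identical seed and data reproduce identical draws.
Convergence is summarized per parameter by split-R-hat and bulk ESS
(computed with arviz); a fit whose worst R-hat exceeds `rhat_max`
(default 1.01) or worst ESS falls below `ess_min` (default 400) carries an
explicit warning state, surfaced in the run manifest and the CLI exit
code — never silently dropped.

Degenerate inputs: an all-zero predictor column is legal (its coefficient
simply retains its prior marginal — verified by a KS test against
ancestral prior draws); numerical guards clip `|beta_j|` at 1e-12 in the
inverse-Gaussian update and cap its mean at 1e8.

## Credible intervals and classification

Coefficients are summarized by the posterior median and equal-tailed
50%/90% intervals using linear interpolation between order statistics
(the quantile convention is fixed here because different software defaults
disagree at these draw counts). Classification: 50% interval entirely
above zero = light positive; 90% interval also above zero = strong
positive; mirrored for negative. An endpoint exactly at zero counts as
covering zero — the conservative reading. Negative classifications are
reported but should not be interpreted as protective effects: in a
case/non-case registry design they largely reflect the composition of the
comparison group. No multiplicity adjustment is applied; the shrinkage
prior is the multiplicity control.

## Synthetic cohorts

The generator emulates the structure of a large multi-center
emergency-department ADR registry:

* **Scale** (defaults): 7967 raw cases, of which 791 are second visits by
  the same patient and 1 has a missing medication record, over a catalog
  of 1627 substances — so the curation pipeline leaves exactly 7175
  analysis cases.
* **Demographics**: ages from a skew-normal (location 90, scale 27,
  shape −3) truncated to [18, 105], giving median ≈72, IQR ≈(58, 81);
  49.2% female.
* **Exposures**: per-case drug counts from a zero-truncated negative
  binomial (mean 7.8, dispersion 2.0; median 7, IQR within one unit of
  (3, 10)); drug identities sampled without replacement within a case from
  Zipf weights with exponent 1.45 over the catalog. The exponent was
  calibrated (once, by pilot simulation) so that the per-case count of
  drugs excluded by top-100 selection has median 1, IQR (0, 2), while at
  least 100 substances still clear the 32-occurrence frequency threshold.
  Without-replacement sampling flattens the head of the empirical rank
  curve, so exponent recovery is only expected on mid-tail ranks.
* **Catalog structure**: configurable fractions of combination products
  ("a/b" names), unspecific labels, and supplements (defaults 5%/2%/3%),
  spread across the popularity ranking; the eight CYP substrate/inhibitor
  flags are assigned independently per drug with probability 8%.
* **Outcomes**: Bernoulli draws from a sparse logistic ground truth
  (a handful of drug effects plus optional age/sex/covariate effects).
  The registry-scale preset additionally *fixes the case split exactly*
  (455 fall or 1977 bleeding positives among the 7175 survivors) by
  weighted sampling without replacement proportional to each survivor's
  true outcome probability — the planted associations are preserved while
  the count arithmetic becomes deterministic.
* **Repeat visits** are exactly one extra visit per selected patient;
  missing medication is an empty drug list (not a sentinel), and the
  missing-record filter applies to raw records only — a case whose drugs
  are all dropped as unspecific/supplements stays in the analysis with a
  correspondingly large excluded-drug count.

What the generator does **not** emulate: co-prescription correlation
beyond shared popularity weights (no therapy-class bundles, no
confounding by indication), MedDRA outcome coding, causality assessment,
dose or duration. Passing the recovery benchmarks therefore shows the
estimator works when its sparsity assumptions hold — not that it defeats
indication bias in real registries, where a drug prescribed *because* of a
fall-risk condition can carry a genuine but non-causal signal.

## Benchmarks and numerical checks

* **Oracle agreement**: on a fixed 50-observation, one-predictor dataset
  with `tau` and `c` held fixed, the sampler's posterior mean and sd agree
  with deterministic (beta, lambda) quadrature to <0.02. The oracle
  integrates the local scale out per beta value with adaptive quadrature
  on the half-Cauchy CDF transform; a naive 2-D grid is *not* adequate —
  the near-delta normal at tiny lambda concentrates unresolved mass at
  beta=0 and biases the grid answer by ~0.2.
* **Recovery benchmark** (frozen after a pilot, seeds 101–105): ~4000
  curated cases, 100 drug indicators plus the 11 covariates, five planted
  drug effects of +1.5 at plain-product popularity positions
  11/19/29/41/56 (per-drug exposure ~1.5–15%), outcome prevalence ≈8%
  (falls-like). Fits use 2 chains x (500 warmup + 500 kept) draws — sized
  so interval estimates are stable while a full two-prior, five-seed sweep
  stays in the minutes range on one CPU. The horseshoe runs with
  calibrated `p0=5`; the lasso benchmark runs at fixed `b=0.1`, the
  penalty scale commensurate with the same sparsity expectation (the
  adaptive default, which must hedge against non-sparse data, settles near
  b≈0.3 here and flags too many borderline noise coefficients to serve as
  a selection benchmark). Pass criteria: all five planted effects at least
  light positive and ≥90% of null predictors classified none, on ≥4 of
  the 5 seeds per prior.
* **Shrinkage contrast**: on every benchmark seed the lasso flags at least
  as many predictors (50%-interval criterion) as the horseshoe — in
  practice roughly twice as many — matching the qualitative behavior
  expected of the lighter-tailed prior.

## Known limitations

* The Gibbs sweep is O(n p + p^3 + n_PG) per iteration; fine up to a few
  hundred predictors, not designed for p in the thousands.
* Posterior summaries at default draw counts carry Monte-Carlo error of a
  few hundredths on coefficient medians; borderline light-positive calls
  near an interval endpoint of zero can flip between seeds.
* Negative signal classes are structurally uninterpretable as protection
  (see above).
* The curation stage trusts its configuration lists; it has no built-in
  pharmacological dictionary (combination main-substance rules, unspecific
  and supplement lists, and the CYP table are user- or catalog-supplied).
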