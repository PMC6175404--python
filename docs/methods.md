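# Methods

## The model

`pairsel` implements Bayesian variable selection for *paired* predictors in
a case–control logistic regression. The motivating data structure is
ultrahigh-resolution mass-spectrometry proteomics, where each isotope
cluster yields two summary measures: an intensity summary *u* (the sum of
log-transformed peak intensities, Eq. below) and a shape summary *v* (the
center of gravity of the residual distribution over the cluster's peak
positions):

    u = Σ_j l_j ,    v = Σ_j j·p_j ,   p_j = x_j / Σ_j x_j ,

with `l_j` the log peak intensities and `x_j` the residuals from a typical
isotope pattern (computed upstream; this package accepts them as given).
Intensity is the established, "primary" predictor source; the scientific
question is whether — and where — shape adds predictive value beyond it.

The sampling model for `n` individuals and `p` pairs is

    y_i ~ Bernoulli(p_i),
    logit(p_i) = β₀ + Σ_{j∈couples} (a_j u_ij + b_j v_ij) + Σ_{l∈singletons} a_l u_il,

where a cluster may be included as a *couple* (both components) or as an
intensity *singleton*, but never as shape alone. This asymmetric constraint
encodes the prior knowledge that shape is complementary: a shape effect is
only meaningful on top of its intensity. The number of included clusters
k = k_C + k_I is itself a parameter.

### Priors

* β₀ ~ N(0, `intercept_sd`²), default `intercept_sd = 10` (weakly
  informative on the logit scale).
* a_j ~ N(0, σ_a²), b_j ~ N(0, σ_b²) with σ_a² = τ_a²/s_a, σ_b² = τ_b²/s_b.
  τ_a, τ_b are fixed rescaling factors that absorb the (large) scale
  difference between the two sources; s_a, s_b ~ Gamma(α, β) (shape–rate),
  default α = β = 1, are adaptive scale factors updated by conjugate Gibbs
  draws.
* k ~ Uniform{0, …, kmax}; given k, all `C(p,k)·2^k` configurations
  (choice of clusters and couple/singleton composition) are equally likely.
  This is the only model-space prior consistent with the stated discrete
  uniform prior on k, and it is validated exactly (see below).

`prior_scale_heuristic` produces data-driven τ's from the logistic-regression
approximation Cov(β̂) ≈ n(XᵀX)⁻¹: τ = n·median_j(1/xⱼᵀxⱼ), rounded to two
significant figures, separately for the u and the v columns. Columns are
used as supplied (no centering or standardization); the separate τ's are
the mechanism that accommodates the source scale difference. For columns
with cross-products of order 10³ (u) and 10² (v) at n = 254 this yields
0.25 and 2.5.

## The sampler

A reversible-jump MCMC with six moves: birth/death of a singleton,
birth/death of a couple, and two composition changes (add/remove the shape
of an included cluster). The move schedule assigns probability 1/6 to each
move in interior states and redistributes the mass of structurally
impossible moves at the boundaries (empty model, full model k = kmax,
states with no singletons or no couples); the full table is in
`sampler.move_probabilities`. Birth targets are uniform over fully excluded
clusters; death/change targets are uniform over the relevant included set.

### Auxiliary-variable augmentation

The logistic likelihood is handled with the Holmes–Held construction:
z_i = η_i + ε_i with ε_i ~ Logistic(0,1), y_i = 1{z_i > 0}, and
ε_i | λ_i ~ N(0, λ_i) with λ_i = (2ψ_i)², ψ_i ~ Kolmogorov–Smirnov.
Each sweep refreshes (z, λ) jointly: z_i from its truncated-logistic
conditional (mixing variance integrated out — this is the better-mixing
joint update, equivalent to the truncated-normal decomposition), then λ_i
from p(λ | z_i − η_i) by rejection sampling. The mixing density has the
exact series representation p(λ) = Σ_{n≥1} (−1)^{n+1} n² e^{−n²λ/2};
proposals are GIG(1/2, 1, r²) (generated as the reciprocal of an
inverse-Gaussian(1/r, 1) draw) and are accepted with probability
S(λ) = p(λ)e^{λ/2}, evaluated to double precision by the alternating
series for λ > 4/3 and its Jacobi-theta transform for small λ. The kernel
is compiled with numba for speed; the identical series is exposed in
NumPy form and the two are cross-checked in the tests, and the λ
conditional is validated against direct numerical quadrature of the
mixing density.

### Coefficient-integrated move acceptance

Conditional on (z, λ, s_a, s_b) the model is Gaussian-linear, so the move
acceptance uses the closed-form marginal likelihood of z with β integrated
against its block-diagonal normal prior, evaluated through the Cholesky
factor of the (1+k+k_C)-dimensional posterior precision
Q = XᵀΛ⁻¹X + Σ₀⁻¹ (the n×n covariance is never formed; a 1e-10 jitter is
applied once on a Cholesky failure, and a second failure aborts with
context). The acceptance probability is

    A = min{1, ML-ratio × prior-ratio × proposal-ratio},

where the prior ratio follows from the uniform-k/uniform-configuration
prior and the proposal ratio uses the reverse-move probability and
candidate-set sizes. Because coefficients are integrated out at acceptance,
an accepted change move needs no dimension-matching Jacobian; the new
shape coefficient materializes in the subsequent Gibbs draw.

Each iteration then draws β ~ N(m, Q⁻¹) exactly, refreshes (z, λ), and
updates the scales by conjugacy:
s_a ~ Gamma(α + k/2, β + Σa²/(2τ_a²)), s_b ~ Gamma(α + k_C/2, β + Σb²/(2τ_b²)).
The sweep order (move, coefficients, augmentation, scales) is one valid
cyclic composition of the conditional updates; the order is not prescribed
by the science. The intercept is always in the model and is integrated
alongside the effects. A single seeded `numpy` Generator drives every
random choice, so chains are exactly reproducible.

### Validation hooks

`ChainSettings(prior_only=True)` forces the marginal-likelihood ratio to
one, so the chain targets the model-space prior; the test suite verifies
the k-marginal is uniform both by simulation (χ² GOF on a thinned trace —
the raw k trace is a random walk, so thinning to near-independence is
required for a valid GOF test) and *exactly*, by building the (k_I, k_C)
transition matrix from the package's own acceptance ratios and solving for
its stationary distribution (uniform to 1e-10). `fix_scales=(s_a, s_b)`
pins the variance scales, which makes small problems exhaustively
enumerable: on a p = 2, n = 8 problem the chain's posterior over all nine
configurations matches Laplace-centered Gauss–Hermite quadrature of the
Bernoulli marginal likelihoods to total-variation distance < 0.01.

### Default run lengths

The default schedule (`pairsel fit`) is 500,000 iterations after a 200,000
burn-in, thinned every 50 (≈10⁴ stored states), matching full-scale
proteomic analyses; whether to run one long chain split for diagnostics or
two independent chains is an open convention — the diagnostics
(`convergence_diagnostics`) accept either. The simulation-study and
acceptance runs use 150,000 iterations with 50,000 burn-in and thin 25
(4,000 stored states); scenario 3, whose seven strong effects make the
coefficient/variance-scale coupling mix slowly, is run at 400,000
iterations with 120,000 burn-in.
Convergence is monitored by comparing chain halves through autocorrelations
(lags 1, 5, 10, 50) and two-sample Kolmogorov–Smirnov distances on k, k_C,
k_I, s_a, s_b; no automatic verdict is issued. Mixing of large coefficients
is slow under near-separation (lag-1 autocorrelations near 1) — a known
property of this augmentation — which is why the simulation chains are run
long and thinned.

## Posterior summaries

* Inclusion probabilities per cluster, split by composition:
  p_any = p_singleton + p_couple holds exactly by counting. The log-ratio
  log(p_couple/p_singleton) is reported only when both probabilities are
  positive (NaN otherwise; no ε-padding).
* Marginal mean coefficients: the average over *all* stored models,
  counting zero when the component is excluded. Under heavy overselection a
  component can have sizeable inclusion probability yet near-zero marginal
  mean — that combination is the diagnostic for a null effect.
* Combined posterior summary PS: per model, |β| is normalized by the total
  |β| of the *same source* (intensities normalized over the k′ = k included
  intensities, shapes over the k′ = k_C included shapes) and weighted by
  1/k′; PS is the average over models. Source-specific normalization
  accounts for the scale difference between u and v. Summing PS within a
  source gives the chain average of 1/k′ over models using that source.
* Dimensionality percentiles use the nearest-rank definition.
* Prediction: the model-averaged logistic probability (mean over stored
  models), invariant to sample order.
* Metrics: error rate at a 0.5 cutoff, Brier score, AUC by the
  Mann–Whitney statistic with midranks, and a 95% DeLong CI (checked
  against R's pROC to 1e-9; a bootstrap CI was considered and rejected as
  the default because DeLong is deterministic and standard).

## Cross-validation

Stratified k-fold (default 10): within-class random permutation followed by
round-robin assignment, so per-fold class counts differ by at most one.
Ratio preservation deliberately takes precedence over exactly equal fold
sizes, because the case:control ratio strongly affects selection. One chain
is fitted per calibration set with a distinct sub-seed spawned
deterministically from the master seed; held-out model-averaged
probabilities are pooled across folds for the metrics. Per-fold cluster
inclusion probabilities are reported with their across-fold mean and
spread; the spread is the sample SD of the fold-wise probabilities (an
SD/√nfolds convention would be a standard error of the mean — both are
defensible; the SD is reported because the folds are the quantity of
interest, and dividing by √10 merely rescales the column).

## Synthetic data

`simulate.generate_scenario` emulates the study structure: n = 254
individuals (the analysis sample size; the cohort itself had 273 — the
exclusion rule is not derivable, so n is configurable), p = 100 pairs,
both components iid N(0, 2.5²), outcome Bernoulli(logistic(β₀ + Ua + Vb))
with β₀ = 0. Three built-in scenarios:

1. a₁₀₀ = 3.5 (single informative intensity);
2. a₁ = b₁ = 2.5, a₁₀₀ = 1.5;
3. a₁ = 3.5, a₃₀ = 2, a₅₀ = a₈₀ = 2.5, a₁₀₀ = 1.5; b₁ = 1.5, b₃₀ = 1;

all fitted with kmax = 50, α = β = 1, τ_a = τ_b = 1. An optional
equicorrelation knob correlates (u_j, v_j) within pairs through a bivariate
normal with the stated marginals; 0 is the faithful default. The generator
is deliberately unconstrained (a nonzero b with zero a is representable):
the asymmetric constraint is a property of the *model* under test, not of
the data.

What the simulations do not emulate: real isotope-cluster summaries are
heavy-tailed, heteroscedastic and correlated across clusters, the u and v
scales differ by an order of magnitude (hence the τ heuristic), and p
reaches ~1300. Passing the scenario tests therefore demonstrates correct
inference under the stated generative model, not robustness to real
spectra.

### Known behaviour worth stating plainly

* **Shape overselection.** In scenario 2 the shape of the last pair has no
  true effect yet attains a non-trivial couple-inclusion probability while
  its marginal mean coefficient stays at zero. This is a known deficiency
  of reversible-jump selection, reproduced deliberately — the PS summary is
  the designed mitigation.
* **Coefficient inflation under near-separation.** With a true effect of
  3.5 on an N(0, 2.5²) component, most observations are deterministically
  classified and the likelihood for the slope is nearly flat on one side.
  The exact posterior mean (verified by quadrature, independently of MCMC)
  then varies roughly between 3 and 5 across data realizations with an
  average near 4. The model-averaged coefficient inherits this: recovery of
  strong effects is accurate only up to this intrinsic sampling spread,
  which is why scenario-recovery checks average over replicate datasets.

## Numerical choices

* Overflow-safe log-likelihoods (`log1p`/`logaddexp` forms throughout);
  linear predictors clipped at ±700 before `exp`.
* λ rejection sampling floors |r| at 1e-8; the truncated-logistic draw
  clips the uniform into [1e-300, 1−1e-16] and enforces the sign invariant
  exactly.
* Chain persistence is JSON-lines with full `repr` float round-tripping
  (bit-exact reload), configurations stored as sparse index lists, and a
  header carrying settings, prior and sample count; truncation or version
  mismatch raises a format error.
* Missing values and non-binary outcomes are rejected at the reader, never
  imputed.
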