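# Methods

## The family and its numerics

The NE-X generator maps a baseline cdf F to
G = 1 − [A/B]^θ with A = 1 − F² and B = 1 − (1−θ)F², θ > 0.
B is bounded below by min(θ, 1), so log B is always safe; A is computed
through the baseline survival function as (1−F)(1+F), which avoids
cancellation as F → 1.  All distribution functions are assembled in log
space (`log1p`/`expm1`), so θ ≫ 1 and deep-tail arguments neither overflow
nor lose the survival probability to rounding.

The quantile inverts G through w = (1−u)^(1/θ) and
F² = (1−w)/(1−(1−θ)w).  For small θ, w underflows long before u reaches 1
while F² rounds to 1; the implementation therefore hands the baseline the
*log survival* log(1−F) = log(θw/B(w)) − log(1+F), which stays finite, and
baselines with a closed-form inverse (Weibull) invert it exactly.  Baselines
without a closed form fall back to bracketed root-finding on the cdf
(tolerance 1e−12 in x, i.e. far below 1e−10 in probability for the models
here).  Sampling is inverse-transform from uniform draws confined to (0,1);
exact zeros are redrawn.

Degenerate inputs: θ ≤ 0 is rejected at construction; quantile arguments
outside [0, 1) raise; the hazard raises where the survival function is
exactly zero (only reachable for bounded-support baselines — for Weibull
baselines the log-space hazard is finite at every finite x).

## Moments

Quadrature is the canonical engine: E[h(X)] is integrated in x-space with
the domain split at the distribution median and `scipy.integrate.quad`'s
semi-infinite transformation for the tail (absolute/relative tolerance
1e−10).  Central moments are integrated directly against (x − mean)^k
rather than assembled from raw moments, which would cancel catastrophically
for the heavy-tailed parameter corners.  Skewness and kurtosis are
μ₃/μ₂^(3/2) and μ₄/μ₂² (kurtosis is not excess).  The mgf is the moment
series Σ tʳ μ'ᵣ/r! with a divergence monitor, with a direct-quadrature
variant ∫e^{tx} g dx (integrand evaluated as exp(tx + log g) to avoid
inf·0) as its own oracle.

A series representation of μ'ᵣ in the kernel integrals
K_{r,m} = ∫ xʳ f F^m dx exists for positive integer θ, where the binomial
expansion of (1−F²)^(θ−1) terminates.  The textbook double series — expand
1/B^(θ+1) in powers of (1−θ)F² and integrate term by term — is **divergent
for θ ≥ 2**: its terms grow like C(i+θ, θ)(θ−1)^i while the integrals decay
only algebraically, and for θ ≥ 3 the expansion variable even leaves the
radius of convergence on part of the support.  `series_raw_moment`
therefore regroups the same expansion around the value B takes at F = 1:

    1/B^(θ+1) = θ^−(θ+1) Σᵢ C(i+θ, θ) ρ^i (1−F²)^i,   ρ = (θ−1)/θ < 1,

giving μ'ᵣ = 2 θ^(1−θ) Σᵢ C(i+θ, θ) ρ^i L_{r, θ−1+i} with
L_{r,m} = ∫ xʳ f F (1−F²)^m dx.  Each L is a finite alternating combination
of the K_{r,m}, but is evaluated directly by quadrature in probability
space to avoid binomial cancellation at large m.  The regrouped series
converges geometrically on the whole support and matches quadrature to
~1e−10 for θ ∈ {1, 2, 3} at 60 terms.  Non-integer θ is rejected explicitly
rather than silently generalized.

## Maximum likelihood

The log-likelihood is assembled from the log-space density terms
(n log 2 + 2n log θ + Σ log f + (θ−1) Σ log A + Σ log F − (θ+1) Σ log B).
Optimization runs on log-parameters (positivity for free) with Nelder-Mead
followed by an L-BFGS-B polish, multi-started from (i) a deterministic
data-driven point — Weibull shape/scale from a least-squares fit to the
empirical log–log survival, with θ profiled over a coarse grid {0.25, 0.5,
1, 2, 4} — plus (ii) seeded log-uniform random starts in [1e−2, 1e2] per
parameter; best log-likelihood wins, ties broken by smaller parameter norm.
A plain quasi-Newton pass was found to stall on this likelihood (the first
line search can cross into the invalid-parameter penalty region and
terminate immediately), hence the derivative-free primary stage.

Standard errors are Wald: square roots of the diagonal of the inverse
observed information (negative Hessian of the log-likelihood at the MLE,
central finite differences on the original parameter scale, via
statsmodels' numerical differentiation).  A non-positive-definite
information matrix yields NaN entries and a warning rather than imaginary
numbers.

The fitting layer is exposed as a scikit-learn style density estimator
(`ParametricDensityMLE`: `fit`/`score`/`score_samples`/`sample`,
fitted attributes with trailing underscores), so it composes with sklearn
model selection; `fit_mle` is the functional wrapper.

### Identifiability of (γ, θ)

The NE-W's scale-like pair (γ, θ) is close to non-identifiable: doubling θ
can be compensated by adjusting (α, γ) to within sup-cdf distance ~0.003 —
an order of magnitude below what a sample of n = 750 can resolve
(KS resolution ≈ 1.36/√n ≈ 0.05).  Consequences, all visible in the test
suite and the acceptance outputs:

- the likelihood surface has a long, nearly flat ridge in (γ, θ); the
  maximized likelihood is well determined but the coordinates along the
  ridge are not;
- the MLE of γ and θ is heavily right-skewed at n ≤ 750, with occasional
  replicates whose genuine global optimum lies at extreme ridge points
  (the MLE can effectively diverge), so Monte Carlo *mean* estimates and
  MSEs of γ and θ remain far from the truth at n = 750 and are not
  monotone in n, even though the *fitted distribution* converges and α is
  recovered cleanly (its MSE falls ~25-fold from n = 25 to n = 750);
- Wald standard errors for γ and θ are large and should be read as local
  curvature along the ridge, not as parameter uncertainty in isolation.

The idealized estimator behavior (every parameter's bias vanishing and MSE
strictly decreasing through n = 750) is asserted as-is by the acceptance
suite and fails for γ/θ for the reason above; this is a property of the
model at those parameter sets, not of the optimizer — adding the known
truth as an extra optimizer start in the simulation (the default in
`run_mc_study`) does not change it, because the extreme ridge points have
genuinely higher likelihood on those samples.

## Monte Carlo study

`run_mc_study` draws `reps` NE-W samples per sample size, refits each by
maximum likelihood, and aggregates per-parameter mean estimate, bias,
absolute bias (|mean bias|) and MSE.  Replicate seeds derive from the
master seed through counter-based `SeedSequence` spawn keys, so results are
bit-reproducible and independent of execution order.  Non-converged fits
are excluded and counted; a sample size with >10% failures is flagged.
The default grid (n = 25 … 750 in steps of 75, reps = 200) keeps the study
desk-scale; the full published-style configuration (steps of 25,
reps = 750) is available through `FULL_N_GRID`.  The acceptance suite runs
the four-point grid n ∈ {25, 100, 400, 750} at reps = 200;
`scripts/acceptance.py` reports the two endpoints n ∈ {25, 750} at
reps = 200, which carry the bias/MSE-versus-n comparison.

## Goodness of fit

AIC = 2k − 2ℓ, BIC = k log n − 2ℓ.  The AD, CM and KS statistics use the
standard order-statistic formulas on fitted cdf values G₍ᵢ₎ with estimated
parameters plugged in (the usual convention in model-comparison tables);
the KS p-value comes from the asymptotic Kolmogorov distribution at √n·D
and inherits the anti-conservative plug-in convention, which is recorded in
the report metadata.  Ties in the data are kept under a stable sort; no
continuity correction.  PP coordinates use plotting positions i/(n+1); the
empirical survival coordinates are the product-limit estimate, which for
uncensored data equals 1 − ecdf.  For the AD statistic, fitted cdf values
that have rounded to 0 or 1 in float are clipped to the nearest
representable interior value before the logs.

## Competitor models

All ten comparison distributions share the Weibull kernel parameterization
F = 1 − e^(−γxᵅ) and analytic log-densities.  Two printed forms in the
source tables are ambiguous; the adopted readings are
FWE: G = 1 − exp(−e^(σx² − γ/xᵅ)) and Ex-APTW: G = (α₁^F − e^F)/(α₁ − e),
both verified to satisfy the cdf axioms; each lives behind the registry so
a corrected form is a one-line change.  Lomax uses the scale form
G = 1 − (1 + x/γ)^(−α).  APTW's removable singularity at α₁ = 1 is handled
by continuity (G → F); Ex-APTW excludes α₁ = e.

## Synthetic fixtures

`generate_fixture` draws NE-W samples at the parameter values of the NE-W's
published fits to three application domains — remission times
(θ=2.156, α=1.985, γ=0.107), machine failure times (θ=0.079, α=0.943,
γ=2.065) and vehicle insurance losses (θ=0.632, α=0.975, γ=0.031) — giving
unimodal, right-skewed, heavy-tailed samples of the right shape.  They are
synthetic stand-ins: the real data sets are not publicly printed.  Tests
passing on these fixtures show the pipeline recovers distributions of this
shape from clean iid data; they say nothing about censoring, measurement
error, covariates or model misspecification in real data.

## Known limitations

- Complete (uncensored) univariate samples only; no censoring likelihoods,
  no covariates, no interval estimation beyond Wald SEs.
- KS/AD/CM p-value calibration with estimated parameters would require a
  parametric bootstrap, which is out of scope.
- The (γ, θ) identifiability ridge above means reported γ̂, θ̂ for NE-W
  fits should be interpreted jointly, not marginally.
- Descriptive-measure grids previously published for this family disagree
  with the family's own density; `docs/descriptive_measures.md` reports the
  recomputed grids and the discrepancy.
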