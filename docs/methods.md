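# Methods

## The transform and the family

The scalar transform `T_λ(x) = sin((π/2)x) − λ(π/2)x·cos((π/2)x)` on [0,1]
(0 below, 1 above) is a continuous, strictly increasing cdf for every
λ ∈ [0,1]: its derivative (π/2)[(1−λ)cos((π/2)x) + λ(π/2)x·sin((π/2)x)] is a
sum of nonnegative terms, and `sin y ≥ y·cos y` on [0,π/2] sandwiches it
between `T_1` and `sin((π/2)x)`.  Its second derivative
(π²/4)[(2λ−1)sin((π/2)x) + λ(π/2)x·cos((π/2)x)] is ≤ 0 for λ ≤ 1/3 and ≥ 0
for λ ≥ 1/2; in the open gap the sign can change (e.g. at λ = 2/5 it is
+0.07592538 at x = 0.1 and −0.08606892 at x = 0.8), which is what lets the
transform "convexify or not" the sine cdf.  `classify_shape` short-circuits
the two proven intervals analytically and otherwise inspects the second
derivative on an interior grid (default 512 points) with a 1e−10 deadband —
the gap interval admits no clean analytic classification, so numerical
inspection is the honest tool there.  The star form
`T*_λ(u) = u − λ·arcsin(u)√(1−u²)` satisfies `T*_λ(sin((π/2)x)) = T_λ(x)`;
its cdf property is verified numerically (monotonicity on a grid) rather
than proven.

A TS-G distribution composes the transform with a baseline cdf:
`F = T_λ∘G`.  Useful identities implemented and tested: the two-component
mixture `F(·;λ) = (1−λ)F(·;0) + λF(·;1)`; first-order stochastic dominance
in λ (larger λ pushes the cdf down); monotone likelihood ratio between two
members sharing a baseline; tail equivalents `F ~ (π/2)(1−λ)G` as G→0 and
`1−F ~ (π²/4)λ(1−G)` as G→1; the expansion
`F = Σ_k a_k G^{2k+1}` with `a_k = (π/2)^{2k+1}(−1)^k[1−λ(2k+1)]/(2k+1)!`;
and the baseline-free stress–strength reliability
`R = 1/2 + (λ₁−λ₂)(π²−4)/16`.

## Numerical choices

* **Transform inverse** (quantiles, sampling): bracketed bisection on [0,1],
  default tolerance 1e−12 (~40 halvings).  Bisection rather than
  Newton/Brent because it is branch-free, vectorises over whole probability
  arrays, and is immune to the near-flat regions of `T_λ` at the endpoints
  for extreme λ.  Quantiles compose `Q = Q_G∘T_λ⁻¹`; sampling is inverse
  transform with an explicit seed or Generator (no global state).
* **Survival precision.**  The family cdf evaluated as `1 − F` cancels
  catastrophically when G ≈ 1.  With e = 1−G,
  `1 − F = 2sin²((π/4)e) + λ(π/2)G·sin((π/2)e)`; baselines may supply a
  tail-accurate survival function (the Weibull and exponential registries
  do), keeping hazard rates meaningful deep in the right tail.  The TSW
  closed forms use the same device via the second algebraic form in
  `E = e^{−αx^β}`.  Where the survival function still underflows to zero the
  hazard returns +inf with a warning, never a silent clip.
* **Critical points** of the pdf and hazard: the stationarity equations are
  transcendental, so roots of d log f/dx (central differences, step 1e−6 of
  the bracket width) are located by a uniform sign-change scan (default 2048
  points) refined by Brent's method, then classified by the sign of the
  second log-derivative (max / min / inflection with a 1e−8 deadband).  An
  empty list means a monotone function on the bracket, not a failure.
* **Moments.**  `Θ_φ = E[φ(X)]` by two routes.  Quadrature: the
  substitution u = G(x) gives
  `Θ = λ(π²/4)∫₀¹φ(Q_G(u))·u·sin((π/2)u)du + (1−λ)(π/2)∫₀¹φ(Q_G(u))cos((π/2)u)du`,
  adaptive with absolute tolerance 1e−10 on the unit interval (no infinite
  limits).  Series: `Θ = Σ_k a_k·E_{γ=2k+1}[φ]` with the exponentiated
  -baseline expectations again computed on the u-scale, default truncation
  K = 40; coefficients decay factorially, and the first omitted coefficient
  enters the reported error bound.  Divergent requests (e.g. the m-th
  inverse moment when the density carries too much mass at 0) raise a
  convergence error instead of returning a number.  The incomplete-moment
  integrand's jump at u = G(t) is passed to the integrator as a split point.
* **Rate-like Weibull parameterisation**: α multiplies x^β, so the
  conventional scale parameter is α^(−1/β).  All printed estimates follow
  this convention.

## Maximum likelihood

The log-likelihood, score (analytic in all three parameters; the (α,β)
components chain through ∂G/∂ζ), and multi-start bounded quasi-Newton
optimisation on (λ, log α, log β) with λ ∈ [0,1]: five λ-grid starts
anchored at a plain Weibull fit of the data plus seeded jittered starts
(default 8 total).  A vanishing density at any observation yields −inf (not
an exception) so the optimiser can retreat.  Convergence is certified by the
optimiser's success flag or a KKT projected-gradient norm below 1e−5 —
L-BFGS-B sporadically aborts its line search at machine-precision optima,
and at an active λ-bound the raw gradient component is allowed to point out
of the box.  Ties across starts break first on likelihood, then on the
smaller projected gradient.

Standard errors are square roots of the diagonal of the inverse observed
information `J = −∇²ℓ` at the MLE, computed by central differences on the
working scale (relative step 1e−4; step-halving changes the result by less
than 1e−4 relative) and mapped back by the delta method (the score is ~0 at
an interior optimum).  A non-positive-definite J is flagged, not silently
inverted; a λ̂ on the boundary sets a `boundary` flag since Wald asymptotics
fail there, and Wald intervals for λ are truncated to [0,1].

## Goodness of fit

With u_(i) the fitted cdf at the i-th order statistic: KS uses both
one-sided envelopes and the asymptotic Kolmogorov p-value at √n·D (exact
finite-n available by flag).  CVM and AD default to the
Chen–Balakrishnan form used throughout the distribution-fitting literature:
u_(i) ↦ Φ⁻¹, standardised (ddof = 1), mapped back through Φ, then
`W* = W²(1+0.5/n)` and `A* = A²(1+0.75/n+2.25/n²)`; the plain
order-statistic forms are available with `modified=False`.  AIC is
2k − 2ℓ̂ with k the number of fitted parameters.  Statistics are computed on
the same data used for estimation (no Lilliefors-type correction), matching
standard practice for these model comparisons.

## Simulation study and synthetic data

`run_mse_study` draws `reps` samples of each size n from a TSW truth,
refits, and tabulates the empirical MSE per parameter.  The study truths are
S1 = (λ=0.3, α=3, β=5) and S2 = (λ=0.1, α=3.5, β=4.5) with the default grid
n ∈ {10, 20, 30, 40, 50}; `reps` defaults to 200 (a desk-scale N preserving
the qualitative MSE-versus-n shape; the full-scale study uses 3000).
Replicate seeds derive from the master seed by a counter-based spawn key, so
results are bit-reproducible and parallelisable.  Refits start the optimiser
at the generating truth (`start_at_truth=True`), the usual protocol for
recovery studies: under an exhaustive multi-start search, samples of size
10–20 frequently admit degenerate global likelihood maxima with runaway
(α,β) whose squared errors dominate the MSE and destroy the curves'
monotone decay.  Non-converged refits are dropped and counted; more than
20% failures at any n flags the result.  `make_synthetic` returns a sample
plus a provenance record (model, parameters, n, seed) that regenerates it
exactly.

What the generator emulates — and does not.  Samples are complete,
i.i.d., and exactly TSW-distributed; real lifetime data bring censoring,
rounding/ties, covariates and model misspecification, none of which the
generator produces.  Passing recovery tests therefore demonstrates the
correctness of the sampler–likelihood–optimiser loop, not robustness of the
model on field data.

## Known limitations

* Complete samples only; no censored likelihoods.
* Identifiability of (λ, α, β) is checked only empirically (the λ-score is
  nearly collinear with the (α,β) scores in small samples, which is why λ̂
  has a large standard error at n below ~50).
* Moment series route evaluates exponentiated-baseline expectations by
  quadrature per term; closed-form exponentiated-Weibull moment formulas
  are not used.
* The [0,1] box on λ means boundary estimates occur in small samples; their
  reported standard errors carry a flag rather than a boundary-corrected
  distribution.
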