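# Methods

## Model and identification

The target parameter is the marginal causal risk ratio of infection under
vaccination, `RR = E[Y(1)]/E[Y(0)] = exp(β₀)`, with `VE = 1 − exp(β₀)`.
Identification from a test-negative (S = 1) sample rests on:

1. consistency, latent exchangeability given `(U, X)`, and positivity;
2. **treatment-independent sampling**: `S ⫫ A | Y, U, X` — vaccination
   influences testing only through infection and the (possibly latent)
   characteristics that drive care seeking;
3. **no effect modification by the latent confounder**:
   `P(Y=1 | A=a, U, X) = exp(β₀ a) g(U, X)` (relaxable to
   `β₀(X) = d(X)ᵀb` for measured modifiers);
4. **NCE validity**: `Z ⫫ (Y, S) | A, U, X`;
5. **bridge existence**: some `q(A, Z, X)` satisfies
   `E[q(a, Z, X) | A=a, U, X] = 1/P(A=a | U, X)` — a Fredholm integral
   equation of the first kind whose solvability requires the NCE to carry
   enough information about `U` (for binary `Z` it is non-singularity of
   the 2×2 cell-probability matrix; for the Gaussian family it is a
   nonzero `Z`–`U` loading);
6. **NCO validity** and a **rare infection** condition
   (`P(Y=1 | A, W, U, X) ≤ δ` with small δ), under which the bridge is
   recoverable from test-negative controls: the control-based moment
   equations identify a `q*` within `O(δ)` of the true bridge.  Under the
   null of no vaccine effect, `q*` equals the true bridge exactly, so the
   null is preserved even for common outcomes.

Under treatment-induced selection the identical computation estimates a
causal odds ratio under modified negative-control conditions; results
carry a `scale_note` field distinguishing the two readings, and no
separate algorithm exists because none is needed.

## Estimation pipeline

1. **Bridge fit** (`estimate_bridge_params`): solve the control-restricted
   moment equations in τ.  Just-identified systems (`dim(m) = dim(τ)`) use
   damped Newton iteration: central-difference Jacobian with step
   `1e−6·(1+|τⱼ|)`, halving line search on the residual max-norm,
   tolerance `1e−10`, at most 200 iterations, and — on failure — restarts
   from eight fixed quasi-random perturbations.  Over-identified systems
   minimise the unweighted residual norm (identity-weighted GMM); optimal
   GMM weighting is deliberately not used so that the variance formula
   below applies verbatim in its projection form.  Starting values:
   `τ = (1, 0, 0, 0)` (bridge ≡ 1) for the saturated family; for the
   logistic family, an *observed-propensity start* obtained by logistic
   regression of `A` on `(Z, X)` among controls — the bridge that would be
   exact if `Z` itself were the confounder — falling back to `τ = 0`
   (bridge ≡ 2).  Fitted bridge values below 1 cannot be inverse
   probabilities; they are reported as a validity warning on the
   convergence report (fraction and minimum), never truncated silently.
2. **Point estimate** (`estimate_log_rr`): the closed-form weighted case
   ratio.  It is exactly invariant to positive rescaling of `q̂` and is
   undefined (a reported error, not ±∞) when either arm has no cases.
3. **Inference** (`stacked_moments`, `sandwich_covariance`): per-subject
   stacked estimating functions — the VE component
   `(−1)^{1−A} q(·; τ) Y exp(−βA)` over the bridge components — with the
   Jacobian of their mean taken by central differences at `(β̂, τ̂)`, and
   the sandwich `(ΩᵀΩ)⁻¹ Ωᵀ Var̂(G) Ω (ΩᵀΩ)⁻¹ / n` (symmetrised; rank
   deficiency raises an error naming the unidentified direction).  The VE
   interval transforms the β-interval endpoints through `1 − exp(·)`
   with the order swap that the decreasing transform requires — not a
   delta method on the VE scale.
4. **Effect modification** (`estimate_log_rr_modified`): the estimating
   function is multiplied by the basis `d(X)` (default `(1, Xᵀ)ᵀ`), the
   minimal construction yielding `dim(d)` equations; Newton with the
   analytic Jacobian (only vaccinated cases depend on `b`), and the same
   stacked sandwich with the β-block widened.

Default moment bases: `(1, W, A, WA)` for a binary NCO (just-identified
with the saturated bridge), `(1, W, A, X)` for a scalar continuous NCO
with covariates, and `(1, W…, A, W·A…, X…)` for vector `W` — a documented
convention; any user-supplied `m` with `dim(m) ≥ dim(τ)` is accepted.

## Synthetic data: what it emulates and what it does not

Two generators mirror the causal graph (confounder `U` → treatment,
NCE, NCO, illness, infection; selection triggered by infection or other
illness; treatment-independent sampling holds by construction).

**Binary world.**  `U, Z, W, D` binary; log-linear risk
`Y | A, U ~ Bern(exp(η₀ᵧ + β₀A + ηᵤᵧU))`; selection only possible when at
least one of `Y, W, D` is 1 (probability 0.5 for cases, 0.012 for
test-negative symptomatics).  Calibration: `P(A=1|U) = (0.15, 0.85)`,
`P(U=1) = 0.5`, and the confounder risk effect `exp(ηᵤᵧ) ≈ 1.58` chosen in
closed form so the unvaccinated prevalence is exactly 0.75 % and the
marginal confounding ratio `E[g|A=1]/E[g|A=0]` equals 48/35 — giving a
vaccinated-arm prevalence of 0.72 % at RR = 0.7 and a maximal stratum risk
near 1 %, comfortably inside the rare-infection regime the estimator
assumes.  The NCE is a strong proxy of `U` (`P(Z=1|U) = 0.05/0.95`);
weaker proxies leave the bridge defined but push its values negative and
its estimate unstable under strong confounding.  Default populations of
one million yield TND samples of roughly 8–10 thousand.

**Continuous world.**  `U, X ~ N(0,1)`; logistic treatment
(`μ₀ₐ, μᵤₐ, μₓₐ = 0, 1, 0.3`); Gaussian NCE
(`Z = 0.3A + 1.5U + 0.2X + ε`); Gaussian NCO; log-linear risk with a
`U·X` interaction in the nuisance `g`.  The intercept and `U`-loading of
the risk model are calibrated by Gauss–Hermite quadrature to an
unvaccinated prevalence of 0.34 % and confounding ratio ≈ 1.30; the
probability of a subject with model risk above 1 is ~3e−22, and any
realised violation aborts the draw.  The analytic bridge for this family
has `τ₂ = μᵤₐ/μᵤ𝓏`, `τ₃ = μₓₐ − μₓ𝓏 μᵤₐ/μᵤ𝓏`, and intercepts derived via
the normal moment generating function:
`τ₀ = μ₀ₐ − μᵤₐμ₀𝓏/μᵤ𝓏 − σ𝓏²μᵤₐ²/(2μᵤ𝓏²)`,
`τ₁ = σ𝓏²μᵤₐ²/μᵤ𝓏² − μᵤₐμₐ𝓏/μᵤ𝓏`; it satisfies the defining integral
identity to quadrature precision (test-asserted at 1e−8, observed ~1e−15).

A non-rare preset raises the binary baseline risk to a 10 % unvaccinated
prevalence while keeping the confounding structure; it exhibits the
predicted failure mode — the control-estimated bridge is biased away from
the null but remains exact at it.

Not emulated: interference/transmission dynamics, test misclassification,
time-varying vaccination or calendar effects, misspecified bridge
families, and vector-valued negative controls beyond the moment-basis
convention above.  Passing tests therefore demonstrate correctness of the
estimator under its stated assumptions, not robustness to their failure.

## Study-size choices

Monte Carlo checks run at populations of one million with 300 replicates
(rare-outcome experiments; three risk ratios 0.2, 0.5, 1.0) and 200
replicates for the non-rare variant — large enough that the binomial
coverage band around 95 % is ±2.4 % and bias checks resolve ~0.01 on the
log scale, while a full study completes in minutes on one CPU.  The
acceptance script reports interval coverage from the same design at
RR = 0.5.

## Numerical choices and degenerate inputs

* Condition-number threshold 1e8 for the 2×2 closed-form bridge; beyond
  it an identification error names the offending treatment level.
* Bridge exponents are clipped at ±500 inside evaluation so solver
  iterates stay finite; the clip is unreachable at any fitted optimum.
* Case rows are excluded from the bridge moment terms by construction
  (`(1 − Y)` factor), so duplicating or permuting cases cannot move τ̂.
* Samples with no controls, no cases in an arm, empty selection, or
  non-binary `A`/`Y` raise informative errors rather than returning
  infinities; replicate-level failures inside a study are counted and
  excluded from aggregates, never fatal.
* The Hausman statistic uses the classical scalar form
  `(β̂₁−β̂₂)²/(V₁−V₂)` with one degree of freedom and returns NaN with a
  warning when the variance difference is non-positive.

## Known limitations

* **Rare-disease bias floor.**  The control-estimated bridge inherits an
  `O(δ(1−RR))` bias — under the calibrated binary preset about −0.008 on
  the log scale at RR = 0.2, vanishing exactly at RR = 1.  This is a
  property of the identification strategy, not the implementation; the
  oracle-bridge estimator shows no such bias.
* **Moment-equation solvability in small samples.**  For the logistic
  bridge family the sample moment system occasionally has no root
  (heavy-tailed exponential moments); with ~6 000 controls this affects
  roughly 5–10 % of continuous-world replicates, reported as convergence
  failures.  Larger control pools eliminate it.
* The printed-precision calibration targets cannot all be matched
  simultaneously by any fixed log-linear generator (the vaccinated-arm
  prevalence must scale exactly as `exp(β₀)` times a constant across
  scenarios); the presets match the unvaccinated prevalence exactly and
  the RR = 0.7 vaccinated-arm figure, which keeps every stratum risk
  rare.
* No optimal-GMM weighting, nonparametric/sieve bridges, or
  doubly-robust outcome-bridge estimators.
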