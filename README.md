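# tndbridge

Double negative control estimation of vaccine effectiveness (VE) from
test-negative design (TND) studies.

## The problem

The test-negative design recruits only symptomatic, care-seeking, tested
individuals: test-positives are cases, test-negatives controls.  It is the
workhorse of real-world VE estimation (influenza, rotavirus, COVID-19),
but it is vulnerable to two entangled biases that covariate adjustment
cannot fix:

* **residual confounding** by unmeasured factors `U` such as health-care
  seeking behaviour, occupation, or prior infection, which affect both
  vaccination `A` and infection `Y`; and
* **collider stratification bias** from conditioning on selection `S`
  (testing), a common consequence of infection and of `U`.

`tndbridge` implements a proximal causal inference solution that uses a
pair of negative control variables measured on the same subjects:

* a **negative control exposure** (NCE) `Z` — e.g. prior-season or
  unrelated vaccination — with no causal effect on `Y` or `S`, associated
  with them only through `U`;
* a **negative control outcome** (NCO) `W` — e.g. unrelated acute-care
  visits — not caused by `A` or `Z`, associated with them only through
  `U`.

## The method

Under a multiplicative risk model `P(Y=1 | A=a, U, X) = exp(β₀ a) g(U, X)`
with no effect modification by `U`, the marginal causal risk ratio is
`exp(β₀)` and `VE = 1 − exp(β₀)`.  The key device is a **treatment
confounding bridge function** `q(A, Z, X)` satisfying

    E[ q(a, Z, X) | A = a, U, X ] = 1 / P(A = a | U, X),

an inverse treatment probability expressed through observables.  For a
rare infection, `q` can be estimated from test-negative controls alone by
solving the moment equations

    (1/n) Σᵢ (1 − Yᵢ) [ m(Wᵢ, Aᵢ, Xᵢ) q(Aᵢ, Zᵢ, Xᵢ; τ)
                        − m(Wᵢ, 1, Xᵢ) − m(Wᵢ, 0, Xᵢ) ] = 0,

where `m` is any user-chosen vector function with `dim(m) ≥ dim(τ)`.
Plugging `q̂ = q(·; τ̂)` into the inverse-weighting estimating equation
gives the closed form

    β̂ = log [ Σᵢ q̂ᵢ Aᵢ Yᵢ / Σᵢ q̂ᵢ (1 − Aᵢ) Yᵢ ],    VÊ = 1 − exp(β̂),

with joint `(β̂, τ̂)` inference from the stacked M-estimation sandwich
`Σ̂ₙ = (Ω̂ᵀΩ̂)⁻¹ Ω̂ᵀ Var̂(Gᵢ) Ω̂ (Ω̂ᵀΩ̂)⁻¹ / n` and a Wald interval for VE
obtained by transforming the β-interval endpoints.  Two bridge families
are built in: a saturated model `τ₀ + τ₁Z + τ₂A + τ₃ZA` for binary `Z`,
and `1 + exp[(−1)^A (τ₀ + τ₁A + τ₂Z + τ₃ᵀX)]` for Gaussian `Z` with
logistic treatment.  Extensions cover effect modification by measured
covariates (`β₀(x) = d(x)ᵀb`), negative-control bias-detection
regressions, and a Hausman comparison against conventional logistic
regression.

## Worked example

```sh
python examples/estimate_ve.py
```

simulates one million people with true VE = 50 % (`β₀ = −0.693`), selects
the tested subsample and prints:

```
TND sample: n=9223 (3140 test-positive cases, 6083 test-negative controls)
log RR estimate: -0.750 (SE 0.068); truth -0.693
VE = 52.7%  (95% CI 46.0% to 58.6%)
Bridge parameters (saturated model): [0.928, 5.922, 4.979, -10.829]
Logistic log OR: -1.071 -> VE 65.7% (confounded: compare with the negative control estimate above)
```

The negative control estimate recovers the truth within its interval,
while the conventional logistic analysis overstates VE by ~15 percentage
points because it ignores the unmeasured confounder.  Other examples
cover the closed-form bridge (`bridge_closed_form.py`), bias/coverage
Monte Carlo studies (`simulation_study.py`), bias detection and the
Hausman test (`diagnostics.py`), and covariate-varying VE
(`effect_modification.py`).

A thin CLI wraps the same pipeline:

```sh
tndbridge simulate --preset binary-rare --seed 5 --out tnd.csv
tndbridge estimate --input tnd.csv --bridge saturated --out result.json
tndbridge diagnose --input tnd.csv
tndbridge study --setting binary --replicates 50 --seed 1
```

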