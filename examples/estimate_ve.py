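"""Estimate vaccine effectiveness from a test-negative sample.

Simulates a target population of one million people with an unmeasured
confounder, selects the tested subsample (the TND study), and runs the
double negative control pipeline: bridge fit on test-negative controls,
closed-form log risk ratio, sandwich Wald interval.
"""

import tndbridge as tb

config = tb.binary_rare(beta0=-0.693)  # true risk ratio 0.5, i.e. VE = 50%
population = tb.simulate_binary_population(config, seed=7)
sample = tb.select_tnd_sample(population)
print(f"TND sample: n={sample.n} ({sample.n_cases} test-positive cases, "
      f"{sample.n_controls} test-negative controls)")

result = tb.estimate_ve(sample, family="saturated-binary")
print(f"log RR estimate: {result.beta_hat:+.3f} (SE {result.se:.3f}); "
      f"truth {config.beta0:+.3f}")
print(f"VE = {100 * result.ve:.1f}%  "
      f"(95% CI {100 * result.ve_ci[0]:.1f}% to {100 * result.ve_ci[1]:.1f}%)")
print("Bridge parameters (saturated model):",
      [round(float(t), 3) for t in result.tau_hat])

# the conventional logistic analysis ignores the unmeasured confounder
logit = tb.logistic_or_estimate(sample, covariates=())
print(f"Logistic log OR: {logit.beta_hat:+.3f} -> VE {100 * logit.ve:.1f}% "
      "(confounded: compare with the negative control estimate above)")
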