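"""Detecting hidden bias with negative controls.

A valid NCE should show no adjusted association with the test result or
with the NCO; a significant association flags residual confounding.  The
Hausman test then compares the negative-control VE estimate against the
conventional logistic one: a significant difference indicates that the
no-unmeasured-confounding assumption behind the logistic analysis fails.
"""

import tndbridge as tb

pop = tb.simulate_binary_population(tb.binary_rare(), seed=19)
sample = tb.select_tnd_sample(pop)

print("negative-control bias detection (small p => hidden bias):")
print(tb.nce_bias_tests(sample).to_string(index=False))

nc = tb.estimate_ve(sample)
logit = tb.logistic_or_estimate(sample, covariates=())
out = tb.hausman_test(nc, logit)
print(f"\nNC log RR {nc.beta_hat:+.3f} (SE {nc.se:.3f}) vs "
      f"logistic log OR {logit.beta_hat:+.3f} (SE {logit.se:.3f})")
print(f"Hausman chi-square(1) = {out.statistic:.2f}, p = {out.p_value:.2e}")
print("A small p-value says the two estimators disagree beyond chance, "
      "i.e. the logistic analysis is biased by unmeasured confounding.")
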