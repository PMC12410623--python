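"""Minimum development sample size for a binary-outcome prediction model.

Evaluates the three standard criteria for 12 candidate parameters, an
anticipated Cox-Snell R-squared of 0.11 and an outcome prevalence of 55%,
targeting a shrinkage factor of at least 0.9.
"""

import endopredict as ep

spec = ep.SampleSizeSpec(p=12, R2_CS=0.11, phi=0.55, S_target=0.9)
res = ep.riley_min_n(spec)

print(f"criterion 1 (shrinkage >= {spec.S_target}):        n = {res.n_shrinkage}")
print(f"criterion 2 (R2 optimism <= {spec.delta_R2}):       n = {res.n_optimism}")
print(f"criterion 3 (prevalence margin {spec.margin_phi}): n = {res.n_intercept}")
print(f"minimum sample size: n = {res.n_min} (binding: {res.binding_criterion})")
print(f"implied events: {res.events_implied}")
# The binding criterion is almost always the shrinkage target: enough data
# that the fitted coefficients need shrinking by no more than 10%.
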