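"""Estimate the median paralytic dose (PD50) from a quantal bioassay.

Simulates blowfly injections (6 doses x 20 flies, logistic dose-response
with a true 1-minute PD50 of 3.07 ug/fly), fits a binomial GLM on log10
dose, and converts the estimate to a per-gram dose at a 25 mg fly mass.
"""

from asilidvenom import DoseResponseObservation, SyntheticVenomSpec, fit_pd50, per_gram
from asilidvenom.synthetic import generate_dose_response

df = generate_dose_response(SyntheticVenomSpec(seed=7))
obs = [
    DoseResponseObservation(r.dose, r.n_injected, r.n_paralysed, r.timepoint)
    for r in df.itertuples()
    if r.timepoint == "1 min"
]
fit = fit_pd50(obs)
print(f"PD50 = {fit.pd50:.2f} ug/fly  (95% CI {fit.ci_low:.2f}-{fit.ci_high:.2f}, "
      f"slope {fit.slope:.2f})")
print(f"     = {per_gram(fit.pd50, 0.025):.1f} ug/g at 25 mg per fly")
# The estimate recovers the planted 3.07 ug/fly within sampling error; a
# ~400 ug venom harvest therefore holds >25 rapid-paralysis doses.
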