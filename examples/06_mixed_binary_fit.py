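"""FIML on mixed continuous/binary twin data with missing co-twins.

A continuous trait and a binary liability-threshold trait (prevalence
19.62%) share a genetic path; 8% of twins are missing at random.  The
binary trait's liability variance is identified at 1, so its paths are
directly on the liability scale.  Runtime is dominated by the rectangle
probabilities of the binary blocks (about half a minute).
"""

import numpy as np

from twinsem import FitOptions, GenerativeSpec, PhenotypeSpec, fit, heritability, simulate_cohort

phenotypes = (
    PhenotypeSpec("fatigue"),
    PhenotypeSpec("cwp", "binary", prevalence=0.1962),
)
a = np.array([[0.8, 0.0], [0.45, np.sqrt(0.72 - 0.45**2)]])
e = np.array([[0.6, 0.0], [0.15, np.sqrt(0.28 - 0.15**2)]])
spec = GenerativeSpec(150, 170, phenotypes, {"A": a, "E": e},
                      seed=11, missing_twin_prob=0.08)
data = simulate_cohort(spec)
n_missing = int(np.isnan(data.values()).all(axis=1).sum())
print(f"{data.n_pairs} pairs retained; incomplete pairs are kept and their "
      "observed twin still contributes")

model = spec.model_spec()
result = fit(model, data, FitOptions(n_starts=2))
print(f"converged: {result.converged}, -2lnL = {result.minus2LL:.1f}")
print(heritability(result, ci=False).round(1).to_string(index=False))
total = result.phenotypic_cov()
print(f"implied cwp liability variance: {total[1, 1]:.4f} (identified at 1)")
print(
    "\nGenerative heritabilities are 64% (fatigue) and 72% (cwp); at this\n"
    "modest cohort size the estimates carry sampling error of ~10 points."
)
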