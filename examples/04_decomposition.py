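"""Variance decomposition of a fitted trivariate AE Cholesky model.

Reports heritabilities, the factor-by-trait percentage table, genetic and
non-shared-environmental correlation matrices, and the attribution of the
third trait's genetic variance to factors originating at earlier traits.
"""

import numpy as np

from twinsem import (
    FitOptions,
    GenerativeSpec,
    PhenotypeSpec,
    fit,
    decompose,
    simulate_cohort,
)

phenotypes = tuple(PhenotypeSpec(n) for n in ("dheas", "fatigue", "pain"))
a = np.array([[0.85, 0.0, 0.0], [0.0, 0.62, 0.0], [-0.2, 0.5, 0.55]])
e = np.array([[0.53, 0.0, 0.0], [0.1, 0.77, 0.0], [0.0, 0.0, 0.62]])
spec = GenerativeSpec(2000, 2200, phenotypes, {"A": a, "E": e}, seed=11)
data = simulate_cohort(spec)

result = fit(spec.model_spec(), data, FitOptions(n_starts=2))
report = decompose(result, shared_target="pain")

print("heritability (%):")
print(report.heritability.round(2).to_string(index=False))
print("\nfactor x trait variance percentages:")
print(report.variance_percent.round(1).to_string(index=False))
print("\ngenetic correlations (rG):")
print(report.rg.round(3))
print("\nnon-shared environmental correlations (rE):")
print(report.re.round(3))
print("\ngenetic variance of 'pain' attributed to Cholesky sources:")
print(report.shared_genetic.round(1).to_string(index=False))
print(
    "\nAt this cohort size the estimates sit close to the generative values\n"
    "(pain h2 = 61%, rG(pain, fatigue) = 0.65); the source attribution is\n"
    "order-dependent, which is why the declared ordering is printed."
)
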