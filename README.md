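# twinsem

Multivariate variance decomposition for the classical twin design, built
around the question that motivated it: to what extent do chronic
widespread musculoskeletal pain (CWP) and its clinical companions —
chronic fatigue, depression and serum DHEAS — co-occur because they share
genes rather than environments?  Answering it requires fitting structural
models to MZ/DZ twin-pair data in which two phenotypes are continuous and
two are dichotomous disease states, co-twins can be missing, and the
competing hypotheses (distinct correlated genetic factors vs one shared
pathway) are formal nested models.

`twinsem` is a library for biostatisticians and genetic epidemiologists
doing exactly this kind of analysis:

- **Models** (`twinsem.models`): Cholesky, independent-pathway,
  common-pathway and saturated structures over A/C/D/E latent components
  (additive genetic, shared environmental, dominance, non-shared
  environmental), with liability thresholds for binary traits, in-model
  linear age adjustment, and drop-list grammar (`"A[4,1]"`) for reduced
  submodels.  Expected pair moments use the biometrical sharing
  coefficients: cross-twin blocks are Sigma_A + Sigma_C + Sigma_D for MZ
  and 0.5 Sigma_A + Sigma_C + 0.25 Sigma_D for DZ pairs.
- **Estimation** (`twinsem.fiml`): full-information maximum likelihood on
  mixed continuous/binary observations with arbitrary missingness;
  binary blocks are rectangle probabilities of the conditional latent
  normal, evaluated by deterministic quasi-Monte-Carlo; multi-start
  quasi-Newton optimization, Wald and profile CIs.
- **Descriptives** (`twinsem.correlations`, `twinsem.pipeline`):
  Pearson / tetrachoric / biserial correlations chosen by scale,
  double-entered cross-twin cross-trait (CTCT) matrices with bootstrap
  CIs, cohort descriptives with MZ-vs-DZ tests.
- **Inference** (`twinsem.selection`, `twinsem.decompose`): LRT/AIC
  model-comparison ladder (saturated -> ACE/ADE -> AE -> IP/CP ->
  reduced), heritabilities, factor-by-trait variance percentages, genetic
  and environmental correlation matrices (rG, rE), shared-genetic-variance
  attribution.
- **Simulation** (`twinsem.simulate`): a generator that draws cohorts
  with exactly the assumed statistical structure (study defaults: 219 MZ
  + 244 DZ pairs, CWP prevalence 19.62%, depression 30.06%), so every
  stage is testable without access to any registry data.
- **Replication drivers** (`twinsem.recovery`): bias/coverage recovery
  experiments and LRT null-calibration over many simulated replicates.

## Worked example

Fit an AE Cholesky model to a simulated bivariate cohort at the study's
size and decompose the covariance (`examples/04_decomposition.py` is the
three-trait version of this):

```python
import numpy as np
from twinsem import (FitOptions, GenerativeSpec, PhenotypeSpec,
                     fit, heritability, genetic_correlations, simulate_cohort)

phenos = (PhenotypeSpec("pain"), PhenotypeSpec("fatigue"))
a = np.array([[0.8, 0.0], [0.5, 0.6]])   # genetic paths
e = np.array([[0.6, 0.0], [0.1, 0.55]])  # non-shared environmental paths
spec = GenerativeSpec(219, 244, phenos, {"A": a, "E": e}, seed=2)
data = simulate_cohort(spec)

res = fit(spec.model_spec(), data, FitOptions(n_starts=2, compute_ci=True))
print(heritability(res).round(1))
print(genetic_correlations(res).round(3))
```

which prints (seed 2):

```
     trait  h2_pct  ci_low  ci_high
0     pain    61.2    53.8     68.2
1  fatigue    70.7    64.9     76.0
          pain  fatigue
pain     1.000    0.634
fatigue  0.634    1.000
```

The generative heritabilities are 64% for pain (genetic variance 0.8^2 =
0.64 of total 1.0) and 66% for fatigue (0.5^2 + 0.6^2 = 0.61 of total
0.9225), and the generative genetic correlation is
rG = (0.8 x 0.5) / (0.8 sqrt(0.61)) = 0.64.  The fitted values land on
the truth within sampling error at 463 pairs, with 95% Wald intervals.

The model-comparison ladder (`examples/03_model_ladder.py`) then asks
whether the covariation is genetic at all: on the same cohort neither
full Cholesky model is rejected against the saturated reference (p =
0.46 ACE, 0.27 ADE), dropping C is retained (p = 0.36), and the reduced
model without the genetic cross-path is rejected outright (delta -2lnL =
117.5 on 4 df, AIC worse by 112) — the simulated co-occurrence of the
traits is genetic, and the ladder says so.

Each script in `examples/` demonstrates one capability end to end:
cohort simulation and descriptives, correlation tables, the model
ladder, decomposition, recovery experiments, and mixed binary/continuous
fits with missing co-twins.  A thin CLI wraps the pipeline
(`twinsem simulate|describe|correlate|run|recover`); `twinsem run
config.yaml` executes every stage from a YAML config and writes
TSV tables plus a JSON manifest carrying the seed and config hash.

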