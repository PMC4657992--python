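# Methods

## The model family

`twinsem` analyses pair-per-row data from the classical twin design: p
phenotypes observed on both members of monozygotic (MZ) and dizygotic (DZ)
twin pairs.  The phenotypic covariance is decomposed into latent
components — additive genetic (A), shared environmental (C), dominance
genetic (D) and non-shared environmental (E) — using the biometrical
sharing coefficients: co-twins correlate 1 (MZ) / 0.5 (DZ) on A, 1 / 0.25
on D, 1 on C and 0 on E.  C and D are not jointly identifiable from
MZ/DZ data and the model specification refuses them together.  For a
component covariance set {Sigma_A, Sigma_C, Sigma_D, Sigma_E} the expected
2p x 2p pair covariance has within-twin blocks Sigma_A + Sigma_C +
Sigma_D + Sigma_E and cross-twin blocks alpha_A Sigma_A + alpha_C Sigma_C
+ alpha_D Sigma_D with the sharing coefficients above; consequently the
MZ-minus-DZ cross-twin block is exactly 0.5 Sigma_A + 0.75 Sigma_D, which
is both a property test on the algebra and a Monte-Carlo test on the
simulator.

Four structures map free parameters to component covariances:

- **Cholesky**: Sigma_X = P_X P_X' with P_X lower-triangular; entries can
  be fixed to zero through drop lists (`"A[4,1]"` grammar) to express
  reduced submodels.  Positive semidefiniteness holds by construction.
- **Independent pathway** (AE): per factor set, a genetic and a
  non-shared-environmental common loading vector over all traits, plus
  trait-specific A and E paths entering as squared diagonals.  One or two
  factor sets; two sets are left rotationally unconstrained (2p
  parameters each), which is what makes the two-set model sit 6
  structural parameters below the full 4-trait ADE Cholesky.
- **Common pathway** (AE): one or two unit-variance latent phenotypes,
  each split between A and E by a single share parameter (internally
  tanh-parameterized so the split stays in (0, 1)), with free loadings on
  the traits plus trait-specific A and E paths.
- **Saturated**: free mean/threshold per trait, twin position and
  zygosity and a free (Cholesky-parameterized) 2p x 2p covariance per
  zygosity — the reference model for the assumption that means and
  variances are equal across twin order and zygosity.

Binary traits follow the liability-threshold model: the observation is
the indicator of a latent standard-normal liability exceeding a threshold
tau, with the prevalence fixing the starting value of tau.  Age enters as
a fixed-effect linear term on means (continuous traits, observed units
per year) and thresholds (binary traits, liability SD per year), inside
the model rather than by pre-residualization so FIML remains correct
under missingness.  The age covariate is centered at the sample mean
before fitting; the centering constant is stored with the fit.

## Identification of binary traits

The liability scale is identified by fixing each binary trait's total
implied variance to 1.  Rather than a hard constraint, the likelihood
standardizes binary rows/columns of the implied covariance internally, so
it is *exactly* invariant to the scale of those rows; a quadratic gauge
penalty (weight 100) on (implied variance - 1)^2 then selects the
unit-variance representative.  Because the penalized direction is exactly
flat in the likelihood, the penalty is zero at the optimum and does not
distort the maximized -2lnL; it also restores a positive-definite Hessian
for Wald intervals.  Parameter counts for AIC subtract one df per such
constraint (`count_free_parameters(..., effective=True)`).

## Likelihood and its evaluation

Each pair contributes the likelihood of exactly its observed values
(full-information ML).  Missing entries drop rows/columns of the expected
moments; a pair with one twin absent contributes the observed twin's
marginal.  With mixed scales the contribution factorizes into the
multivariate-normal density of the observed continuous entries times the
probability of the rectangle of the conditional latent normal consistent
with the observed 0/1 pattern.

Rectangle probabilities are evaluated by the Genz separation-of-variables
transform averaged over a scrambled Sobol point set with a fixed seed
(`twinsem._mvn`), vectorized across all pairs sharing a missing-data
pattern.  With the seed fixed the likelihood is deterministic and smooth
in the parameters, so finite-difference quasi-Newton optimization is
well-behaved.  Default 2048 points during optimization (orthant error
around 1e-5); accuracy tests against brute-force numerical integration
use 2^16 points and agree to 1e-6.  Up to four binary dimensions arise
per pair (two binary traits times two twins).

Optimization is L-BFGS-B with five jittered starts by default
(convergence: gradient norm 1e-6, relative function change 1e-10).  The
sign of a Cholesky factor column (and of IP/CP loading vectors) is not
identified; instead of reparameterizing the diagonals we normalize signs
after convergence — columns are flipped so diagonals are non-negative —
which yields the same canonical form while avoiding the zero-gradient
point that squared or softplus diagonal reparameterizations create.
Replicate drivers start the fuller model additionally from the embedded
submodel solution plus one jittered start; the jitter matters because an
embedded start can sit exactly on a stationary ridge (a dominance path at
0 enters the likelihood quadratically).

Confidence intervals are Wald by default: parameter covariance
2 H^{-1} from a central-difference Hessian of -2lnL, delta-method
transformed for derived quantities — on the logit scale for
heritabilities and the Fisher-z scale for genetic correlations, which
keeps intervals inside their natural ranges and gives near-nominal
coverage (measured 95.5% and 96.5% over 200 study-scale replicates by the
acceptance suite).  Profile-likelihood intervals for single parameters
are available through `fiml.profile_ci`.

## Descriptive correlations

Estimator choice follows the scales: Pearson with Fisher-z CI
(continuous-continuous), maximum-likelihood tetrachoric with thresholds
fixed at the margins (binary-binary), and maximum-likelihood biserial
(continuous-binary), the latter consistent with the latent-normal model
used everywhere else rather than the classical moment formula.
Cross-twin cross-trait matrices are double-entered (both twin orderings
pooled), making them exactly symmetric; pairwise deletion handles missing
values since these are descriptive (the model fits use FIML).
Tetrachoric, biserial and CTCT intervals are seeded nonparametric
bootstraps over pairs (default 1000 resamples).  Boundary solutions
(|rho| >= 0.999) are flagged rather than silently clipped.

## Model comparison

`four_step_compare` runs: (1) full ACE and ADE Cholesky against the
saturated model (assumption check) with the full base chosen by AIC;
(2) AE Cholesky against the chosen base (dropping C or D); (3) AE
independent- and common-pathway variants against the base; (4)
user-declared reduced Cholesky submodels.  The selected model is the
lowest-AIC candidate not rejected at alpha = 0.05, ties broken toward
fewer parameters, independent of the order candidates are supplied.
Standard chi-square reference distributions are used throughout; for
variance components on their boundary (dropping D when d = 0) this is
conservative — p-values stochastically dominate uniform — which the
calibration tests measure explicitly rather than correcting by mixture
distributions.

Structural parameter counts (per component: p(p+1)/2 Cholesky; 2p per IP
factor set + 2p specifics; 1+p per CP latent + 2p specifics) reproduce
the published 4-trait df ladder: the AE Cholesky, one-set IP, one-latent
CP and two-set IP models sit 10, 14, 17 and 6 structural parameters below
the full ADE Cholesky.  Two notes on counting: a two-latent CP model
counts 18 structural parameters here (df gap 12, not the 10 printed in
the source tables, whose CP-2 parameterization is not stated), and the
saturated-vs-Cholesky df gap depends on bookkeeping of per-group
thresholds and age slopes that the source does not specify; this
implementation documents its own counts and does not force agreement.

## Decomposition

From a converged structured fit: heritability per trait is 100 x
Sigma_A_ii / Sigma_total_ii; the factor-by-trait table holds squared
standardized loadings x 100 (rows per trait sum to 100 across all factors
of all components); rG and rE are component correlation matrices, with
structural zeros printed as 0 by convention when a path has been dropped.
The attribution of a trait's genetic variance to "sources" follows the
Cholesky ordering: the share attributed to source trait j is the squared
standardized genetic cross-path from the factor originating at j,
normalized over all factors the target loads on (including its own
specific factor).  This attribution is one defensible reading of
shared-genetic-variance statements, is order-dependent, and the declared
ordering is therefore always printed with it.

## The synthetic cohort generator

Component factor scores are drawn per pair as equicorrelated normals with
the component's sharing coefficient and mixed through the same path
matrices the models use, so simulated moments equal
`models.expected_moments` by construction (tested at 50,000 pairs to
0.02 elementwise).  Binary traits require unit implied liability variance
at construction time and are thresholded at the inverse-normal of their
prevalence; age (shared within pair) enters as beta x (age - cohort mean
age) so the stated prevalence holds at the mean age; missing-at-random
dropout (whole twin, then per value) is applied last and never depends on
the values themselves.  Pairs with both twins entirely missing are
removed.

The default spec mirrors the motivating study's conditions: 219 MZ + 244
DZ female pairs; DHEAS (mean 3.10, SD 1.93 umol/L) and fatigue (1.55,
1.29) continuous; depression and chronic widespread pain binary at
prevalences 30.06% and 19.62%; age 58.39 (SD 11.08) years; an AE
structure assembled from the published heritabilities (74.24, 42.58,
49.9, 70.83%) and rG/rE matrices.  Those published correlation matrices
sit numerically on the boundary of positive definiteness, so the
generator shrinks off-diagonals by the smallest deterministic factor
(0.5% steps) that makes each component covariance proper, then rescales
to unit total variance.  Age slopes default to small values (-0.02
umol/L/yr for DHEAS, 0.01 for fatigue, 0.005 liability SD/yr for the
binary traits) — the source adjusts for age but does not print slopes.

What the generator does *not* emulate: assortative mating,
gene-environment correlation or interaction, sibling contrast effects,
non-normal measurement scales (the observed fatigue score is a 0-4 count
in reality; it is simulated as Gaussian), and informative missingness.
Passing recovery tests therefore show the estimators are correct under
the model's own assumptions, not that those assumptions hold in real
cohorts.

## Problem sizes and numerical choices

Replicate experiments use the study's 219+244 pairs for recovery (200
replicates) and 100+100 pairs for null-calibration (up to 1000
replicates); large-sample convergence checks use 50,000 pairs.  The
four-trait mixed-scale fit on a full simulated cohort takes minutes
(binary rectangle probabilities dominate); continuous-only fits take
tens of milliseconds.  Degenerate inputs are errors, not warnings: empty
pairs, zero margins in 2x2 tables, single-category binary variables,
zero implied phenotypic variance, C and D requested together.  A
submodel fitting better than its superset model beyond 1e-3 raises,
since it can only be an optimization failure.

## Known limitations

- Wald intervals can misbehave near variance boundaries (h^2 near 0 or
  1); profile intervals are the fallback.
- The two-set independent-pathway model is rotationally unidentified by
  design (only its fit, not its loadings, is interpretable).
- Tetrachoric/biserial bootstrap CIs resample assuming exchangeable
  pairs; no small-sample continuity corrections are applied.
- No sex-limitation, age-moderation, extended-pedigree or
  direction-of-causation models.
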