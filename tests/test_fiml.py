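"""FIML evaluation and optimization: closed-form oracles, invariances, recovery."""

import numpy as np
import pytest
from scipy import integrate, stats

from twinsem import (
    GenerativeSpec,
    ModelSpec,
    PhenotypeSpec,
    expected_moments,
    fit,
    pair_loglik,
    simulate_cohort,
    standardize,
    total_minus2LL,
)
from twinsem.fiml import FitOptions, saturated_gaussian_minus2ll
from twinsem.models import Parameterization


@pytest.fixture(scope="module")
def biv_data(biv_ae_spec):
    return simulate_cohort(biv_ae_spec)


def test_complete_data_fiml_equals_gaussian_likelihood(biv_ae_spec, biv_ae_model, biv_data):
    """With no missing values the FIML -2lnL is the plain 2p-variate
    normal likelihood, to 1e-8."""
    theta = biv_ae_spec.true_theta()
    m2ll = total_minus2LL(biv_ae_model, theta, biv_data)
    mom = expected_moments(biv_ae_model, theta)
    direct = 0.0
    for z in ("MZ", "DZ"):
        v = biv_data.values(z)
        direct += -2.0 * stats.multivariate_normal(
            mom[z].mean, mom[z].cov
        ).logpdf(v).sum()
    assert m2ll == pytest.approx(direct, abs=1e-8)


def test_saturated_evaluated_at_sample_moments_matches_closed_form(biv_data):
    model = ModelSpec("saturated", biv_data.phenotypes, include_age=False)
    par = Parameterization(model)
    theta = np.zeros(par.n_free)
    k = 0
    groups = {}
    for z in ("MZ", "DZ"):
        v = biv_data.values(z)
        groups[z] = v
        q = v.shape[1]
        theta[k : k + q] = v.mean(axis=0)
        k += q
        cov = np.cov(v, rowvar=False, bias=True)
        L = np.linalg.cholesky(cov)
        theta[k : k + q * (q + 1) // 2] = L[np.tril_indices(q)]
        k += q * (q + 1) // 2
    m2ll = total_minus2LL(model, theta, biv_data)
    assert m2ll == pytest.approx(saturated_gaussian_minus2ll(groups), abs=1e-8)


def test_missing_cotwin_reduces_to_marginal_density(biv_ae_spec, biv_ae_model):
    theta = biv_ae_spec.true_theta()
    mom = expected_moments(biv_ae_model, theta, "DZ")
    vals = np.array([0.3, -1.1, np.nan, np.nan])
    ll = pair_loglik(vals, mom)
    marginal = stats.multivariate_normal(mom.mean[:2], mom.cov[:2, :2]).logpdf(
        vals[:2]
    )
    assert ll == pytest.approx(marginal, abs=1e-10)


def test_binary_pair_orthant_probability_oracle():
    """Both twins affected under a standardized AE liability model: the
    log-likelihood is the upper-right orthant mass of a bivariate normal
    with rho = rMZ = 0.64 at tau = 0.856."""
    ph = (PhenotypeSpec("b", "binary", prevalence=1 - stats.norm.cdf(0.856)),)
    model = ModelSpec("cholesky", ph, ("A", "E"), include_age=False)
    theta = np.array([0.8, 0.6, 0.856])
    mom = expected_moments(model, theta, "MZ")
    ll = pair_loglik([1.0, 1.0], mom, qmc_points=2**16)
    cov = np.array([[1.0, 0.64], [0.64, 1.0]])
    dist = stats.multivariate_normal([0, 0], cov)
    ref, _ = integrate.dblquad(
        lambda y, x: dist.pdf([x, y]), 0.856, 9, lambda x: 0.856, lambda x: 9
    )
    assert np.exp(ll) == pytest.approx(ref, abs=1e-6)


def test_duplicating_pairs_doubles_minus2ll(biv_ae_spec, biv_ae_model, biv_data):
    import pandas as pd

    theta = biv_ae_spec.true_theta()
    doubled = biv_data.subset(np.ones(biv_data.n_pairs, dtype=bool))
    doubled.df = pd.concat([biv_data.df, biv_data.df], ignore_index=True)
    assert total_minus2LL(biv_ae_model, theta, doubled) == pytest.approx(
        2 * total_minus2LL(biv_ae_model, theta, biv_data), rel=1e-12
    )


def test_likelihood_invariant_to_twin_order(mixed2):
    e = np.array([[1.0, 0.0], [0.4, 0.0]])
    a = np.zeros((2, 2))
    # binary trait needs unit liability variance
    e[1, 1] = np.sqrt(1 - e[1, 0] ** 2)
    spec = GenerativeSpec(80, 90, mixed2, {"A": a + np.diag([0.0, 0.0]), "E": e},
                          seed=13, missing_twin_prob=0.1)
    spec.paths = {"E": e}
    data = simulate_cohort(spec)
    model = ModelSpec("cholesky", mixed2, ("A", "E"), include_age=False)
    par = Parameterization(model)
    rng = np.random.default_rng(0)
    theta = par.start() + 0.1 * rng.standard_normal(par.n_free)
    swapped = data.subset(np.ones(data.n_pairs, dtype=bool))
    cols = swapped.df.columns
    mapping = {}
    for ph in mixed2:
        mapping[f"{ph.name}_1"] = f"{ph.name}_2"
        mapping[f"{ph.name}_2"] = f"{ph.name}_1"
    mapping.update({"age_1": "age_2", "age_2": "age_1"})
    swapped.df = swapped.df.rename(columns=mapping)[cols]
    # exact for the continuous blocks; binary orthants are evaluated by QMC,
    # so the numerical agreement tightens with the point count
    a_val = total_minus2LL(model, theta, data, qmc_points=2**15)
    b_val = total_minus2LL(model, theta, swapped, qmc_points=2**15)
    assert a_val == pytest.approx(b_val, abs=2e-3)
    cont = ModelSpec("cholesky", (mixed2[0],), ("A", "E"), include_age=False)
    cont_data = data.subset(~np.isnan(data.df[["x_1", "x_2"]]).any(axis=1).to_numpy())
    cont_df = cont_data.df.drop(columns=["b_1", "b_2"])
    cont_swapped = cont_df.rename(columns={"x_1": "x_2", "x_2": "x_1",
                                           "age_1": "age_2", "age_2": "age_1"})
    from twinsem import TwinDataset
    t0 = np.array([0.7, 0.6, 0.1])
    a_c = total_minus2LL(cont, t0, TwinDataset(cont_df, (mixed2[0],)))
    b_c = total_minus2LL(cont, t0, TwinDataset(cont_swapped[cont_df.columns],
                                               (mixed2[0],)))
    assert a_c == pytest.approx(b_c, rel=1e-12)


def test_structured_model_never_beats_saturated(biv_data):
    ae = ModelSpec("cholesky", biv_data.phenotypes, ("A", "E"), include_age=False)
    res = fit(ae, biv_data, FitOptions(n_starts=2))
    groups = {z: biv_data.values(z) for z in ("MZ", "DZ")}
    assert res.minus2LL >= saturated_gaussian_minus2ll(groups) - 1e-6


class TestStandardize:
    def test_univariate_rescaling(self):
        ph = (PhenotypeSpec("x"),)
        model = ModelSpec("cholesky", ph, ("A", "E"), include_age=False)
        par = Parameterization(model)
        spec = GenerativeSpec(50, 50, ph, {"A": [[1.0]], "E": [[0.5]]}, seed=1)
        data = simulate_cohort(spec)
        res = fit(model, data, FitOptions(n_starts=1))
        # overwrite with exact paths to check the arithmetic, not the fit
        res.theta = np.array([1.6, 1.2, 0.0])
        std = standardize(res).standardized
        assert std["A"][0, 0] == pytest.approx(0.8)
        assert std["E"][0, 0] == pytest.approx(0.6)

    def test_squared_standardized_rows_sum_to_one(self, biv_data):
        model = ModelSpec("cholesky", biv_data.phenotypes, ("A", "E"),
                          include_age=False)
        res = standardize(fit(model, biv_data, FitOptions(n_starts=2)))
        total = sum(
            (res.standardized[c] ** 2).sum(axis=1) for c in ("A", "E")
        )
        assert total == pytest.approx(np.ones(2), abs=1e-6)


def test_univariate_recovery_and_ci(univ_ae_spec, univ_ae_model):
    data = simulate_cohort(univ_ae_spec, seed=21)
    res = fit(univ_ae_model, data, FitOptions(n_starts=2, compute_ci=True))
    assert res.converged
    est = res.estimates()
    h2 = est["a[1,1]"] ** 2 / (est["a[1,1]"] ** 2 + est["e[1,1]"] ** 2)
    assert h2 == pytest.approx(0.7, abs=0.12)
    assert res.ci is not None and (res.ci["se"] > 0).all()


def test_mixed_fit_with_missing_cotwins_recovers_structure(mixed2):
    a = np.array([[0.8, 0.0], [0.45, np.sqrt(0.72 - 0.45**2)]])
    e = np.array([[0.6, 0.0], [0.15, np.sqrt(0.28 - 0.15**2)]])
    spec = GenerativeSpec(150, 170, mixed2, {"A": a, "E": e}, seed=11,
                          missing_twin_prob=0.08)
    data = simulate_cohort(spec)
    model = ModelSpec("cholesky", mixed2, ("A", "E"), include_age=False)
    res = fit(model, data, FitOptions(n_starts=2))
    assert res.converged
    comps = res.component_covariances()
    tot = np.diag(sum(comps.values()))
    # liability variance pinned at 1 by the gauge constraint
    assert tot[1] == pytest.approx(1.0, abs=1e-3)
    h2 = np.diag(comps["A"]) / tot
    assert h2 == pytest.approx([0.64, 0.72], abs=0.2)
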