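"""Decomposition arithmetic and large-sample convergence to generative values."""

import numpy as np
import pytest

from twinsem import (
    FitOptions,
    GenerativeSpec,
    ModelSpec,
    PhenotypeSpec,
    fit,
    genetic_correlations,
    environmental_correlations,
    heritability,
    shared_genetic_variance,
    simulate_cohort,
    variance_percent,
)
from twinsem.fiml import FitResult
from twinsem.models import Parameterization


def _fit_at(model: ModelSpec, theta) -> FitResult:
    par = Parameterization(model)
    theta = np.asarray(theta, dtype=float)
    assert theta.size == par.n_free
    return FitResult(
        model=model, param_names=list(par.names), theta=theta, minus2LL=0.0,
        k=par.n_free, k_structural=par.n_structural_, converged=True,
        boundary=False, n_pairs=0, age_center=0.0,
    )


def test_univariate_heritability_is_squared_standardized_path():
    model = ModelSpec("cholesky", (PhenotypeSpec("x"),), include_age=False)
    res = _fit_at(model, [0.8, 0.6, 0.0])
    assert heritability(res)["h2_pct"].iloc[0] == pytest.approx(64.0)
    res0 = _fit_at(model, [0.0, 1.0, 0.0])
    assert heritability(res0)["h2_pct"].iloc[0] == pytest.approx(0.0)


def test_variance_percent_squared_loadings_and_total():
    model = ModelSpec("cholesky", (PhenotypeSpec("x"),), include_age=False)
    res = _fit_at(model, [0.6325, np.sqrt(1 - 0.6325**2), 0.0])
    table = variance_percent(res)
    a_row = table[table.factor == "A1"].iloc[0]
    assert a_row["x"] == pytest.approx(40.0, abs=0.02)
    assert table["x"].sum() == pytest.approx(100.0, abs=1e-6)


def test_genetic_correlation_closed_form_and_structural_zeros():
    ph = (PhenotypeSpec("u"), PhenotypeSpec("v"))
    model = ModelSpec("cholesky", ph, include_age=False)
    # a = [[0.6, 0], [0.3, 0.4]], e diagonal
    res = _fit_at(model, [0.6, 0.3, 0.4, 0.7, 0.0, 0.7, 0.0, 0.0])
    rg = genetic_correlations(res)
    assert rg.loc["u", "v"] == pytest.approx(0.6)
    re = environmental_correlations(res)
    assert re.loc["u", "v"] == pytest.approx(0.0)
    # diagonal genetic paths: off-diagonal rG is zero
    res_d = _fit_at(model, [0.6, 0.0, 0.4, 0.7, 0.2, 0.7, 0.0, 0.0])
    assert genetic_correlations(res_d).loc["u", "v"] == 0.0
    # dropped genetic row: structural zero, not an error
    dropped = model.with_drops(["A[2,1]", "A[2,2]"])
    res0 = _fit_at(dropped, [0.6, 0.7, 0.0, 0.7, 0.0, 0.0])
    assert genetic_correlations(res0).loc["u", "v"] == 0.0


def test_heritability_equals_sum_of_a_rows_of_variance_percent():
    rng = np.random.default_rng(8)
    ph = tuple(PhenotypeSpec(f"t{i}") for i in range(3))
    model = ModelSpec("cholesky", ph, ("A", "E"), include_age=False)
    par = Parameterization(model)
    theta = rng.normal(0.4, 0.3, par.n_free)
    res = _fit_at(model, theta)
    h2 = heritability(res, ci=False).set_index("trait")["h2_pct"]
    table = variance_percent(res)
    a_sum = table[table.component == "A"][list(res.model.trait_names)].sum()
    for name in res.model.trait_names:
        assert h2[name] == pytest.approx(a_sum[name], abs=0.1)
    rg = genetic_correlations(res).to_numpy()
    assert np.diag(rg) == pytest.approx(np.ones(3))
    assert np.linalg.eigvalsh(rg).min() >= -1e-8


class TestSharedGeneticVariance:
    ph = (PhenotypeSpec("u"), PhenotypeSpec("v"))
    model = ModelSpec("cholesky", ph, include_age=False)

    def test_single_source_gets_everything(self):
        # v loads only on the factor originating at u
        res = _fit_at(self.model, [0.6, 0.5, 0.0, 0.7, 0.0, 0.7, 0.0, 0.0])
        shares = shared_genetic_variance(res, "v").set_index("source")["share_pct"]
        assert shares["u"] == pytest.approx(100.0)

    def test_no_cross_paths_is_fully_specific(self):
        res = _fit_at(self.model, [0.6, 0.0, 0.5, 0.7, 0.0, 0.7, 0.0, 0.0])
        frame = shared_genetic_variance(res, "v")
        specific = frame[frame.kind == "specific"]["share_pct"].iloc[0]
        assert specific == pytest.approx(100.0)

    def test_known_cross_paths_split(self):
        res = _fit_at(self.model, [0.6, 0.3, 0.4, 0.7, 0.0, 0.7, 0.0, 0.0])
        frame = shared_genetic_variance(res, "v").set_index("source")
        assert frame.loc["u", "share_pct"] == pytest.approx(100 * 0.09 / 0.25)
        assert frame.loc["v", "share_pct"] == pytest.approx(100 * 0.16 / 0.25)
        assert frame["share_pct"].sum() == pytest.approx(100.0)
        assert (frame["ordering"] == "u>v").all()

    def test_zero_genetic_variance_raises(self):
        dropped = self.model.with_drops(["A[2,1]", "A[2,2]"])
        res = _fit_at(dropped, [0.6, 0.7, 0.0, 0.7, 0.0, 0.0])
        with pytest.raises(ValueError, match="no genetic variance"):
            shared_genetic_variance(res, "v")


def test_large_sample_decomposition_converges_to_truth():
    """At 50k pairs the fitted decomposition matches the generative
    heritabilities and correlations within 0.02."""
    ph = tuple(PhenotypeSpec(f"t{i}") for i in range(3))
    a = np.array([[0.85, 0, 0], [0.4, 0.55, 0], [0.3, 0.35, 0.5]])
    e = np.array([[0.55, 0, 0], [0.1, 0.6, 0], [0.05, 0.2, 0.55]])
    spec = GenerativeSpec(25_000, 25_000, ph, {"A": a, "E": e}, seed=17)
    data = simulate_cohort(spec)
    model = spec.model_spec()
    res = fit(model, data, FitOptions(n_starts=1, start_theta=spec.true_theta()))
    assert res.converged
    sig_a, sig_e = a @ a.T, e @ e.T
    tot = np.diag(sig_a + sig_e)
    h2_true = 100 * np.diag(sig_a) / tot
    h2_est = heritability(res, ci=False)["h2_pct"].to_numpy()
    # percentages: 0.02 on the proportion scale = 2 points
    assert h2_est == pytest.approx(h2_true, abs=2.0)
    rg_true = sig_a / np.sqrt(np.outer(np.diag(sig_a), np.diag(sig_a)))
    assert genetic_correlations(res).to_numpy() == pytest.approx(rg_true, abs=0.02)
    re_true = sig_e / np.sqrt(np.outer(np.diag(sig_e), np.diag(sig_e)))
    assert environmental_correlations(res).to_numpy() == pytest.approx(
        re_true, abs=0.02
    )
    shares = shared_genetic_variance(res, "t2").set_index("source")["share_pct"]
    a_std_row = a[2, :] / np.sqrt(tot[2])
    true_shares = 100 * a_std_row**2 / (a_std_row**2).sum()
    assert shares.to_numpy() == pytest.approx(true_shares, abs=2.0)
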