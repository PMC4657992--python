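"""Model structures: component covariances, expected moments, parameter counts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twinsem import (
    ModelSpec,
    PhenotypeSpec,
    component_covariance,
    count_free_parameters,
    expected_moments,
    structural_parameter_count,
    study_phenotypes,
)
from twinsem.models import Parameterization, parse_drop


def test_component_covariance_examples():
    path = [[0.6, 0.0], [0.3, 0.4]]
    expected = [[0.36, 0.18], [0.18, 0.25]]
    assert component_covariance(path) == pytest.approx(np.array(expected))
    assert component_covariance(np.eye(3)) == pytest.approx(np.eye(3))
    assert component_covariance(np.zeros((2, 2))) == pytest.approx(np.zeros((2, 2)))
    with pytest.raises(ValueError):
        component_covariance(np.zeros((2, 3)))


@pytest.mark.parametrize(
    "components,a2,c2,d2,e2,r_mz,r_dz",
    [
        (("A", "E"), 0.64, 0, 0, 0.36, 0.64, 0.32),
        (("A", "C", "E"), 0.5, 0.3, 0, 0.2, 0.8, 0.55),
        (("A", "D", "E"), 0.4, 0, 0.3, 0.3, 0.7, 0.275),
    ],
)
def test_univariate_cross_twin_covariances(components, a2, c2, d2, e2, r_mz, r_dz):
    ph = (PhenotypeSpec("x"),)
    model = ModelSpec("cholesky", ph, components, include_age=False)
    paths = [np.sqrt(v) for v, c in ((a2, "A"), (c2, "C"), (d2, "D"), (e2, "E"))
             if c in components]
    theta = np.array(paths + [0.0])
    mom = expected_moments(model, theta)
    for z, r in (("MZ", r_mz), ("DZ", r_dz)):
        assert mom[z].cov[0, 0] == pytest.approx(1.0)
        assert mom[z].cov[0, 1] == pytest.approx(r)


def test_structural_counts_match_published_df_ladder():
    ph = study_phenotypes()
    ade = ModelSpec("cholesky", ph, ("A", "D", "E"))
    counts = {
        "ade": structural_parameter_count(ade),
        "ae": structural_parameter_count(ModelSpec("cholesky", ph)),
        "ip1": structural_parameter_count(
            ModelSpec("independent_pathway", ph, n_factors=1)
        ),
        "cp1": structural_parameter_count(
            ModelSpec("common_pathway", ph, n_factors=1)
        ),
        "ip2": structural_parameter_count(
            ModelSpec("independent_pathway", ph, n_factors=2)
        ),
    }
    assert counts["ade"] == 30  # 3 components x p(p+1)/2
    assert counts["ade"] - counts["ae"] == 10
    assert counts["ade"] - counts["ip1"] == 14
    assert counts["ade"] - counts["cp1"] == 17
    assert counts["ade"] - counts["ip2"] == 6


def test_count_includes_means_thresholds_age_and_constraints():
    ph = study_phenotypes()  # 2 continuous + 2 binary
    ae = ModelSpec("cholesky", ph)
    assert count_free_parameters(ae) == 20 + 4 + 4
    assert count_free_parameters(ae, effective=True) == 20 + 4 + 4 - 2
    no_age = ModelSpec("cholesky", ph, include_age=False)
    assert count_free_parameters(no_age) == 20 + 4


def test_drop_lists_reduce_counts_and_parse():
    ph = study_phenotypes()
    assert parse_drop("A[4,1]") == ("A", 3, 0)
    reduced = ModelSpec("cholesky", ph).with_drops(["A[4,1]", "E[2,1]", "E[3,1]"])
    assert structural_parameter_count(reduced) == 17
    with pytest.raises(ValueError):
        ModelSpec("cholesky", ph, drop=(("A", 0, 1),))  # upper triangle
    with pytest.raises(ValueError):
        ModelSpec("cholesky", ph, components=("A", "C", "D", "E"))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**32 - 1))
def test_mz_minus_dz_cross_block_is_half_a_plus_three_quarter_d(seed):
    rng = np.random.default_rng(seed)
    p = 3
    ph = tuple(PhenotypeSpec(f"t{i}") for i in range(p))
    model = ModelSpec("cholesky", ph, ("A", "D", "E"), include_age=False)
    par = Parameterization(model)
    theta = rng.normal(0, 0.6, par.n_free)
    mom = par.moments(theta)
    cross_mz = mom["MZ"].cov[:p, p:]
    cross_dz = mom["DZ"].cov[:p, p:]
    comps = par.component_covariances(theta)
    expected = 0.5 * comps["A"] + 0.75 * comps["D"]
    assert cross_mz - cross_dz == pytest.approx(expected, abs=1e-10)
    # within-twin blocks identical across zygosity and PSD by construction
    assert mom["MZ"].cov[:p, :p] == pytest.approx(mom["DZ"].cov[:p, :p])
    for sig in comps.values():
        assert np.linalg.eigvalsh(sig).min() >= -1e-10


@pytest.mark.parametrize("structure,n_factors", [
    ("independent_pathway", 1), ("independent_pathway", 2),
    ("common_pathway", 1), ("common_pathway", 2),
])
def test_ip_cp_component_covariances_are_psd_and_ae_only(structure, n_factors):
    ph = study_phenotypes()
    model = ModelSpec(structure, ph, n_factors=n_factors, include_age=False)
    par = Parameterization(model)
    rng = np.random.default_rng(3)
    theta = rng.normal(0, 0.5, par.n_free)
    comps = par.component_covariances(theta)
    assert set(comps) == {"A", "E"}
    for sig in comps.values():
        assert np.linalg.eigvalsh(sig).min() >= -1e-10
    with pytest.raises(ValueError):
        ModelSpec(structure, ph, components=("A", "C", "E"), n_factors=n_factors)


def test_saturated_moments_are_per_zygosity():
    ph = (PhenotypeSpec("x"), PhenotypeSpec("b", "binary", prevalence=0.3))
    model = ModelSpec("saturated", ph, include_age=False)
    par = Parameterization(model)
    theta = par.start()
    theta[par.index("mz_mean_x_1")] = 1.5
    mom = par.moments(theta)
    assert mom["MZ"].mean[0] == pytest.approx(1.5)
    assert mom["DZ"].mean[0] == pytest.approx(0.0)
    # binary slots carry thresholds, latent mean stays zero
    assert mom["MZ"].mean[1] == 0.0
    assert np.isfinite(mom["MZ"].thresholds[1])
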