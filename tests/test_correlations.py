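"""Correlation estimators against closed forms, grid search and simulation."""

import numpy as np
import pytest

from twinsem import (
    GenerativeSpec,
    PhenotypeSpec,
    biserial_corr,
    ctct_matrix,
    pearson_corr,
    simulate_cohort,
    tetrachoric_corr,
)
from twinsem.correlations import ctct_square, tetrachoric_negll


class TestPearson:
    def test_perfect_and_null(self):
        x = np.arange(10.0)
        assert pearson_corr(x, x).value == pytest.approx(1.0)
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal((2, 100_000))
        assert abs(pearson_corr(a, b).value) < 0.02

    def test_bivariate_normal_recovery_and_ci(self):
        rng = np.random.default_rng(1)
        n = 100_000
        x = rng.standard_normal(n)
        y = 0.45 * x + np.sqrt(1 - 0.45**2) * rng.standard_normal(n)
        est = pearson_corr(x, y)
        assert est.value == pytest.approx(0.45, abs=0.01)
        assert est.ci_low < est.value < est.ci_high

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            pearson_corr(np.ones(10), np.arange(10.0))


class TestTetrachoric:
    def test_independence_and_boundary(self):
        assert tetrachoric_corr([[50, 50], [50, 50]]).value == pytest.approx(
            0.0, abs=1e-3
        )
        est = tetrachoric_corr([[40, 0], [0, 40]])
        assert est.value == 1.0 and est.boundary

    def test_median_split_arcsine_closed_form(self):
        # for median splits p11 = 1/4 + arcsin(rho)/(2 pi); counts 2:1:1:2
        # give p11 = 1/3, hence rho = 0.5
        est = tetrachoric_corr([[200, 100], [100, 200]])
        assert est.value == pytest.approx(0.5, abs=2e-3)

    def test_ml_matches_grid_search(self):
        table = np.array([[310.0, 95.0], [72.0, 160.0]])
        est = tetrachoric_corr(table)
        n = table.sum()
        from scipy.special import ndtri

        tau1 = ndtri(1 - table[1].sum() / n)
        tau2 = ndtri(1 - table[:, 1].sum() / n)
        grid = np.arange(-0.999, 0.999, 1e-3)
        lls = [tetrachoric_negll(r, table, tau1, tau2) for r in grid]
        assert est.value == pytest.approx(grid[int(np.argmin(lls))], abs=2e-3)

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError):
            tetrachoric_corr([[10, 0], [20, 0]])


class TestBiserial:
    def test_independent_near_zero(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(100_000)
        y = (rng.standard_normal(100_000) > 0.85).astype(float)
        assert abs(biserial_corr(x, y).value) < 0.02

    def test_latent_rho_recovery(self):
        rng = np.random.default_rng(3)
        n = 100_000
        x = rng.standard_normal(n)
        latent = 0.5 * x + np.sqrt(1 - 0.25) * rng.standard_normal(n)
        y = (latent > np.median(latent)).astype(float)
        assert biserial_corr(x, y).value == pytest.approx(0.5, abs=0.02)

    def test_degenerate_indicator_hits_boundary(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(4000)
        y = (x > np.median(x)).astype(float)
        est = biserial_corr(x, y)
        assert est.value > 0.99
        assert est.boundary

    def test_single_category_raises(self):
        with pytest.raises(ValueError):
            biserial_corr(np.arange(10.0), np.zeros(10))


@pytest.fixture(scope="module")
def e_only_data():
    ph = (PhenotypeSpec("x"), PhenotypeSpec("b", "binary", prevalence=0.3))
    e = np.array([[1.0, 0.0], [0.4, np.sqrt(1 - 0.16)]])
    spec = GenerativeSpec(4000, 4000, ph, {"E": e}, seed=5)
    return simulate_cohort(spec)


class TestCtct:
    def test_e_only_model_has_no_cross_twin_correlation(self, e_only_data):
        for z in ("MZ", "DZ"):
            frame = ctct_matrix(e_only_data, z)
            assert np.abs(frame["r"].to_numpy()).max() < 0.06

    def test_univariate_ae_diagonal_is_a2_and_half_a2(self):
        ph = (PhenotypeSpec("x"),)
        spec = GenerativeSpec(
            20000, 20000, ph,
            {"A": [[np.sqrt(0.72)]], "E": [[np.sqrt(0.28)]]}, seed=6,
        )
        d = simulate_cohort(spec)
        r_mz = ctct_matrix(d, "MZ")["r"].iloc[0]
        r_dz = ctct_matrix(d, "DZ")["r"].iloc[0]
        assert r_mz == pytest.approx(0.72, abs=0.02)
        assert r_dz == pytest.approx(0.36, abs=0.02)

    def test_double_entry_symmetry_and_method_choice(self, e_only_data):
        frame = ctct_matrix(e_only_data, "MZ")
        mat = ctct_square(frame, e_only_data.trait_names)
        assert mat == pytest.approx(mat.T)
        methods = dict(zip(zip(frame.trait_1, frame.trait_2), frame.method))
        assert methods[("x", "x")] == "pearson"
        assert methods[("b", "b")] == "tetrachoric"
        assert methods[("b", "x")] == "biserial"

    def test_mz_exceeds_dz_under_positive_genetic_paths(self):
        ph = (PhenotypeSpec("x"), PhenotypeSpec("y"))
        a = np.array([[0.8, 0.0], [0.5, 0.5]])
        e = np.array([[0.6, 0.0], [0.2, 0.55]])
        spec = GenerativeSpec(20000, 20000, ph, {"A": a, "E": e}, seed=7)
        d = simulate_cohort(spec)
        mz = ctct_square(ctct_matrix(d, "MZ"), d.trait_names)
        dz = ctct_square(ctct_matrix(d, "DZ"), d.trait_names)
        assert (mz - dz > -0.02).all()

    def test_bootstrap_ci_brackets_estimate(self):
        ph = (PhenotypeSpec("x"),)
        spec = GenerativeSpec(
            300, 300, ph, {"A": [[np.sqrt(0.72)]], "E": [[np.sqrt(0.28)]]}, seed=8
        )
        d = simulate_cohort(spec)
        frame = ctct_matrix(d, "MZ", ci=True, n_boot=200, seed=1)
        row = frame.iloc[0]
        assert row.ci_low <= row.r <= row.ci_high
        again = ctct_matrix(d, "MZ", ci=True, n_boot=200, seed=1)
        assert frame.equals(again)
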