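import numpy as np
import pytest

from twinsem import GenerativeSpec, ModelSpec, PhenotypeSpec


@pytest.fixture(scope="session")
def cont1():
    """One continuous phenotype."""
    return (PhenotypeSpec("x"),)


@pytest.fixture(scope="session")
def cont2():
    return (PhenotypeSpec("x"), PhenotypeSpec("y"))


@pytest.fixture(scope="session")
def mixed2():
    """Continuous + binary pair of phenotypes (CWP-like prevalence)."""
    return (PhenotypeSpec("x"), PhenotypeSpec("b", "binary", prevalence=0.1962))


@pytest.fixture(scope="session")
def univ_ae_spec(cont1):
    """Univariate AE truth with h2 = 0.7, study-scale pair counts."""
    return GenerativeSpec(
        219, 244, cont1,
        {"A": [[np.sqrt(0.7)]], "E": [[np.sqrt(0.3)]]},
        seed=7,
    )


@pytest.fixture(scope="session")
def biv_ae_spec(cont2):
    """Bivariate AE truth with cross-paths (rG about 0.64)."""
    a = np.array([[0.8, 0.0], [0.5, 0.6]])
    e = np.array([[0.6, 0.0], [0.1, 0.55]])
    return GenerativeSpec(219, 244, cont2, {"A": a, "E": e}, seed=11)


@pytest.fixture(scope="session")
def univ_ae_model(cont1):
    return ModelSpec("cholesky", cont1, ("A", "E"), include_age=False)


@pytest.fixture(scope="session")
def biv_ae_model(cont2):
    return ModelSpec("cholesky", cont2, ("A", "E"), include_age=False)
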