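"""Synthetic MZ/DZ twin cohorts with the exact structure the models assume.

Component factor scores are drawn per pair as correlated normals — the
cross-twin correlation is the component's sharing coefficient (A: 1 MZ /
0.5 DZ; C: 1; D: 1 / 0.25; E: 0) — and mixed through lower-triangular path
matrices, so simulated moments match :func:`twinsem.models.expected_moments`
by construction.  Binary traits are thresholded standard-normal liabilities;
a linear age effect (age shared within pair, centered at the cohort mean so
stated prevalences hold at the mean age) and missing-at-random dropout are
applied last.

The default cohort mirrors the study conditions this package was written
around: 219 MZ + 244 DZ female pairs, four phenotypes — serum DHEAS and
chronic fatigue (continuous), depression (prevalence 30.06%) and chronic
widespread pain (prevalence 19.62%) (binary) — with an AE covariance
structure assembled from the published heritabilities and genetic /
non-shared-environmental correlation matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .data import TwinDataset
from .models import DZ, MZ, SHARING, ModelSpec, Parameterization, PhenotypeSpec

__all__ = [
    "GenerativeSpec",
    "simulate_cohort",
    "dichotomize",
    "study_phenotypes",
    "study_default_spec",
]

_COMPONENTS = ("A", "C", "D", "E")


@dataclass
class GenerativeSpec:
    """Generative parameters for a synthetic twin cohort.

    ``paths`` maps component letters to p x p lower-triangular path matrices
    on the latent (liability) scale; absent components default to zero.
    Continuous traits are reported as ``mean + sd * latent``; binary traits
    as indicators of latent-plus-age-effect liability above the threshold
    implied by their prevalence.  Age slopes are per year on the reported
    trait scale (liability SD units for binary traits).
    """

    n_mz: int
    n_dz: int
    phenotypes: tuple[PhenotypeSpec, ...]
    paths: dict[str, np.ndarray]
    trait_means: np.ndarray | None = None
    trait_sds: np.ndarray | None = None
    age_mean: float = 58.39
    age_sd: float = 11.08
    age_slopes: np.ndarray | None = None
    missing_twin_prob: float = 0.0
    missing_value_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.phenotypes = tuple(self.phenotypes)
        p = self.p
        if self.n_mz < 0 or self.n_dz < 0:
            raise ValueError("pair counts must be non-negative")
        paths = {}
        for comp, mat in self.paths.items():
            if comp not in _COMPONENTS:
                raise ValueError(f"unknown component {comp!r}")
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (p, p):
                raise ValueError(f"path matrix {comp} must be {p}x{p}")
            paths[comp] = mat
        self.paths = paths
        if self.trait_means is None:
            self.trait_means = np.zeros(p)
        if self.trait_sds is None:
            self.trait_sds = np.ones(p)
        if self.age_slopes is None:
            self.age_slopes = np.zeros(p)
        self.trait_means = np.asarray(self.trait_means, dtype=float)
        self.trait_sds = np.asarray(self.trait_sds, dtype=float)
        self.age_slopes = np.asarray(self.age_slopes, dtype=float)
        for arr, nm in (
            (self.trait_means, "trait_means"),
            (self.trait_sds, "trait_sds"),
            (self.age_slopes, "age_slopes"),
        ):
            if arr.shape != (p,):
                raise ValueError(f"{nm} must have length {p}")
        if not (0.0 <= self.missing_twin_prob < 1.0) or not (
            0.0 <= self.missing_value_prob < 1.0
        ):
            raise ValueError("missingness probabilities must be in [0,1)")
        # binary traits must carry unit total latent variance
        total = self.total_latent_cov()
        for i, ph in enumerate(self.phenotypes):
            if ph.binary and abs(total[i, i] - 1.0) > 1e-6:
                raise ValueError(
                    f"binary trait {ph.name!r} has implied liability variance "
                    f"{total[i, i]:.4f}; must be 1"
                )

    @property
    def p(self) -> int:
        return len(self.phenotypes)

    def components(self) -> tuple[str, ...]:
        return tuple(c for c in _COMPONENTS if c in self.paths)

    def total_latent_cov(self) -> np.ndarray:
        return sum(m @ m.T for m in self.paths.values())

    def model_spec(self, include_age: bool | None = None) -> ModelSpec:
        """The fitting-side model family this spec generates from."""
        if include_age is None:
            include_age = bool(np.any(self.age_slopes != 0.0))
        return ModelSpec(
            structure="cholesky",
            phenotypes=self.phenotypes,
            components=self.components(),
            include_age=include_age,
        )

    def true_theta(self) -> np.ndarray:
        """Generative parameters in fitting order, on the standardized-trait
        scale used by the likelihood (continuous traits as stored, binary on
        the liability scale)."""
        model = self.model_spec()
        par = Parameterization(model)
        theta = np.zeros(par.n_free)
        k = 0
        sds = np.where([ph.binary for ph in self.phenotypes], 1.0, self.trait_sds)
        for c in model.components:
            for i, j in par.free_entries[c]:
                theta[k] = self.paths[c][i, j] * sds[i]
                k += 1
        for i, ph in enumerate(self.phenotypes):
            theta[k] = ph.threshold if ph.binary else self.trait_means[i]
            k += 1
        if model.include_age:
            theta[k : k + self.p] = self.age_slopes
        return theta


def dichotomize(liability, threshold: float) -> np.ndarray:
    """Indicator of liability exceeding the threshold (1 iff above)."""
    threshold = float(threshold)
    if np.isnan(threshold):
        raise ValueError("threshold must be finite or +/-inf")
    return (np.asarray(liability, dtype=float) > threshold).astype(float)


def simulate_cohort(
    spec: GenerativeSpec,
    seed: int | None = None,
    return_liabilities: bool = False,
) -> TwinDataset:
    """Draw a synthetic cohort; deterministic under a fixed seed.

    With ``return_liabilities=True`` the pre-threshold latent liabilities of
    binary traits are appended as ``<trait>_liab_{1,2}`` columns (used by
    moment-equivalence tests; they are not part of the observed data model).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    p = spec.p
    binary = np.array([ph.binary for ph in spec.phenotypes])
    thresholds = np.array(
        [ph.threshold if ph.binary else np.nan for ph in spec.phenotypes]
    )

    frames = []
    pair_offset = 0
    for zyg, n in ((MZ, spec.n_mz), (DZ, spec.n_dz)):
        lat = np.zeros((n, 2, p))
        for comp, path in spec.paths.items():
            alpha = SHARING[zyg][comp]
            shared = rng.standard_normal((n, p))
            f = np.empty((n, 2, p))
            for t in range(2):
                unique = rng.standard_normal((n, p))
                f[:, t, :] = np.sqrt(alpha) * shared + np.sqrt(1.0 - alpha) * unique
            lat += f @ path.T
        age = rng.normal(spec.age_mean, spec.age_sd, size=n)  # shared within pair
        age_c = age - spec.age_mean
        # age effect on the latent/standardized scale
        scaled_slopes = np.where(binary, spec.age_slopes, spec.age_slopes / spec.trait_sds)
        lat = lat + age_c[:, None, None] * scaled_slopes[None, None, :]

        values = np.empty((n, 2, p))
        for i in range(p):
            if binary[i]:
                values[:, :, i] = dichotomize(lat[:, :, i], thresholds[i])
            else:
                values[:, :, i] = (
                    spec.trait_means[i] + spec.trait_sds[i] * lat[:, :, i]
                )

        # missing at random: whole-twin dropout, then per-value dropout
        drop_twin = rng.random((n, 2)) < spec.missing_twin_prob
        drop_val = rng.random((n, 2, p)) < spec.missing_value_prob
        values[drop_twin, :] = np.nan
        values[drop_val] = np.nan

        cols = {
            "pair_id": np.arange(pair_offset, pair_offset + n),
            "zygosity": zyg,
            "age_1": age,
            "age_2": age,
        }
        for t in range(2):
            for i, ph in enumerate(spec.phenotypes):
                cols[f"{ph.name}_{t + 1}"] = values[:, t, i]
        if return_liabilities:
            for t in range(2):
                for i, ph in enumerate(spec.phenotypes):
                    if ph.binary:
                        cols[f"{ph.name}_liab_{t + 1}"] = lat[:, t, i]
        frames.append(pd.DataFrame(cols))
        pair_offset += n

    df = pd.concat(frames, ignore_index=True)
    value_cols = [f"{ph.name}_{t}" for t in (1, 2) for ph in spec.phenotypes]
    keep = ~df[value_cols].isna().all(axis=1)
    df = df.loc[keep].reset_index(drop=True)
    return TwinDataset(df, spec.phenotypes)


# ---------------------------------------------------------------------
# study-condition defaults
# ---------------------------------------------------------------------

def study_phenotypes() -> tuple[PhenotypeSpec, ...]:
    """The four phenotypes in Cholesky order: DHEAS, fatigue (continuous),
    depression (prevalence 30.06%), chronic widespread pain (19.62%)."""
    return (
        PhenotypeSpec("dheas", "continuous"),
        PhenotypeSpec("fatigue", "continuous"),
        PhenotypeSpec("depression", "binary", prevalence=0.3006),
        PhenotypeSpec("cwp", "binary", prevalence=0.1962),
    )


def _nearest_feasible(sigma: np.ndarray) -> np.ndarray:
    """Shrink off-diagonals just enough for positive definiteness."""
    sig = sigma.copy()
    diag = np.diag(sig).copy()
    shrink = 1.0
    for _ in range(200):
        if np.linalg.eigvalsh(sig).min() > 1e-8:
            return sig
        shrink *= 0.995
        off = (sigma - np.diag(np.diag(sigma))) * shrink
        sig = np.diag(diag) + off
    return np.diag(diag)


def study_default_spec(seed: int = 0, missing_twin_prob: float = 0.0) -> GenerativeSpec:
    """Generative spec emulating the study cohort.

    AE structure with per-trait heritabilities (74.24%, 42.58%, 49.9%,
    70.83% for DHEAS, fatigue, depression, CWP), genetic correlations
    (CWP-fatigue 0.78, CWP-depression 0.625, CWP-DHEAS -0.296,
    DHEAS-depression -0.433, others 0) and non-shared-environmental
    correlations (depression-DHEAS 0.491, depression-fatigue 0.381,
    others 0).  The published correlation matrices sit on the boundary of
    positive definiteness, so off-diagonals are shrunk by the minimal
    deterministic factor that makes the component covariances proper.
    """
    phenos = study_phenotypes()
    h2 = np.array([0.7424, 0.4258, 0.499, 0.7083])
    e2 = 1.0 - h2
    rg = np.array(
        [
            [1.0, 0.0, -0.433, -0.296],
            [0.0, 1.0, 0.0, 0.780],
            [-0.433, 0.0, 1.0, 0.625],
            [-0.296, 0.780, 0.625, 1.0],
        ]
    )
    re = np.array(
        [
            [1.0, 0.0, 0.491, 0.0],
            [0.0, 1.0, 0.381, 0.0],
            [0.491, 0.381, 1.0, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )
    sig_a = _nearest_feasible(rg * np.sqrt(np.outer(h2, h2)))
    sig_e = _nearest_feasible(re * np.sqrt(np.outer(e2, e2)))
    # renormalize so total latent variance is exactly 1 per trait
    total = np.diag(sig_a + sig_e)
    scale = np.sqrt(np.outer(total, total))
    sig_a /= scale
    sig_e /= scale
    paths = {
        "A": np.linalg.cholesky(sig_a + 1e-10 * np.eye(4)),
        "E": np.linalg.cholesky(sig_e + 1e-10 * np.eye(4)),
    }
    return GenerativeSpec(
        n_mz=219,
        n_dz=244,
        phenotypes=phenos,
        paths=paths,
        trait_means=np.array([3.10, 1.55, 0.0, 0.0]),
        trait_sds=np.array([1.93, 1.29, 1.0, 1.0]),
        age_mean=58.39,
        age_sd=11.08,
        age_slopes=np.array([-0.02, 0.01, 0.005, 0.005]),
        missing_twin_prob=missing_twin_prob,
        seed=seed,
    )
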