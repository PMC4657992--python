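"""Declarative twin-model structures and their expected moments.

A classical twin design decomposes the phenotypic covariance of p traits
into latent components: additive genetic (A), shared environmental (C),
dominance genetic (D) and non-shared environmental (E).  MZ co-twins share
A and D fully and C by definition; DZ co-twins share half of A, a quarter
of D and all of C; E is never shared.  Binary traits are modelled as
thresholded standard-normal liabilities.

Four structures are supported:

``cholesky``
    Each component covariance is ``P @ P.T`` for a free lower-triangular
    path matrix ``P`` (optionally with entries fixed to zero via a drop
    list), guaranteeing positive semidefiniteness.
``independent_pathway``
    Per component, one or two common factors load directly on every trait,
    plus trait-specific factors (AE only).
``common_pathway``
    One or two latent phenotypes, each with unit variance split between A
    and E, load on the traits; trait-specific A and E factors mop up the
    residual variance (AE only).
``saturated``
    Free mean/threshold per trait, twin and zygosity group and a free
    covariance per zygosity — the reference model for assumption checks.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.special import ndtri

__all__ = [
    "PhenotypeSpec",
    "ModelSpec",
    "ExpectedMoments",
    "Parameterization",
    "component_covariance",
    "expected_moments",
    "count_free_parameters",
    "structural_parameter_count",
    "parse_drop",
    "SHARING",
]

MZ, DZ = "MZ", "DZ"

#: cross-twin sharing coefficients per component and zygosity
SHARING = {
    MZ: {"A": 1.0, "C": 1.0, "D": 1.0, "E": 0.0},
    DZ: {"A": 0.5, "C": 1.0, "D": 0.25, "E": 0.0},
}

_COMPONENT_ORDER = ("A", "C", "D", "E")


@dataclass(frozen=True)
class PhenotypeSpec:
    """One observed phenotype.

    Binary traits are indicators of a latent standard-normal liability
    exceeding a threshold; the threshold is derived from the prevalence via
    the inverse normal CDF.
    """

    name: str
    scale: str = "continuous"  # "continuous" | "binary"
    prevalence: float | None = None
    age_slope_free: bool = True

    def __post_init__(self):
        if self.scale not in ("continuous", "binary"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "binary":
            if self.prevalence is None or not (0.0 < self.prevalence < 1.0):
                raise ValueError(
                    f"binary phenotype {self.name!r} needs prevalence in (0,1)"
                )

    @property
    def binary(self) -> bool:
        return self.scale == "binary"

    @property
    def threshold(self) -> float:
        """Liability threshold implied by the prevalence (binary only)."""
        if not self.binary:
            raise ValueError(f"{self.name} is continuous")
        return float(ndtri(1.0 - self.prevalence))


def parse_drop(text: str) -> tuple[str, int, int]:
    """Parse ``"A[4,1]"`` into ``("A", 3, 0)`` (0-based row/col)."""
    m = re.fullmatch(r"\s*([ACDEacde])\s*\[\s*(\d+)\s*,\s*(\d+)\s*\]\s*", text)
    if not m:
        raise ValueError(f"cannot parse drop entry {text!r}")
    comp, i, j = m.group(1).upper(), int(m.group(2)) - 1, int(m.group(3)) - 1
    return comp, i, j


@dataclass(frozen=True)
class ModelSpec:
    """Declarative structure of a twin model."""

    structure: str
    phenotypes: tuple[PhenotypeSpec, ...]
    components: tuple[str, ...] = ("A", "E")
    drop: tuple[tuple[str, int, int], ...] = ()
    n_factors: int = 1  # IP factor sets / CP latent phenotypes
    include_age: bool = True

    def __post_init__(self):
        if self.structure not in (
            "saturated",
            "cholesky",
            "independent_pathway",
            "common_pathway",
        ):
            raise ValueError(f"unknown structure {self.structure!r}")
        comps = tuple(c for c in _COMPONENT_ORDER if c in self.components)
        if set(self.components) - set(_COMPONENT_ORDER):
            raise ValueError(f"unknown components {self.components}")
        object.__setattr__(self, "components", comps)
        if "E" not in comps:
            raise ValueError("E must always be present")
        if "C" in comps and "D" in comps:
            raise ValueError("C and D are not jointly identifiable")
        if self.structure in ("independent_pathway", "common_pathway"):
            if comps != ("A", "E"):
                raise ValueError(f"{self.structure} supports AE only")
            if self.n_factors not in (1, 2):
                raise ValueError("n_factors must be 1 or 2")
        p = self.p
        for comp, i, j in self.drop:
            if comp not in comps:
                raise ValueError(f"drop refers to absent component {comp}")
            if not (0 <= j <= i < p):
                raise ValueError(f"drop ({comp},{i},{j}) not lower-triangular")
        if self.structure != "cholesky" and self.drop:
            raise ValueError("drop lists apply to cholesky models only")

    @property
    def p(self) -> int:
        return len(self.phenotypes)

    @property
    def trait_names(self) -> tuple[str, ...]:
        return tuple(ph.name for ph in self.phenotypes)

    @property
    def binary_mask(self) -> np.ndarray:
        return np.array([ph.binary for ph in self.phenotypes])

    def with_drops(self, drops: Iterable[str | tuple[str, int, int]]) -> "ModelSpec":
        """Return a reduced submodel with additional paths fixed to zero."""
        parsed = tuple(
            parse_drop(d) if isinstance(d, str) else (d[0].upper(), d[1], d[2])
            for d in drops
        )
        return replace(self, drop=tuple(self.drop) + parsed)


@dataclass
class ExpectedMoments:
    """Per-zygosity expected first and second moments of a twin pair.

    Vectors have length 2p, ordered twin-1 traits then twin-2 traits.
    ``mean`` holds latent means (0 for binary traits), ``thresholds`` holds
    tau for binary entries and NaN otherwise, ``beta`` the per-entry linear
    age slope.
    """

    mean: np.ndarray
    cov: np.ndarray
    thresholds: np.ndarray
    beta: np.ndarray
    binary: np.ndarray

    @property
    def p(self) -> int:
        return self.mean.shape[0] // 2


def component_covariance(path) -> np.ndarray:
    """``path @ path.T`` for a lower-triangular path matrix (symmetric PSD)."""
    path = np.asarray(path, dtype=float)
    if path.ndim != 2 or path.shape[0] != path.shape[1]:
        raise ValueError("path matrix must be square")
    return path @ path.T


def _pair_cov(within: np.ndarray, cross: np.ndarray) -> np.ndarray:
    return np.block([[within, cross], [cross.T, within]])


class Parameterization:
    """Mapping between a flat free-parameter vector and model matrices.

    Parameter ordering: structural paths/loadings first (components in
    A, C, D, E order), then means (continuous) / thresholds (binary), then
    age slopes.  The saturated model instead carries per-zygosity mean and
    Cholesky-covariance blocks.
    """

    def __init__(self, model: ModelSpec):
        self.model = model
        self.names: list[str] = []
        self._build()

    # -- construction -------------------------------------------------
    def _build(self) -> None:
        m = self.model
        p = m.p
        names = self.names
        traits = m.trait_names
        if m.structure == "cholesky":
            dropset = set(m.drop)
            self.free_entries = {
                c: [
                    (i, j)
                    for i in range(p)
                    for j in range(i + 1)
                    if (c, i, j) not in dropset
                ]
                for c in m.components
            }
            for c in m.components:
                names += [f"{c.lower()}[{i + 1},{j + 1}]" for i, j in self.free_entries[c]]
        elif m.structure == "independent_pathway":
            for s in range(1, m.n_factors + 1):
                names += [f"ipA{s}_{t}" for t in traits]
                names += [f"ipE{s}_{t}" for t in traits]
            names += [f"spA_{t}" for t in traits]
            names += [f"spE_{t}" for t in traits]
        elif m.structure == "common_pathway":
            for k in range(1, m.n_factors + 1):
                names.append(f"cp{k}_ashare")
                names += [f"cp{k}_load_{t}" for t in traits]
            names += [f"spA_{t}" for t in traits]
            names += [f"spE_{t}" for t in traits]
        elif m.structure == "saturated":
            for z in (MZ, DZ):
                for t_idx in (1, 2):
                    for ph in m.phenotypes:
                        kind = "tau" if ph.binary else "mean"
                        names.append(f"{z.lower()}_{kind}_{ph.name}_{t_idx}")
                q = 2 * p
                names += [
                    f"{z.lower()}_l[{i + 1},{j + 1}]"
                    for i in range(q)
                    for j in range(i + 1)
                ]
        self.n_structural_ = len(names)

        if m.structure != "saturated":
            for ph in m.phenotypes:
                names.append(f"tau_{ph.name}" if ph.binary else f"mean_{ph.name}")
        if m.include_age:
            names += [f"beta_{t}" for t in traits]
        self.n_free = len(names)
        self._index = {n: i for i, n in enumerate(names)}

    def index(self, name: str) -> int:
        return self._index[name]

    # -- structural matrices ------------------------------------------
    def path_matrices(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        """Cholesky path matrices per component (cholesky structure only)."""
        m = self.model
        if m.structure != "cholesky":
            raise ValueError("path matrices are defined for cholesky models")
        p = m.p
        out = {}
        k = 0
        for c in m.components:
            mat = np.zeros((p, p))
            for i, j in self.free_entries[c]:
                mat[i, j] = theta[k]
                k += 1
            out[c] = mat
        return out

    def component_covariances(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        """Implied per-component covariance matrices (structured models)."""
        m = self.model
        p = m.p
        theta = np.asarray(theta, dtype=float)
        if theta.shape[0] != self.n_free:
            raise ValueError(
                f"parameter vector has length {theta.shape[0]}, expected {self.n_free}"
            )
        if m.structure == "cholesky":
            return {
                c: component_covariance(mat)
                for c, mat in self.path_matrices(theta).items()
            }
        if m.structure == "independent_pathway":
            k = 0
            sig_a = np.zeros((p, p))
            sig_e = np.zeros((p, p))
            for _ in range(m.n_factors):
                ga = theta[k : k + p]
                k += p
                ge = theta[k : k + p]
                k += p
                sig_a += np.outer(ga, ga)
                sig_e += np.outer(ge, ge)
            sa = theta[k : k + p]
            k += p
            se = theta[k : k + p]
            sig_a += np.diag(sa**2)
            sig_e += np.diag(se**2)
            return {"A": sig_a, "E": sig_e}
        if m.structure == "common_pathway":
            k = 0
            sig_a = np.zeros((p, p))
            sig_e = np.zeros((p, p))
            for _ in range(m.n_factors):
                a_lat = math.tanh(theta[k])  # latent genetic path, unit latent variance
                k += 1
                lam = theta[k : k + p]
                k += p
                outer = np.outer(lam, lam)
                sig_a += a_lat**2 * outer
                sig_e += (1.0 - a_lat**2) * outer
            sa = theta[k : k + p]
            k += p
            se = theta[k : k + p]
            sig_a += np.diag(sa**2)
            sig_e += np.diag(se**2)
            return {"A": sig_a, "E": sig_e}
        raise ValueError("saturated models have no component decomposition")

    # -- moments -------------------------------------------------------
    def moments(self, theta: np.ndarray) -> dict[str, ExpectedMoments]:
        m = self.model
        p = m.p
        theta = np.asarray(theta, dtype=float)
        binary = np.concatenate([m.binary_mask, m.binary_mask])
        if m.include_age:
            beta_tr = theta[self.n_free - p :]
        else:
            beta_tr = np.zeros(p)
        beta = np.concatenate([beta_tr, beta_tr])

        if m.structure == "saturated":
            out = {}
            q = 2 * p
            nl = q * (q + 1) // 2
            k = 0
            for z in (MZ, DZ):
                mv = theta[k : k + q]
                k += q
                lvals = theta[k : k + nl]
                k += nl
                L = np.zeros((q, q))
                L[np.tril_indices(q)] = lvals
                cov = L @ L.T
                mean = np.where(binary, 0.0, mv)
                thr = np.where(binary, mv, np.nan)
                out[z] = ExpectedMoments(mean, cov, thr, beta, binary)
            return out

        comps = self.component_covariances(theta)
        within = sum(comps.values())
        mt = theta[self.n_structural_ : self.n_structural_ + p]
        mean_tr = np.where(m.binary_mask, 0.0, mt)
        thr_tr = np.where(m.binary_mask, mt, np.nan)
        mean = np.concatenate([mean_tr, mean_tr])
        thr = np.concatenate([thr_tr, thr_tr])
        out = {}
        for z in (MZ, DZ):
            cross = sum(SHARING[z][c] * comps[c] for c in comps)
            out[z] = ExpectedMoments(mean, _pair_cov(within, cross), thr, beta, binary)
        return out

    # -- starts --------------------------------------------------------
    def start(self, summary: dict | None = None) -> np.ndarray:
        """Heuristic start values (optionally informed by sample summaries).

        ``summary`` may contain ``means``/``variances`` per trait (length p)
        and, for the saturated model, per-zygosity 2p x 2p ``cov`` and
        length-2p ``mean`` entries.
        """
        m = self.model
        p = m.p
        var = np.ones(p)
        mu = np.zeros(p)
        if summary:
            var = np.asarray(summary.get("variances", var), dtype=float).copy()
            mu = np.asarray(summary.get("means", mu), dtype=float).copy()
        var = np.where(m.binary_mask, 1.0, np.clip(var, 1e-3, None))
        for i, ph in enumerate(m.phenotypes):
            if ph.binary:
                mu[i] = ph.threshold

        theta = np.zeros(self.n_free)
        if m.structure == "cholesky":
            nc = len(m.components)
            k = 0
            for c in m.components:
                for i, j in self.free_entries[c]:
                    theta[k] = math.sqrt(var[i] / nc) if i == j else 0.0
                    k += 1
        elif m.structure == "independent_pathway":
            k = 0
            for _ in range(m.n_factors):
                theta[k : k + p] = 0.3 * np.sqrt(var)
                k += p
                theta[k : k + p] = 0.3 * np.sqrt(var)
                k += p
            theta[k : k + p] = 0.55 * np.sqrt(var)
            k += p
            theta[k : k + p] = 0.55 * np.sqrt(var)
        elif m.structure == "common_pathway":
            k = 0
            for _ in range(m.n_factors):
                theta[k] = math.atanh(0.7)
                k += 1
                theta[k : k + p] = 0.4 * np.sqrt(var)
                k += p
            theta[k : k + p] = 0.55 * np.sqrt(var)
            k += p
            theta[k : k + p] = 0.55 * np.sqrt(var)
        elif m.structure == "saturated":
            q = 2 * p
            k = 0
            for z in (MZ, DZ):
                if summary and f"mean_{z}" in summary:
                    theta[k : k + q] = summary[f"mean_{z}"]
                else:
                    theta[k : k + q] = np.concatenate([mu, mu])
                k += q
                if summary and f"cov_{z}" in summary:
                    cov = np.asarray(summary[f"cov_{z}"], dtype=float)
                else:
                    cov = np.diag(np.concatenate([var, var]))
                cov = cov + 1e-6 * np.eye(q)
                try:
                    L = np.linalg.cholesky(cov)
                except np.linalg.LinAlgError:
                    L = np.diag(np.sqrt(np.diag(cov)))
                theta[k : k + q * (q + 1) // 2] = L[np.tril_indices(q)]
                k += q * (q + 1) // 2
        if m.structure != "saturated":
            theta[self.n_structural_ : self.n_structural_ + p] = mu
        # age slopes start at zero
        return theta

    # -- canonical form ------------------------------------------------
    def normalize_signs(self, theta: np.ndarray) -> np.ndarray:
        """Fix reflection indeterminacy (likelihood-invariant sign flips).

        Cholesky columns are flipped so diagonals are non-negative; IP
        loading vectors so their largest-magnitude entry is positive; CP
        loadings likewise and latent genetic paths made non-negative.
        """
        m = self.model
        p = m.p
        theta = np.asarray(theta, dtype=float).copy()
        if m.structure == "cholesky":
            mats = self.path_matrices(theta)
            k = 0
            for c in m.components:
                mat = mats[c]
                for j in range(p):
                    if mat[j, j] < 0:
                        mat[:, j] *= -1.0
                for i, j in self.free_entries[c]:
                    theta[k] = mat[i, j]
                    k += 1
        elif m.structure == "independent_pathway":
            k = 0
            for _ in range(m.n_factors):
                for _ in range(2):
                    vec = theta[k : k + p]
                    if vec[np.argmax(np.abs(vec))] < 0:
                        theta[k : k + p] = -vec
                    k += p
            theta[k : k + 2 * p] = np.abs(theta[k : k + 2 * p])
        elif m.structure == "common_pathway":
            k = 0
            for _ in range(m.n_factors):
                theta[k] = abs(theta[k])
                k += 1
                vec = theta[k : k + p]
                if vec[np.argmax(np.abs(vec))] < 0:
                    theta[k : k + p] = -vec
                k += p
            theta[k : k + 2 * p] = np.abs(theta[k : k + 2 * p])
        return theta


def expected_moments(
    model: ModelSpec, theta: Sequence[float], zygosity: str | None = None
):
    """Expected 2p means/thresholds and 2p x 2p covariance per zygosity.

    With ``zygosity`` given returns that group's :class:`ExpectedMoments`;
    otherwise a dict for both groups.
    """
    mom = Parameterization(model).moments(np.asarray(theta, dtype=float))
    if zygosity is None:
        return mom
    if zygosity not in mom:
        raise ValueError(f"unknown zygosity {zygosity!r}")
    return mom[zygosity]


def structural_parameter_count(model: ModelSpec) -> int:
    """Free structural (path/loading/covariance) parameters.

    Cholesky: p(p+1)/2 per component minus drops; independent pathway:
    2p per factor set plus 2p specifics; common pathway: (1+p) per latent
    plus 2p specifics; saturated: 2p(2p+1)/2 per zygosity.
    """
    p = model.p
    if model.structure == "cholesky":
        return len(model.components) * (p * (p + 1) // 2) - len(model.drop)
    if model.structure == "independent_pathway":
        return model.n_factors * 2 * p + 2 * p
    if model.structure == "common_pathway":
        return model.n_factors * (1 + p) + 2 * p
    if model.structure == "saturated":
        q = 2 * p
        return 2 * (q * (q + 1) // 2)
    raise ValueError(model.structure)


def count_free_parameters(model: ModelSpec, effective: bool = False) -> int:
    """Total free parameters: structural + means/thresholds + age slopes.

    ``effective=True`` subtracts one df per unit-liability-variance
    constraint (one per binary trait, or per binary row and zygosity for
    the saturated model), the count appropriate for AIC.
    """
    p = model.p
    n_mean = 4 * p if model.structure == "saturated" else p
    k = structural_parameter_count(model) + n_mean
    if model.include_age:
        k += p
    if effective:
        n_bin = int(model.binary_mask.sum())
        k -= 4 * n_bin if model.structure == "saturated" else n_bin
    return k
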