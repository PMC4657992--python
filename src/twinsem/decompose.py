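"""Headline quantities of a fitted twin model.

Heritability (percentage of phenotypic variance attributable to additive
genetic variance), per-factor variance percentages, genetic and
non-shared-environmental correlation matrices (rG, rE), and the
attribution of a trait's genetic variance to the Cholesky factors first
loading on earlier traits.  Cholesky attributions are order-dependent, so
reports always carry the trait ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fiml import FitResult, delta_ci, standardize

__all__ = [
    "heritability",
    "variance_percent",
    "genetic_correlations",
    "environmental_correlations",
    "shared_genetic_variance",
    "DecompositionReport",
    "decompose",
]


def _component_fraction(result: FitResult, component: str) -> np.ndarray:
    comps = result.component_covariances()
    if component not in comps:
        raise ValueError(f"fit has no {component} component")
    total = np.diag(sum(comps.values()))
    if np.any(total <= 0):
        raise ValueError("zero implied phenotypic variance")
    return np.diag(comps[component]) / total


def heritability(result: FitResult, ci: bool = True) -> pd.DataFrame:
    """Per-trait h2 as a percentage, with a logit-scale Wald CI when the
    fit carries a parameter covariance."""
    frac = _component_fraction(result, "A")
    names = result.model.trait_names
    rows = []
    par = result.parameterization
    for i, name in enumerate(names):
        lo = hi = np.nan
        if ci and result.theta_cov is not None:
            def f(theta, i=i):
                comps = par.component_covariances(theta)
                tot = np.diag(sum(comps.values()))
                return np.diag(comps["A"])[i] / tot[i]

            _, lo, hi = delta_ci(result, f, transform="logit")
            lo, hi = 100.0 * lo, 100.0 * hi
        rows.append(
            {"trait": name, "h2_pct": 100.0 * frac[i], "ci_low": lo, "ci_high": hi}
        )
    return pd.DataFrame(rows)


def variance_percent(result: FitResult) -> pd.DataFrame:
    """Factor-by-trait percentages of phenotypic variance.

    Entry (factor k of component X, trait i) is 100 times the squared
    standardized loading; per trait the entries of one component sum to
    that component's variance percentage, and over all components to 100.
    """
    res = standardize(result) if result.standardized is None else result
    std = res.standardized
    names = result.model.trait_names
    rows = []
    for comp in (c for c in ("A", "C", "D", "E") if c in std):
        mat = std[comp]
        for k in range(mat.shape[1]):
            col = mat[:, k]
            if not np.any(col != 0.0):
                continue
            row = {"component": comp, "factor": f"{comp}{k + 1}"}
            for i, name in enumerate(names):
                row[name] = 100.0 * col[i] ** 2
            rows.append(row)
    return pd.DataFrame(rows)


def _component_correlation(result: FitResult, component: str) -> np.ndarray:
    """Correlation matrix of one latent component.

    Structural zeros (a trait with no variance from the component) get 0
    off-diagonal by convention and 1 on the diagonal.
    """
    sig = result.component_covariances()[component]
    d = np.diag(sig).copy()
    p = d.size
    corr = np.eye(p)
    for i in range(p):
        for j in range(i):
            if d[i] <= 1e-12 or d[j] <= 1e-12:
                if abs(sig[i, j]) > 1e-8:
                    raise ValueError(
                        "nonzero component covariance with zero variance"
                    )
                corr[i, j] = corr[j, i] = 0.0
            else:
                corr[i, j] = corr[j, i] = sig[i, j] / np.sqrt(d[i] * d[j])
    return corr


def genetic_correlations(result: FitResult) -> pd.DataFrame:
    """rG matrix: correlation of additive-genetic effects across traits."""
    names = result.model.trait_names
    return pd.DataFrame(
        _component_correlation(result, "A"), index=names, columns=names
    )


def environmental_correlations(result: FitResult) -> pd.DataFrame:
    """rE matrix for the non-shared environmental component."""
    names = result.model.trait_names
    return pd.DataFrame(
        _component_correlation(result, "E"), index=names, columns=names
    )


def shared_genetic_variance(result: FitResult, target: str) -> pd.DataFrame:
    """Attribution of a trait's genetic variance to Cholesky sources.

    Each genetic factor first loads on one trait (in declaration order);
    the share attributed to source trait j is the squared standardized
    genetic cross-path from factor j to the target, renormalized so the
    shares across contributing sources (including the target-specific
    factor) sum to 100%.  This attribution depends on the declared trait
    ordering, which is recorded in the output.
    """
    model = result.model
    if model.structure != "cholesky":
        raise ValueError("shared-variance attribution requires a Cholesky fit")
    names = list(model.trait_names)
    if target not in names:
        raise ValueError(f"unknown trait {target!r}")
    t = names.index(target)
    res = standardize(result) if result.standardized is None else result
    a_std = res.standardized["A"]
    loads = a_std[t, : t + 1] ** 2
    total = loads.sum()
    if total <= 1e-12:
        raise ValueError(f"{target!r} has no genetic variance")
    rows = [
        {
            "target": target,
            "source": names[j],
            "kind": "specific" if j == t else "cross",
            "share_pct": 100.0 * loads[j] / total,
            "ordering": ">".join(names),
        }
        for j in range(t + 1)
    ]
    return pd.DataFrame(rows)


@dataclass
class DecompositionReport:
    heritability: pd.DataFrame
    variance_percent: pd.DataFrame
    rg: pd.DataFrame
    re: pd.DataFrame
    shared_genetic: pd.DataFrame | None
    ordering: tuple[str, ...]

    def to_dict(self) -> dict:
        out = {
            "ordering": list(self.ordering),
            "heritability": self.heritability.to_dict(orient="records"),
            "variance_percent": self.variance_percent.to_dict(orient="records"),
            "rg": self.rg.to_dict(),
            "re": self.re.to_dict(),
        }
        if self.shared_genetic is not None:
            out["shared_genetic"] = self.shared_genetic.to_dict(orient="records")
        return out


def decompose(result: FitResult, shared_target: str | None = None) -> DecompositionReport:
    """Full decomposition report for a converged structured fit."""
    shared = None
    if shared_target is not None and result.model.structure == "cholesky":
        shared = shared_genetic_variance(result, shared_target)
    return DecompositionReport(
        heritability=heritability(result),
        variance_percent=variance_percent(result),
        rg=genetic_correlations(result),
        re=environmental_correlations(result),
        shared_genetic=shared,
        ordering=result.model.trait_names,
    )
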