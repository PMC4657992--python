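"""Likelihood-ratio tests, AIC and the four-step model-comparison ladder.

The ladder mirrors standard multivariate twin-modelling practice:

1. full ACE and ADE Cholesky models against the saturated model
   (assumption check: equal means/variances across twin order and
   zygosity should not be rejected), choosing ACE vs ADE by AIC;
2. the AE Cholesky against the chosen full model (can C or D be dropped?);
3. AE independent-pathway and common-pathway variants against the AE
   Cholesky base;
4. user-declared reduced Cholesky submodels (drop lists) against the full
   base.

The selected model is the lowest-AIC candidate not rejected by the LRT at
alpha = 0.05, with AIC ties broken toward fewer parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .data import TwinDataset
from .fiml import FitOptions, FitResult, fit
from .models import ModelSpec, PhenotypeSpec

__all__ = ["ComparisonTable", "chi2_sf", "lrt", "aic", "four_step_compare"]

_NEG_TOL = 1e-3


def chi2_sf(x: float, df: int) -> float:
    """Upper-tail chi-square probability."""
    if x < 0:
        raise ValueError("chi-square statistic must be non-negative")
    if df <= 0:
        raise ValueError("df must be positive")
    return float(chi2.sf(x, df))


def lrt(fit_sub: FitResult, fit_full: FitResult) -> tuple[float, int, float | None]:
    """Likelihood-ratio test of a nested submodel against a fuller model.

    Returns (delta -2lnL, delta df, p); p is None for a zero-df comparison.
    """
    delta = fit_sub.minus2LL - fit_full.minus2LL
    df = fit_full.k - fit_sub.k
    if df < 0:
        raise ValueError("submodel has more parameters than the full model")
    if delta < -_NEG_TOL:
        raise ValueError(
            f"submodel fits better than the full model (delta={delta:.4f}); "
            "optimization of the full model likely failed"
        )
    delta = max(delta, 0.0)
    if df == 0:
        return delta, 0, None
    return delta, df, chi2_sf(delta, df)


def aic(fit_result: FitResult) -> float:
    """Akaike information criterion, -2lnL + 2k."""
    return fit_result.minus2LL + 2.0 * fit_result.k


@dataclass
class ComparisonTable:
    """LRT/AIC rows of candidate models against a base model."""

    base: str
    rows: list[dict] = field(default_factory=list)

    def add(self, name: str, fit_sub: FitResult, fit_full: FitResult,
            step: int) -> None:
        delta, df, p = lrt(fit_sub, fit_full)
        self.rows.append(
            {
                "model": name,
                "step": step,
                "delta_m2ll": delta,
                "delta_df": df,
                "p": p,
                "aic": aic(fit_sub),
                "converged": fit_sub.converged,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def four_step_compare(
    data: TwinDataset,
    phenotypes: tuple[PhenotypeSpec, ...] | None = None,
    reduced_drops: dict[str, list[str]] | None = None,
    fits: dict[str, FitResult] | None = None,
    include_saturated: bool = True,
    include_acde_choice: bool = True,
    ip_cp_sets: tuple[int, ...] = (1, 2),
    alpha: float = 0.05,
    include_age: bool = True,
    options: FitOptions | None = None,
) -> tuple[pd.DataFrame, str, dict[str, FitResult]]:
    """Run (or assemble) the four-step ladder.

    ``fits`` may supply precomputed :class:`FitResult` objects under the
    canonical names (``saturated``, ``cholesky_ACE``, ``cholesky_ADE``,
    ``cholesky_AE``, ``ip1_AE``, ``ip2_AE``, ``cp1_AE``, ``cp2_AE`` and the
    keys of ``reduced_drops``); anything missing is fitted here.

    Returns (comparison frame, selected model name, fits dict).
    """
    phenos = tuple(phenotypes or (data.phenotypes if data is not None else ()))
    fits = dict(fits or {})
    opts = options or FitOptions()

    def get(name: str, spec: ModelSpec) -> FitResult:
        if name not in fits:
            fits[name] = fit(spec, data, opts)
        return fits[name]

    def spec(structure, components=("A", "E"), drops=(), n_factors=1):
        s = ModelSpec(
            structure=structure,
            phenotypes=phenos,
            components=tuple(components),
            n_factors=n_factors,
            include_age=include_age,
        )
        return s.with_drops(drops) if drops else s

    table_rows = []

    # step 1: full Cholesky models vs saturated; pick ACE vs ADE by AIC
    full_candidates = {}
    for comps in (("A", "C", "E"), ("A", "D", "E")) if include_acde_choice else (
        ("A", "E"),
    ):
        name = "cholesky_" + "".join(comps)
        full_candidates[name] = get(name, spec("cholesky", comps))
    if include_saturated:
        sat = get("saturated", spec("saturated"))
        t1 = ComparisonTable("saturated")
        for name, f in full_candidates.items():
            t1.add(name, f, sat, step=1)
        table_rows += t1.rows
    base_name = min(
        full_candidates, key=lambda n: (aic(full_candidates[n]), full_candidates[n].k)
    )
    base = full_candidates[base_name]

    # step 2: drop C/D
    t = ComparisonTable(base_name)
    ae = get("cholesky_AE", spec("cholesky"))
    t.add("cholesky_AE", ae, base, step=2)

    # step 3: IP/CP variants vs the full base
    for n_f in ip_cp_sets:
        t.add(f"ip{n_f}_AE", get(f"ip{n_f}_AE",
                                 spec("independent_pathway", n_factors=n_f)),
              base, step=3)
        t.add(f"cp{n_f}_AE", get(f"cp{n_f}_AE",
                                 spec("common_pathway", n_factors=n_f)),
              base, step=3)

    # step 4: user-declared reduced submodels
    for name, drops in (reduced_drops or {}).items():
        t.add(name, get(name, spec("cholesky", drops=drops)), base, step=4)
    table_rows += t.rows

    frame = pd.DataFrame(table_rows)
    # AIC identity check column: AIC_sub - AIC_base - (delta - 2 df) == 0
    base_aic = aic(base)
    frame["aic_identity_gap"] = np.where(
        frame["step"] > 1,
        frame["aic"] - (base_aic + frame["delta_m2ll"] - 2 * frame["delta_df"]),
        np.nan,
    )

    candidates = {base_name: base}
    for _, row in frame[frame["step"] > 1].iterrows():
        p_val = row["p"]
        if p_val is None or (isinstance(p_val, float) and np.isnan(p_val)) or p_val >= alpha:
            candidates[row["model"]] = fits[row["model"]]
    selected = min(
        sorted(candidates), key=lambda n: (aic(candidates[n]), candidates[n].k, n)
    )
    return frame, selected, fits
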