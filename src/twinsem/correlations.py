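"""Phenotypic and cross-twin cross-trait (CTCT) correlations.

The correlation type follows the measurement scales of the pair of
variables: Pearson between two continuous traits, tetrachoric between two
dichotomous traits (maximum-likelihood latent correlation of a thresholded
bivariate normal) and biserial between a continuous and a dichotomous
trait (maximum-likelihood latent-normal estimator, consistent with the
liability-threshold model used throughout).

CTCT matrices are double-entered — both twin orderings pooled — because
twin order is arbitrary; that makes the matrix exactly symmetric.  CIs are
Fisher-z for Pearson and a seeded nonparametric bootstrap over pairs for
tetrachoric, biserial and all CTCT entries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import ndtr, ndtri
from scipy.stats import norm, pearsonr

from ._mvn import mvn_rectangle_prob
from .data import TwinDataset

__all__ = [
    "CorrelationEstimate",
    "pearson_corr",
    "tetrachoric_corr",
    "biserial_corr",
    "phenotypic_corr_matrix",
    "ctct_matrix",
]

_RHO_BOUND = 0.999


@dataclass
class CorrelationEstimate:
    value: float
    method: str  # pearson | tetrachoric | biserial
    n: int
    ci_low: float = np.nan
    ci_high: float = np.nan
    boundary: bool = False

    def __post_init__(self):
        if not -1.0 <= self.value <= 1.0:
            raise ValueError(f"correlation {self.value} outside [-1,1]")


def _pairwise_complete(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m = ~(np.isnan(x) | np.isnan(y))
    return x[m], y[m]


# ---------------------------------------------------------------------
# scalar estimators
# ---------------------------------------------------------------------

def pearson_corr(x, y, ci: bool = True) -> CorrelationEstimate:
    """Product-moment correlation with a Fisher-z 95% interval."""
    x, y = _pairwise_complete(x, y)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("zero variance")
    r = float(pearsonr(x, y).statistic)
    lo = hi = np.nan
    if ci and n > 3:
        z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
        se = 1.0 / np.sqrt(n - 3)
        zq = norm.ppf(0.975)
        lo, hi = float(np.tanh(z - zq * se)), float(np.tanh(z + zq * se))
    return CorrelationEstimate(r, "pearson", n, lo, hi)


def _tetra_table(x, y) -> np.ndarray:
    """2x2 counts with cell [i][j] = #(x == i, y == j)."""
    x = np.asarray(x); y = np.asarray(y)
    return np.array(
        [
            [np.sum((x == 0) & (y == 0)), np.sum((x == 0) & (y == 1))],
            [np.sum((x == 1) & (y == 0)), np.sum((x == 1) & (y == 1))],
        ],
        dtype=float,
    )


def tetrachoric_negll(rho: float, table: np.ndarray, tau1: float, tau2: float) -> float:
    """Negative multinomial log-likelihood of a 2x2 table under a
    thresholded bivariate normal with correlation ``rho``."""
    cov = np.array([[1.0, rho], [rho, 1.0]])
    lims = {0: (-np.inf, 0.0), 1: (0.0, np.inf)}
    lower = []
    upper = []
    for i in (0, 1):
        for j in (0, 1):
            lo1, up1 = lims[i]
            lo2, up2 = lims[j]
            lower.append([tau1 + lo1 if np.isfinite(lo1) else -np.inf,
                          tau2 + lo2 if np.isfinite(lo2) else -np.inf])
            upper.append([tau1 + up1 if np.isfinite(up1) else np.inf,
                          tau2 + up2 if np.isfinite(up2) else np.inf])
    probs = mvn_rectangle_prob(np.array(lower), np.array(upper), cov,
                               n_points=4096)
    probs = np.clip(probs, 1e-12, 1.0)
    counts = np.array([table[0, 0], table[0, 1], table[1, 0], table[1, 1]])
    return float(-(counts * np.log(probs)).sum())


def tetrachoric_corr(table, ci: bool = False, n_boot: int = 1000,
                     seed: int = 0) -> CorrelationEstimate:
    """ML tetrachoric correlation from a 2x2 table (thresholds from margins)."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    n = table.sum()
    if np.any(table.sum(axis=0) <= 0) or np.any(table.sum(axis=1) <= 0):
        raise ValueError("zero margin in 2x2 table")
    p1 = table[1, :].sum() / n  # P(x=1)
    p2 = table[:, 1].sum() / n  # P(y=1)
    tau1 = float(ndtri(1.0 - p1))
    tau2 = float(ndtri(1.0 - p2))
    # perfect concordance/discordance solves at the boundary
    if table[0, 1] == 0 and table[1, 0] == 0:
        return CorrelationEstimate(1.0, "tetrachoric", int(n), boundary=True)
    if table[0, 0] == 0 and table[1, 1] == 0:
        return CorrelationEstimate(-1.0, "tetrachoric", int(n), boundary=True)
    res = minimize_scalar(
        tetrachoric_negll,
        bounds=(-_RHO_BOUND, _RHO_BOUND),
        method="bounded",
        args=(table, tau1, tau2),
        options={"xatol": 1e-6},
    )
    rho = float(res.x)
    boundary = abs(rho) >= _RHO_BOUND - 1e-4
    lo = hi = np.nan
    if ci:
        lo, hi = _bootstrap_table_ci(table, n_boot, seed)
    return CorrelationEstimate(rho, "tetrachoric", int(n), lo, hi, boundary)


def _bootstrap_table_ci(table, n_boot, seed):
    rng = np.random.default_rng(seed)
    n = int(table.sum())
    probs = (table / n).ravel()
    vals = []
    for _ in range(n_boot):
        counts = rng.multinomial(n, probs).reshape(2, 2).astype(float)
        if np.any(counts.sum(axis=0) <= 0) or np.any(counts.sum(axis=1) <= 0):
            continue
        vals.append(tetrachoric_corr(counts).value)
    if not vals:
        return np.nan, np.nan
    return tuple(np.percentile(vals, [2.5, 97.5]))


def _biserial_negll(params, x, y):
    mu, log_sigma, tau, zrho = params
    sigma = np.exp(log_sigma)
    rho = np.tanh(zrho)
    z = (x - mu) / sigma
    denom = np.sqrt(max(1.0 - rho**2, 1e-12))
    arg = (rho * z - tau) / denom
    # P(y=1 | x) = Phi((rho z - tau)/sqrt(1-rho^2))
    p1 = np.clip(ndtr(arg), 1e-12, 1.0 - 1e-12)
    ll = (
        -0.5 * (np.log(2 * np.pi) + z**2) - log_sigma
        + np.where(y > 0.5, np.log(p1), np.log(1.0 - p1))
    )
    return float(-ll.sum())


def biserial_corr(x, y, ci: bool = False, n_boot: int = 1000,
                  seed: int = 0) -> CorrelationEstimate:
    """ML latent correlation between a continuous variable and a
    dichotomized normal (point-polyserial ML)."""
    x, y = _pairwise_complete(x, y)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(x) == 0.0:
        raise ValueError("zero variance of the continuous variable")
    prev = y.mean()
    if prev in (0.0, 1.0):
        raise ValueError("dichotomous variable has a single category")
    # moment-based point-biserial start mapped to latent scale
    r_pb = np.corrcoef(x, y)[0, 1]
    tau0 = ndtri(1.0 - prev)
    r0 = np.clip(r_pb * np.sqrt(prev * (1 - prev)) / norm.pdf(tau0), -0.95, 0.95)
    x0 = np.array([x.mean(), np.log(x.std()), tau0, np.arctanh(r0)])
    res = minimize(_biserial_negll, x0, args=(x, y), method="L-BFGS-B")
    rho = float(np.tanh(res.x[3]))
    boundary = abs(rho) >= _RHO_BOUND
    if boundary:
        rho = float(np.clip(rho, -1.0, 1.0))
    lo = hi = np.nan
    if ci:
        rng = np.random.default_rng(seed)
        vals = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            yb = y[idx]
            if yb.mean() in (0.0, 1.0):
                continue
            vals.append(biserial_corr(x[idx], yb).value)
        if vals:
            lo, hi = np.percentile(vals, [2.5, 97.5])
    return CorrelationEstimate(rho, "biserial", n, lo, hi, boundary)


# ---------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------

def _estimate(x, y, binary_x: bool, binary_y: bool) -> CorrelationEstimate:
    if binary_x and binary_y:
        return tetrachoric_corr(_tetra_table(*_pairwise_complete(x, y)))
    if binary_x != binary_y:
        if binary_x:
            x, y = y, x
        return biserial_corr(x, y)
    return pearson_corr(x, y, ci=False)


def phenotypic_corr_matrix(data: TwinDataset) -> pd.DataFrame:
    """Individual-level trait-by-trait correlations, method per scale pair."""
    p = data.p
    names = data.trait_names
    binary = [ph.binary for ph in data.phenotypes]
    vals = data.values()
    stacked = np.vstack([vals[:, :p], vals[:, p:]])  # individuals x traits
    rows = []
    for i in range(p):
        for j in range(i):
            est = _estimate(stacked[:, i], stacked[:, j], binary[i], binary[j])
            rows.append(
                {
                    "trait_1": names[i],
                    "trait_2": names[j],
                    "r": est.value,
                    "method": est.method,
                    "n": est.n,
                }
            )
    return pd.DataFrame(rows)


def ctct_matrix(
    data: TwinDataset,
    zygosity: str,
    ci: bool = False,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-twin cross-trait correlation matrix for one zygosity group.

    Entry (i, j) correlates trait i in one twin with trait j in the co-twin,
    pooled over both twin orderings (double entry); the diagonal is the
    cross-twin within-trait correlation.  Returns a tidy frame with value,
    method, n and (optionally bootstrap) CI columns; pivot on
    ``trait_1``/``trait_2`` for the matrix layout.
    """
    p = data.p
    names = data.trait_names
    binary = [ph.binary for ph in data.phenotypes]
    vals = data.values(zygosity)
    t1, t2 = vals[:, :p], vals[:, p:]

    def entry(i, j, v1, v2):
        x = np.concatenate([v1[:, i], v2[:, i]])
        y = np.concatenate([v2[:, j], v1[:, j]])
        return _estimate(x, y, binary[i], binary[j])

    rows = []
    rng = np.random.default_rng(seed)
    n_pairs = t1.shape[0]
    for i in range(p):
        for j in range(p):
            if j > i:
                continue
            est = entry(i, j, t1, t2)
            lo = hi = np.nan
            if ci:
                boot = []
                for _ in range(n_boot):
                    idx = rng.integers(0, n_pairs, n_pairs)
                    try:
                        boot.append(entry(i, j, t1[idx], t2[idx]).value)
                    except ValueError:
                        continue
                if boot:
                    lo, hi = np.percentile(boot, [2.5, 97.5])
            rows.append(
                {
                    "trait_1": names[i],
                    "trait_2": names[j],
                    "zygosity": zygosity,
                    "r": est.value,
                    "method": est.method,
                    "n": est.n,
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
    return pd.DataFrame(rows)


def ctct_square(frame: pd.DataFrame, names) -> np.ndarray:
    """Symmetric p x p array from a tidy ctct frame."""
    p = len(names)
    mat = np.full((p, p), np.nan)
    pos = {n: i for i, n in enumerate(names)}
    for _, row in frame.iterrows():
        i, j = pos[row["trait_1"]], pos[row["trait_2"]]
        mat[i, j] = mat[j, i] = row["r"]
    return mat
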