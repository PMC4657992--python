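"""Full-information maximum likelihood for mixed binary/continuous twin pairs.

Each pair contributes the likelihood of exactly its observed values: the
multivariate-normal density of the observed continuous entries times the
probability of the rectangle of the conditional latent normal consistent
with the observed 0/1 pattern of the binary entries.  Missing entries are
marginalized by dropping rows/columns of the expected moments, so pairs
with a missing co-twin are retained without imputation.

Binary liabilities are identified by unit total variance: the likelihood
standardizes binary rows of the implied covariance internally (making it
exactly invariant to their scale) and a small quadratic gauge penalty pins
the implied variance at 1, which removes the flat direction without
touching the maximized likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.stats import chi2, norm

from ._mvn import mvn_rectangle_prob
from .data import TwinDataset
from .models import (
    DZ,
    MZ,
    ExpectedMoments,
    ModelSpec,
    Parameterization,
    count_free_parameters,
    structural_parameter_count,
)

__all__ = [
    "FitOptions",
    "FitResult",
    "pair_loglik",
    "total_minus2LL",
    "fit",
    "standardize",
    "delta_ci",
    "profile_ci",
    "saturated_gaussian_minus2ll",
]

_LOG2PI = np.log(2.0 * np.pi)
_TINY = 1e-300


@dataclass
class FitOptions:
    """Optimizer and likelihood settings.

    Five jittered quasi-Newton starts are the default; reduce ``n_starts``
    (and supply ``start_theta``) in large replicate studies.  ``qmc_points``
    controls the accuracy of binary-block rectangle probabilities.
    """

    n_starts: int = 5
    seed: int = 0
    jitter: float = 0.15
    maxiter: int = 2000
    grad_eps: float = 1e-6
    ftol: float = 1e-10
    gtol: float = 1e-6
    qmc_points: int = 2048
    qmc_seed: int = 2026
    penalty_weight: float = 100.0
    compute_ci: bool = False
    ci_level: float = 0.95
    start_theta: np.ndarray | None = None


# ---------------------------------------------------------------------
# likelihood evaluation
# ---------------------------------------------------------------------

def _standardized(mom: ExpectedMoments):
    """Standardize binary rows to unit variance (scale-invariant form)."""
    sd = np.sqrt(np.diag(mom.cov))
    s = np.where(mom.binary, 1.0 / sd, 1.0)
    cov = mom.cov * np.outer(s, s)
    return mom.mean * s, cov, mom.thresholds, mom.beta * s


class _PatternGroup:
    __slots__ = ("zyg", "idx", "cont", "binv", "y_cont", "y_bin", "agec")

    def __init__(self, zyg, idx, cont, binv, y_cont, y_bin, agec):
        self.zyg = zyg
        self.idx = idx          # observed columns in the 2p layout
        self.cont = cont        # continuous positions within idx
        self.binv = binv        # binary positions within idx
        self.y_cont = y_cont    # (n, n_cont)
        self.y_bin = y_bin      # (n, n_bin) of 0/1
        self.agec = agec        # (n, n_obs) centered age per observed entry


def _build_groups(model: ModelSpec, data: TwinDataset, age_center: float):
    p = model.p
    vals = data.values()
    ages = data.ages()
    ages = np.where(np.isnan(ages), age_center, ages)
    agec = ages - age_center
    age_entry = np.repeat(agec, p, axis=1)  # (n, 2p): twin-1 age x p, twin-2 age x p
    binary2p = np.concatenate([model.binary_mask, model.binary_mask])
    zygs = data.df["zygosity"].to_numpy()

    obs = ~np.isnan(vals)
    if (~obs).all(axis=1).any():
        raise ValueError("a pair with no observed values cannot contribute")
    groups = []
    keys = {}
    for r in range(vals.shape[0]):
        key = (zygs[r], obs[r].tobytes())
        keys.setdefault(key, []).append(r)
    for (zyg, _), rows in keys.items():
        rows = np.asarray(rows)
        mask = obs[rows[0]]
        idx = np.flatnonzero(mask)
        is_bin = binary2p[idx]
        cont = np.flatnonzero(~is_bin)
        binv = np.flatnonzero(is_bin)
        sub = vals[np.ix_(rows, idx)]
        groups.append(
            _PatternGroup(
                zyg,
                idx,
                cont,
                binv,
                sub[:, cont],
                sub[:, binv],
                age_entry[np.ix_(rows, idx)],
            )
        )
    return groups


def _group_loglik(g: _PatternGroup, mean, cov, thr, beta, qmc_points, qmc_seed):
    """Sum of pair log-likelihoods for one missing-pattern group."""
    idx = g.idx
    mu = mean[idx][None, :] + beta[idx][None, :] * g.agec  # (n, n_obs)
    sig = cov[np.ix_(idx, idx)]
    n = mu.shape[0]
    ll = 0.0

    if g.cont.size:
        scc = sig[np.ix_(g.cont, g.cont)]
        try:
            cf = cho_factor(scc, lower=True)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise np.linalg.LinAlgError(
                "singular observed-submatrix covariance"
            ) from exc
        logdet = 2.0 * np.log(np.diag(cf[0])).sum()
        resid = g.y_cont - mu[:, g.cont]
        solved = cho_solve(cf, resid.T)  # (n_cont, n)
        quad = np.einsum("ij,ji->i", resid, solved)
        ll += -0.5 * (g.cont.size * _LOG2PI + logdet) * n - 0.5 * quad.sum()

    if g.binv.size:
        if g.cont.size:
            sbc = sig[np.ix_(g.binv, g.cont)]
            w = cho_solve(cf, sbc.T)  # (n_cont, n_bin)
            cond_cov = sig[np.ix_(g.binv, g.binv)] - sbc @ w
            cond_mean = mu[:, g.binv] + (g.y_cont - mu[:, g.cont]) @ w
        else:
            cond_cov = sig[np.ix_(g.binv, g.binv)]
            cond_mean = mu[:, g.binv]
        tau = thr[idx][g.binv][None, :] - cond_mean  # (n, n_bin)
        lower = np.where(g.y_bin > 0.5, tau, -np.inf)
        upper = np.where(g.y_bin > 0.5, np.inf, tau)
        prob = mvn_rectangle_prob(
            lower, upper, cond_cov, n_points=qmc_points, seed=qmc_seed
        )
        ll += np.log(np.maximum(np.atleast_1d(prob), _TINY)).sum()
    return ll


def total_minus2LL(
    model: ModelSpec,
    theta: Sequence[float],
    data: TwinDataset,
    age_center: float | None = None,
    qmc_points: int = 2048,
    qmc_seed: int = 2026,
    _par: Parameterization | None = None,
    _groups=None,
) -> float:
    """-2 log-likelihood of the data under the model at ``theta``."""
    par = _par or Parameterization(model)
    if age_center is None:
        ages = data.ages()
        age_center = float(np.nanmean(ages)) if model.include_age else 0.0
    groups = _groups if _groups is not None else _build_groups(model, data, age_center)
    mom = par.moments(np.asarray(theta, dtype=float))
    std = {z: _standardized(mom[z]) for z in (MZ, DZ)}
    ll = 0.0
    for g in groups:
        mean, cov, thr, beta = std[g.zyg]
        ll += _group_loglik(g, mean, cov, thr, beta, qmc_points, qmc_seed)
    return -2.0 * ll


def pair_loglik(
    values: Sequence[float],
    moments: ExpectedMoments,
    ages: Sequence[float] = (0.0, 0.0),
    qmc_points: int = 8192,
    qmc_seed: int = 2026,
) -> float:
    """Log-likelihood of one pair's observed values (NaN = missing).

    ``values`` has length 2p (twin-1 traits then twin-2 traits); ``ages``
    are the two twins' centered ages.
    """
    values = np.asarray(values, dtype=float)
    p = moments.p
    if values.shape != (2 * p,):
        raise ValueError(f"values must have length {2 * p}")
    obs = ~np.isnan(values)
    if not obs.any():
        raise ValueError("pair has no observed values")
    mean, cov, thr, beta = _standardized(moments)
    idx = np.flatnonzero(obs)
    is_bin = moments.binary[idx]
    age_entry = np.repeat(np.asarray(ages, dtype=float), p)[idx][None, :]
    g = _PatternGroup(
        None,
        idx,
        np.flatnonzero(~is_bin),
        np.flatnonzero(is_bin),
        values[idx][~is_bin][None, :],
        values[idx][is_bin][None, :],
        age_entry,
    )
    return float(_group_loglik(g, mean, cov, thr, beta, qmc_points, qmc_seed))


def _gauge_penalty(par: Parameterization, theta: np.ndarray, weight: float) -> float:
    model = par.model
    if not model.binary_mask.any() or weight == 0.0:
        return 0.0
    mom = par.moments(theta)
    pen = 0.0
    if model.structure == "saturated":
        for z in (MZ, DZ):
            v = np.diag(mom[z].cov)[mom[z].binary]
            pen += float(((v - 1.0) ** 2).sum())
    else:
        v = np.diag(mom[MZ].cov)[mom[MZ].binary]
        pen = float(((v - 1.0) ** 2).sum())
    return weight * pen


def saturated_gaussian_minus2ll(values_by_group: dict[str, np.ndarray]) -> float:
    """Closed-form saturated -2lnL for complete continuous data.

    ``values_by_group`` maps group label to an (n, q) matrix; the saturated
    Gaussian optimum is the sample mean and ML covariance per group.
    """
    total = 0.0
    for arr in values_by_group.values():
        arr = np.asarray(arr, dtype=float)
        n, q = arr.shape
        cov = np.cov(arr, rowvar=False, bias=True)
        sign, logdet = np.linalg.slogdet(np.atleast_2d(cov))
        total += n * (q * _LOG2PI + logdet + q)
    return float(total)


# ---------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------

@dataclass
class FitResult:
    """A converged FIML solution."""

    model: ModelSpec
    param_names: list[str]
    theta: np.ndarray
    minus2LL: float
    k: int
    k_structural: int
    converged: bool
    boundary: bool
    n_pairs: int
    age_center: float
    n_starts_converged: int = 0
    theta_cov: np.ndarray | None = None
    ci: pd.DataFrame | None = None
    standardized: dict | None = None
    options: FitOptions | None = None

    @property
    def parameterization(self) -> Parameterization:
        return Parameterization(self.model)

    def estimates(self) -> dict[str, float]:
        return dict(zip(self.param_names, self.theta))

    def component_covariances(self) -> dict[str, np.ndarray]:
        return self.parameterization.component_covariances(self.theta)

    def phenotypic_cov(self) -> np.ndarray:
        """Implied within-twin p x p phenotypic covariance."""
        return sum(self.component_covariances().values())

    def aic(self) -> float:
        return self.minus2LL + 2.0 * self.k

    def to_dict(self) -> dict:
        out = {
            "structure": self.model.structure,
            "components": list(self.model.components),
            "minus2LL": self.minus2LL,
            "k": self.k,
            "k_structural": self.k_structural,
            "aic": self.aic(),
            "converged": self.converged,
            "boundary": self.boundary,
            "n_pairs": self.n_pairs,
            "estimates": {n: float(v) for n, v in self.estimates().items()},
        }
        if self.ci is not None:
            out["ci"] = self.ci.to_dict(orient="index")
        return out


def _data_summary(model: ModelSpec, data: TwinDataset) -> dict:
    p = model.p
    vals = data.values()
    means = np.zeros(p)
    variances = np.ones(p)
    for i, ph in enumerate(model.phenotypes):
        col = vals[:, [i, p + i]]
        obsd = col[~np.isnan(col)]
        if ph.binary:
            prev = float(np.clip(obsd.mean(), 1e-3, 1 - 1e-3)) if obsd.size else 0.5
            means[i] = norm.ppf(1.0 - prev)
        else:
            means[i] = float(obsd.mean()) if obsd.size else 0.0
            variances[i] = float(obsd.var()) if obsd.size > 1 else 1.0
    summary = {"means": means, "variances": variances}
    if model.structure == "saturated":
        binary2p = np.concatenate([model.binary_mask, model.binary_mask])
        for z in (MZ, DZ):
            sub = pd.DataFrame(data.values(z))
            cov = sub.cov(min_periods=2).to_numpy()
            cov = np.where(np.isnan(cov), 0.0, cov)
            d = np.sqrt(np.clip(np.diag(cov), 1e-3, None))
            s = np.where(binary2p, 1.0 / d, 1.0)
            cov = cov * np.outer(s, s)
            np.fill_diagonal(cov, np.where(binary2p, 1.0, np.diag(cov)))
            mean = np.concatenate([means, means])
            summary[f"cov_{z}"] = cov + 0.05 * np.eye(2 * p)
            summary[f"mean_{z}"] = mean
    return summary


def fit(
    model: ModelSpec,
    data: TwinDataset,
    options: FitOptions | None = None,
) -> FitResult:
    """Minimize the FIML -2lnL with multiple jittered quasi-Newton starts."""
    opts = options or FitOptions()
    par = Parameterization(model)
    if data.n_pairs == 0:
        raise ValueError("empty dataset")
    age_center = (
        float(np.nanmean(data.ages())) if model.include_age else 0.0
    )
    groups = _build_groups(model, data, age_center)
    weight = opts.penalty_weight if model.binary_mask.any() else 0.0

    def objective(theta):
        try:
            val = total_minus2LL(
                model,
                theta,
                data,
                age_center=age_center,
                qmc_points=opts.qmc_points,
                qmc_seed=opts.qmc_seed,
                _par=par,
                _groups=groups,
            )
        except np.linalg.LinAlgError:
            return 1e12
        if not np.isfinite(val):
            return 1e12
        return val + _gauge_penalty(par, theta, weight)

    rng = np.random.default_rng(opts.seed)
    base = (
        np.asarray(opts.start_theta, dtype=float)
        if opts.start_theta is not None
        else par.start(_data_summary(model, data))
    )
    starts = [base]
    for _ in range(opts.n_starts - 1):
        starts.append(
            base + opts.jitter * (np.abs(base) + 0.3) * rng.standard_normal(base.size)
        )

    best = None
    n_ok = 0
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            method="L-BFGS-B",
            options={
                "maxiter": opts.maxiter,
                "ftol": opts.ftol,
                "gtol": opts.gtol,
                "eps": opts.grad_eps,
            },
        )
        if res.success:
            n_ok += 1
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("no optimizer start produced a finite solution")

    theta = par.normalize_signs(best.x)
    m2ll = total_minus2LL(
        model,
        theta,
        data,
        age_center=age_center,
        qmc_points=opts.qmc_points,
        qmc_seed=opts.qmc_seed,
        _par=par,
        _groups=groups,
    )

    boundary = False
    if model.structure == "common_pathway":
        shares = [abs(np.tanh(theta[par.index(f"cp{k}_ashare")]))
                  for k in range(1, model.n_factors + 1)]
        boundary = any(s > 0.999 for s in shares)
    if model.structure != "saturated":
        comps = par.component_covariances(theta)
        tot = np.diag(sum(comps.values()))
        for c, sig in comps.items():
            with np.errstate(invalid="ignore", divide="ignore"):
                frac = np.diag(sig) / tot
            if np.any(frac > 0.999) and c != "E" and len(comps) > 1:
                boundary = boundary or bool(np.any(np.diag(sig) / tot > 0.9999))

    result = FitResult(
        model=model,
        param_names=list(par.names),
        theta=theta,
        minus2LL=float(m2ll),
        k=count_free_parameters(model, effective=True),
        k_structural=structural_parameter_count(model),
        converged=n_ok > 0,
        boundary=boundary,
        n_pairs=data.n_pairs,
        age_center=age_center,
        n_starts_converged=n_ok,
        options=opts,
    )
    if opts.compute_ci:
        result = _with_wald_ci(result, objective, opts)
    return result


def _num_hessian(f: Callable[[np.ndarray], float], x: np.ndarray, rel: float = 1e-4):
    n = x.size
    h = rel * (1.0 + np.abs(x))
    hess = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                xp = x.copy(); xp[i] += h[i]
                xm = x.copy(); xm[i] -= h[i]
                hess[i, i] = (f(xp) - 2.0 * f0 + f(xm)) / h[i] ** 2
            else:
                xpp = x.copy(); xpp[i] += h[i]; xpp[j] += h[j]
                xpm = x.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
                xmp = x.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
                xmm = x.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
                hess[i, j] = hess[j, i] = (
                    f(xpp) - f(xpm) - f(xmp) + f(xmm)
                ) / (4.0 * h[i] * h[j])
    return hess


def _with_wald_ci(result: FitResult, objective, opts: FitOptions) -> FitResult:
    hess = _num_hessian(objective, result.theta)
    # objective is -2lnL (+gauge); parameter covariance is 2 H^{-1}
    cov = 2.0 * np.linalg.pinv(hess)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    zq = norm.ppf(0.5 + opts.ci_level / 2.0)
    ci = pd.DataFrame(
        {
            "estimate": result.theta,
            "se": se,
            "ci_low": result.theta - zq * se,
            "ci_high": result.theta + zq * se,
        },
        index=result.param_names,
    )
    return replace(result, theta_cov=cov, ci=ci)


# ---------------------------------------------------------------------
# standardization and derived intervals
# ---------------------------------------------------------------------

def standardize(result: FitResult) -> FitResult:
    """Divide each path by the implied phenotypic SD of its row trait.

    Squared standardized entries across all factors of all components then
    sum to one per trait.
    """
    model = result.model
    if model.structure == "saturated":
        raise ValueError("saturated models have no paths to standardize")
    par = result.parameterization
    comps = result.component_covariances()
    total_sd = np.sqrt(np.diag(sum(comps.values())))
    if np.any(total_sd <= 0):
        raise ValueError("zero implied phenotypic variance")
    std: dict[str, np.ndarray] = {"_total_sd": total_sd}
    if model.structure == "cholesky":
        for c, mat in par.path_matrices(result.theta).items():
            std[c] = mat / total_sd[:, None]
    else:
        # factor loading matrices: common factors then trait-specific diag
        p = model.p
        theta = result.theta
        k = 0
        a_cols, e_cols = [], []
        if model.structure == "independent_pathway":
            for _ in range(model.n_factors):
                a_cols.append(theta[k : k + p]); k += p
                e_cols.append(theta[k : k + p]); k += p
        else:
            for _ in range(model.n_factors):
                a_lat = np.tanh(theta[k]); k += 1
                lam = theta[k : k + p]; k += p
                a_cols.append(a_lat * lam)
                e_cols.append(np.sqrt(1.0 - a_lat**2) * lam)
        sa = theta[k : k + p]; k += p
        se = theta[k : k + p]
        std["A"] = np.column_stack(a_cols + [np.diag(sa)]) / total_sd[:, None]
        std["E"] = np.column_stack(e_cols + [np.diag(se)]) / total_sd[:, None]
    return replace(result, standardized=std)


def delta_ci(
    result: FitResult,
    func: Callable[[np.ndarray], float],
    level: float = 0.95,
    transform: str | None = None,
) -> tuple[float, float, float]:
    """Wald CI for a smooth scalar function of the parameters.

    ``transform="atanh"`` builds the interval on the Fisher-z scale (for
    correlations); ``transform="logit"`` on the logit scale (for
    proportions such as h^2).
    """
    if result.theta_cov is None:
        raise ValueError("fit was run without compute_ci")
    val = float(func(result.theta))
    h = 1e-5 * (1.0 + np.abs(result.theta))
    grad = np.empty(result.theta.size)
    for i in range(result.theta.size):
        xp = result.theta.copy(); xp[i] += h[i]
        xm = result.theta.copy(); xm[i] -= h[i]
        grad[i] = (func(xp) - func(xm)) / (2.0 * h[i])
    var = float(grad @ result.theta_cov @ grad)
    se = np.sqrt(max(var, 0.0))
    zq = norm.ppf(0.5 + level / 2.0)
    if transform == "atanh" and abs(val) < 1.0:
        zv = np.arctanh(np.clip(val, -1 + 1e-12, 1 - 1e-12))
        zse = se / max(1.0 - val**2, 1e-12)
        return val, float(np.tanh(zv - zq * zse)), float(np.tanh(zv + zq * zse))
    if transform == "logit" and 0.0 < val < 1.0:
        lv = np.log(val / (1.0 - val))
        lse = se / max(val * (1.0 - val), 1e-12)
        inv = lambda u: 1.0 / (1.0 + np.exp(-u))
        return val, float(inv(lv - zq * lse)), float(inv(lv + zq * lse))
    return val, val - zq * se, val + zq * se


def profile_ci(
    model: ModelSpec,
    data: TwinDataset,
    result: FitResult,
    name: str,
    level: float = 0.95,
    options: FitOptions | None = None,
) -> tuple[float, float]:
    """Profile-likelihood interval for one named free parameter.

    Bisects on the parameter value for a -2lnL increase of the chi-square
    quantile, re-optimizing the remaining parameters at each probe.
    """
    opts = options or (result.options or FitOptions())
    par = Parameterization(model)
    j = par.index(name)
    target = result.minus2LL + chi2.ppf(level, 1)
    free = [i for i in range(par.n_free) if i != j]

    def profiled(value: float) -> float:
        def obj(sub):
            theta = result.theta.copy()
            theta[free] = sub
            theta[j] = value
            return total_minus2LL(
                model, theta, data,
                age_center=result.age_center,
                qmc_points=opts.qmc_points, qmc_seed=opts.qmc_seed, _par=par,
            ) + _gauge_penalty(par, theta, opts.penalty_weight)

        res = minimize(obj, result.theta[free], method="L-BFGS-B",
                       options={"maxiter": 200, "eps": opts.grad_eps})
        return float(res.fun)

    est = result.theta[j]
    step = 0.5 * (abs(est) + 0.5)
    bounds = []
    for direction in (-1.0, 1.0):
        lo, hi = est, est + direction * step
        for _ in range(20):
            if profiled(hi) >= target:
                break
            lo, hi = hi, hi + direction * step
        for _ in range(25):
            mid = 0.5 * (lo + hi)
            if profiled(mid) < target:
                lo = mid
            else:
                hi = mid
            if abs(hi - lo) < 1e-4 * (1 + abs(est)):
                break
        bounds.append(0.5 * (lo + hi))
    return min(bounds), max(bounds)
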