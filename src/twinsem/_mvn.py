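"""Multivariate-normal rectangle probabilities.

Deterministic quasi-Monte-Carlo evaluation of P(lower < Z < upper) for
Z ~ N(0, cov), vectorized over a batch of rectangles that share one
covariance matrix.  This is the work-horse of the liability-threshold
likelihood: every twin pair with observed binary traits contributes the
probability of one rectangle of the conditional latent normal, and pairs
with the same missing-data pattern share the conditional covariance while
their limits differ.

The algorithm is the Genz separation-of-variables transform: after a
Cholesky factorization the rectangle probability becomes an integral over
the (d-1)-dimensional unit cube, which is averaged over a scrambled Sobol
point set with a fixed seed.  With the seed fixed the result is a smooth,
deterministic function of the limits, so it can sit inside a
finite-difference optimizer.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cholesky, LinAlgError
from scipy.special import ndtr, ndtri
from scipy.stats import qmc

__all__ = ["mvn_rectangle_prob"]

# clip uniforms away from {0,1} so ndtri stays finite
_UCLIP = 1e-13
# chunk batches so the (n_points, batch) work arrays stay modest
_MAX_WORK = 8_000_000


def _chol_psd(cov: np.ndarray) -> np.ndarray:
    try:
        return cholesky(cov, lower=True)
    except LinAlgError:
        d = cov.shape[0]
        return cholesky(cov + 1e-10 * np.eye(d), lower=True)


def _sobol(dim: int, n_points: int, seed: int) -> np.ndarray:
    m = max(1, int(np.ceil(np.log2(n_points))))
    eng = qmc.Sobol(dim, scramble=True, seed=seed)
    return eng.random_base2(m)


def mvn_rectangle_prob(
    lower,
    upper,
    cov,
    n_points: int = 4096,
    seed: int = 2026,
):
    """P(lower < Z < upper) for Z ~ N(0, cov).

    Parameters
    ----------
    lower, upper
        Arrays of shape ``(d,)`` or ``(batch, d)``; ``-inf``/``inf`` allowed.
    cov
        Positive-definite ``(d, d)`` covariance shared by the batch.
    n_points
        QMC sample size (rounded up to a power of two).  4096 gives ~1e-6
        accuracy for the well-conditioned rectangles arising here; raise it
        when validating against brute-force integration.
    seed
        Seed of the Sobol scrambling; fixed by default so repeated calls are
        bit-identical.

    Returns
    -------
    float or ndarray
        Probability per rectangle (scalar when inputs are 1-D).
    """
    cov = np.asarray(cov, dtype=float)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    squeeze = lower.ndim == 1
    lower = np.atleast_2d(lower)
    upper = np.atleast_2d(upper)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("cov must be a square matrix")
    d = cov.shape[0]
    if lower.shape[1] != d or upper.shape[1] != d:
        raise ValueError("limit arrays do not match cov dimension")

    if d == 1:
        s = np.sqrt(cov[0, 0])
        p = ndtr(upper[:, 0] / s) - ndtr(lower[:, 0] / s)
        p = np.clip(p, 0.0, 1.0)
        return float(p[0]) if squeeze else p

    L = _chol_psd(cov)
    w = _sobol(d - 1, n_points, seed)  # (N, d-1)
    n = w.shape[0]

    batch = lower.shape[0]
    chunk = max(1, int(_MAX_WORK // (n * d)))
    out = np.empty(batch)
    for s0 in range(0, batch, chunk):
        s1 = min(batch, s0 + chunk)
        out[s0:s1] = _genz_chunk(lower[s0:s1], upper[s0:s1], L, w)
    out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if squeeze else out


def _genz_chunk(lower, upper, L, w):
    d = L.shape[0]
    n = w.shape[0]
    b = lower.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        clo = ndtr(lower[:, 0] / L[0, 0])  # (b,)
        chi = ndtr(upper[:, 0] / L[0, 0])
    f = np.broadcast_to(chi - clo, (n, b)).copy()
    clo = np.broadcast_to(clo, (n, b))
    chi = np.broadcast_to(chi, (n, b))
    y = np.empty((n, b, d - 1))
    for i in range(1, d):
        u = clo + w[:, i - 1][:, None] * (chi - clo)
        y[:, :, i - 1] = ndtri(np.clip(u, _UCLIP, 1.0 - _UCLIP))
        mu = y[:, :, :i] @ L[i, :i]  # (n, b)
        with np.errstate(invalid="ignore"):
            clo = ndtr((lower[:, i][None, :] - mu) / L[i, i])
            chi = ndtr((upper[:, i][None, :] - mu) / L[i, i])
        f = f * np.clip(chi - clo, 0.0, 1.0)
    return f.mean(axis=0)
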