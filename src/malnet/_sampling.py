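"""Low-level tail-distribution draws shared by the generators and the
bootstrap.  All functions take an explicit :class:`numpy.random.Generator`."""

from __future__ import annotations

import numpy as np
from scipy import special, stats


def draw_power_law_continuous(rng: np.random.Generator, n: int, alpha: float, xmin: float) -> np.ndarray:
    """Inverse-CDF draw: x = xmin * (1 - u)^(-1/(alpha-1))."""
    u = rng.random(n)
    return xmin * (1.0 - u) ** (-1.0 / (alpha - 1.0))


def power_law_continuous_ppf(u: np.ndarray, alpha: float, xmin: float) -> np.ndarray:
    return xmin * (1.0 - np.asarray(u, dtype=float)) ** (-1.0 / (alpha - 1.0))


def draw_power_law_discrete(rng: np.random.Generator, n: int, alpha: float, xmin: int) -> np.ndarray:
    """Exact draw from P(X = k) ∝ k^(-alpha), k >= xmin, by cumulative search.

    The quantile is located by a vectorized binary search on the exact
    Hurwitz-zeta CCDF, P(X >= k) = zeta(alpha, k) / zeta(alpha, xmin); the
    continuous approximation only supplies the (safe) upper bracket.
    """
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    xmin = int(xmin)
    u = rng.random(n)
    z_xmin = special.zeta(alpha, xmin)
    # want the smallest k with CCDF(k+1) <= 1-u, i.e. F(k) >= u
    target = (1.0 - u) * z_xmin
    # continuous-approximation guess for the bracket, with generous margin
    guess = (xmin - 0.5) * (1.0 - u) ** (-1.0 / (alpha - 1.0)) + 0.5
    hi = np.maximum(np.ceil(guess * 4.0), xmin + 1.0)
    hi = np.minimum(hi, 1e15)
    # ensure hi satisfies F(hi) >= u
    for _ in range(64):
        bad = special.zeta(alpha, hi + 1.0) > target
        if not bad.any():
            break
        hi[bad] = np.minimum(hi[bad] * 2.0, 1e15)
    lo = np.full(n, float(xmin) - 1.0)  # invariant: F(lo) < u
    while True:
        gap = hi - lo
        if (gap <= 1.0).all():
            break
        mid = np.floor((lo + hi) / 2.0)
        ok = special.zeta(alpha, mid + 1.0) <= target  # F(mid) >= u
        hi = np.where(ok, mid, hi)
        lo = np.where(ok, lo, mid)
    return hi.astype(np.int64)


def draw_exponential_tail(rng: np.random.Generator, n: int, lam: float, xmin: float) -> np.ndarray:
    """Left-truncated exponential: memorylessness gives xmin + Exp(lam)."""
    return xmin + rng.exponential(1.0 / lam, n)


def draw_exponential_discrete(rng: np.random.Generator, n: int, lam: float, xmin: int) -> np.ndarray:
    """P(X = k) ∝ exp(-lam k) on integers k >= xmin (shifted geometric)."""
    # X - xmin ~ Geometric with success prob 1 - e^(-lam), support {0, 1, ...}
    p = -np.expm1(-lam)
    return int(xmin) + rng.geometric(p, n).astype(np.int64) - 1


def draw_lognormal_tail(
    rng: np.random.Generator, n: int, mu: float, sigma: float, xmin: float
) -> np.ndarray:
    """Left-truncated log-normal via inverse CDF."""
    if xmin <= 0:
        return rng.lognormal(mu, sigma, n)
    phi0 = stats.norm.cdf((np.log(xmin) - mu) / sigma)
    u = phi0 + rng.random(n) * (1.0 - phi0)
    u = np.clip(u, None, 1.0 - 1e-16)
    return np.exp(mu + sigma * stats.norm.ppf(u))


def draw_lognormal_discrete(
    rng: np.random.Generator, n: int, mu: float, sigma: float, xmin: int
) -> np.ndarray:
    """Discretized log-normal: P(X = k) ∝ F(k + 1/2) - F(k - 1/2), k >= xmin."""
    lo = stats.norm.cdf((np.log(max(xmin - 0.5, 1e-12)) - mu) / sigma)
    u = lo + rng.random(n) * (1.0 - lo)
    u = np.clip(u, None, 1.0 - 1e-16)
    x = np.exp(mu + sigma * stats.norm.ppf(u))
    return np.maximum(np.round(x).astype(np.int64), int(xmin))
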