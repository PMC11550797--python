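"""Exact Polya-Gamma PG(1, z) sampling (Devroye alternating-series method).

PG(1, z) is the mixing distribution that renders Bernoulli-logistic
likelihoods conditionally Gaussian: with omega_i ~ PG(1, eta_i), the
augmented model gives conjugate normal updates for the regression
coefficients.  The sampler below is the exact rejection scheme based on the
two-piece proposal (truncated inverse-Gaussian / exponential) with the
alternating-series acceptance test; compiled with numba for per-observation
draws at MCMC speed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_TRUNC = 0.64  # series crossover point t of the Devroye scheme


@njit(cache=True)
def _norm_cdf(x):
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


@njit(cache=True)
def _rtigauss(z, t, rng):
    """Inverse-Gaussian(mu=1/z, lambda=1) truncated to (0, t)."""
    X = t + 1.0
    if z * t < 1.0:  # mu > t: rejection from truncated inverse-chi-square
        while True:
            while True:
                E1 = rng.standard_exponential()
                E2 = rng.standard_exponential()
                if E1 * E1 <= 2.0 * E2 / t:
                    break
            X = t / ((1.0 + t * E1) ** 2)
            if rng.random() <= math.exp(-0.5 * z * z * X):
                break
    else:
        mu = 1.0 / z
        while True:
            Y = rng.standard_normal()
            Y = Y * Y
            X = mu + 0.5 * mu * mu * Y - 0.5 * mu * math.sqrt(4.0 * mu * Y + (mu * Y) ** 2)
            if rng.random() > mu / (mu + X):
                X = mu * mu / X
            if X <= t:
                break
    return X


@njit(cache=True)
def _a_coef(n, x, t):
    """n-th alternating-series coefficient of the J*(1,.) density."""
    if x <= t:
        return math.pi * (n + 0.5) * (2.0 / math.pi / x) ** 1.5 \
            * math.exp(-2.0 * (n + 0.5) ** 2 / x)
    return math.pi * (n + 0.5) * math.exp(-((n + 0.5) ** 2) * math.pi ** 2 * x / 2.0)


@njit(cache=True)
def pg1_draw(zin, rng):
    """One exact draw from PG(1, z)."""
    z = abs(zin) * 0.5
    t = _TRUNC
    K = math.pi ** 2 / 8.0 + z * z / 2.0
    p = math.pi / (2.0 * K) * math.exp(-K * t)
    sqt = math.sqrt(1.0 / t)
    cdf = _norm_cdf(sqt * (t * z - 1.0)) + math.exp(2.0 * z) * _norm_cdf(-sqt * (t * z + 1.0))
    q = 2.0 * math.exp(-z) * cdf
    ratio = p / (p + q)
    while True:
        if rng.random() < ratio:
            X = t + rng.standard_exponential() / K
        else:
            X = _rtigauss(z, t, rng)
        S = _a_coef(0, X, t)
        Y = rng.random() * S
        n = 0
        accept = False
        while True:
            n += 1
            if n % 2 == 1:
                S -= _a_coef(n, X, t)
                if Y <= S:
                    accept = True
                    break
            else:
                S += _a_coef(n, X, t)
                if Y > S:
                    break
        if accept:
            return X / 4.0


@njit(cache=True)
def pg1_vector(z, rng):
    """Independent PG(1, z_i) draws for a vector of tilts."""
    out = np.empty(z.shape[0])
    for i in range(z.shape[0]):
        out[i] = pg1_draw(z[i], rng)
    return out
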