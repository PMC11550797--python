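"""Independent oracles used by the sampler tests.

These deliberately avoid the package's sampling code paths: posterior
moments come from deterministic quadrature, with the local-scale dimension
integrated out per coefficient value via the half-Cauchy CDF transform
u = (2/pi) arctan(lambda) (so the u-integral is against a uniform measure).
"""

import numpy as np
from scipy import integrate


def bernoulli_loglik(X, y, beta):
    eta = X @ np.atleast_1d(beta)
    return float(np.sum(y * -np.logaddexp(0, -eta) + (1 - y) * -np.logaddexp(0, eta)))


def horseshoe_marginal_prior(beta, tau, c):
    """Density of beta ~ N(0, tau^2 lt^2) with lambda ~ half-Cauchy(0,1)
    integrated out, for fixed tau and slab width c."""

    def f(u):
        lam = np.tan(np.pi * u / 2.0)
        lt2 = (c * c * lam * lam) / (c * c + tau * tau * lam * lam)
        var = tau * tau * lt2
        return np.exp(-0.5 * beta * beta / var) / np.sqrt(2.0 * np.pi * var)

    val, _ = integrate.quad(f, 0.0, 1.0, limit=200)
    return val


def _grid_moments(grid, weights):
    w = weights / weights.sum()
    mean = float(np.sum(grid * w))
    sd = float(np.sqrt(np.sum((grid - mean) ** 2 * w)))
    return mean, sd


def horseshoe_posterior_moments(X, y, tau, c, half_width=4.0, step=0.005):
    """Posterior mean and sd of a single coefficient under the horseshoe
    with fixed tau and c, by quadrature over (beta, lambda).

    The beta grid is offset from 0 to avoid the (integrable) log
    singularity of the marginal prior at the origin.
    """
    grid = np.arange(-half_width + step / 2.0, half_width, step)
    logw = np.array([bernoulli_loglik(X, y, b) for b in grid])
    prior = np.array([horseshoe_marginal_prior(b, tau, c) for b in grid])
    w = np.exp(logw - logw.max()) * prior
    return _grid_moments(grid, w)


def laplace_posterior_moments(X, y, scale, half_width=4.0, step=0.005):
    """Posterior mean and sd of a single coefficient under a fixed-scale
    Laplace prior, by 1-D quadrature."""
    grid = np.arange(-half_width + step / 2.0, half_width, step)
    logw = np.array([bernoulli_loglik(X, y, b) - abs(b) / scale for b in grid])
    w = np.exp(logw - logw.max())
    return _grid_moments(grid, w)
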