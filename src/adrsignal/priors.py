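"""Shrinkage priors for sparse Bayesian logistic regression.

Two priors are supported for the coefficient vector of the logistic model
``y_i ~ Bernoulli(logistic(b0 + x_i . beta))``:

* the regularized horseshoe, a global-local prior with half-Cauchy local
  scales ``lambda_j`` and a finite-width slab bounding how far escaped
  coefficients may grow::

      beta_j ~ Normal(0, tau^2 * lt_j^2),
      lt_j^2 = c^2 lambda_j^2 / (c^2 + tau^2 lambda_j^2),
      lambda_j ~ half-Cauchy(0, 1),
      tau ~ half-Cauchy(0, tau0),
      c^2 ~ Inverse-Gamma(nu/2, nu s^2 / 2)

  with the global scale calibrated as
  ``tau0 = (p0 / (p - p0)) / sqrt(n)`` -- the ratio of the expected number
  of non-zero to zero coefficients divided by the square root of the number
  of observations -- and the slab scale as ``s = sqrt(c0 / p0) * sd(y)``,
  the square root of a constant over the expected non-zero count times the
  outcome standard deviation;

* a Laplace (double-exponential) prior of scale ``b``, the Bayesian
  analogue of the lasso, optionally with its scale learned through a
  conjugate Gamma hyperprior on the squared penalty.

The intercept carries a wide Normal(0, 10^2) prior and is excluded from
shrinkage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "HorseshoePrior",
    "LaplacePrior",
    "compute_global_scale",
    "compute_slab_scale",
    "outcome_sd",
    "prior_predictive",
    "log_unnorm_posterior",
    "INTERCEPT_SD",
]

#: prior standard deviation of the unshrunk intercept
INTERCEPT_SD = 10.0


def compute_global_scale(p0: float, p: int, n: int) -> float:
    """Global-scale calibration ``tau0 = (p0 / (p - p0)) / sqrt(n)``.

    ``p0`` is the expected number of non-zero coefficients among ``p``
    candidates, ``n`` the number of observations.
    """
    if not 0 < p0 < p:
        raise ValueError(f"p0 must satisfy 0 < p0 < p, got p0={p0}, p={p}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return (p0 / (p - p0)) / math.sqrt(n)


def compute_slab_scale(c0: float, p0: float, sd_y: float) -> float:
    """Slab-scale calibration ``s = sqrt(c0 / p0) * sd_y``."""
    if c0 <= 0 or p0 <= 0 or sd_y <= 0:
        raise ValueError("c0, p0 and sd_y must all be positive")
    return math.sqrt(c0 / p0) * sd_y


def outcome_sd(y: np.ndarray) -> float:
    """Population standard deviation of a binary outcome, sqrt(q(1-q))."""
    q = float(np.mean(y))
    return math.sqrt(q * (1.0 - q))


@dataclass(frozen=True)
class HorseshoePrior:
    """Regularized horseshoe prior with its two calibrated scales.

    ``slab_constant`` (c0) defaults to ``6.25 * p0`` so that the slab scale
    comes out as 2.5 outcome standard deviations at any p0 -- a weakly
    informative slab on the logistic scale.
    """

    p0: float
    global_scale: float
    slab_scale: float
    slab_df: float = 4.0
    slab_constant: float | None = None

    def __post_init__(self) -> None:
        if self.p0 <= 0:
            raise ValueError("p0 must be positive")
        if self.global_scale <= 0 or self.slab_scale <= 0 or self.slab_df <= 0:
            raise ValueError("global_scale, slab_scale and slab_df must be positive")

    @classmethod
    def calibrated(cls, p0: float, p: int, n: int, y: np.ndarray,
                   slab_constant: float | None = None,
                   slab_df: float = 4.0) -> "HorseshoePrior":
        """Build the prior from the data dimensions and the outcome vector."""
        c0 = 6.25 * p0 if slab_constant is None else slab_constant
        return cls(
            p0=p0,
            global_scale=compute_global_scale(p0, p, n),
            slab_scale=compute_slab_scale(c0, p0, outcome_sd(y)),
            slab_df=slab_df,
            slab_constant=c0,
        )


@dataclass(frozen=True)
class LaplacePrior:
    """Double-exponential (lasso) prior on coefficients.

    With ``learn_scale`` the squared penalty ``1/b^2`` receives a conjugate
    Gamma(shape, rate) hyperprior and is updated from the data; ``scale``
    then serves as the initial value.
    """

    scale: float = 1.0
    learn_scale: bool = True
    hyper_shape: float = 1.0
    hyper_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.hyper_shape <= 0 or self.hyper_rate <= 0:
            raise ValueError("hyperprior parameters must be positive")


def regularized_scale_sq(lam: np.ndarray, tau: float, c: float) -> np.ndarray:
    """Slab-regularized local scale ``lt^2 = c^2 lam^2 / (c^2 + tau^2 lam^2)``."""
    lam2 = np.square(lam)
    return (c * c * lam2) / (c * c + tau * tau * lam2)


def prior_predictive(prior: HorseshoePrior | LaplacePrior, p: int,
                     n_draws: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Exact ancestral draws from the prior hierarchy.

    Returns a dict with ``beta`` (n_draws x p) and, for the horseshoe, the
    latents ``lambda`` (n_draws x p), ``tau`` and ``c`` (n_draws,).
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if isinstance(prior, HorseshoePrior):
        lam = np.abs(rng.standard_cauchy(size=(n_draws, p)))
        tau = prior.global_scale * np.abs(rng.standard_cauchy(size=n_draws))
        # c^2 ~ InvGamma(nu/2, nu s^2/2)
        c2 = (prior.slab_df * prior.slab_scale ** 2 / 2.0) \
            / rng.gamma(prior.slab_df / 2.0, 1.0, size=n_draws)
        c = np.sqrt(c2)
        lt2 = regularized_scale_sq(lam, tau[:, None], c[:, None])
        beta = rng.standard_normal((n_draws, p)) * tau[:, None] * np.sqrt(lt2)
        return {"beta": beta, "lambda": lam, "tau": tau, "c": c}
    if isinstance(prior, LaplacePrior):
        beta = rng.laplace(0.0, prior.scale, size=(n_draws, p))
        return {"beta": beta}
    raise TypeError(f"unsupported prior type {type(prior).__name__}")


def _log_sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable log logistic(x)
    return -np.logaddexp(0.0, -x)


def bernoulli_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray,
                     intercept: float) -> float:
    eta = intercept + X @ beta
    return float(np.sum(y * _log_sigmoid(eta) + (1 - y) * _log_sigmoid(-eta)))


def log_unnorm_posterior(X: np.ndarray, y: np.ndarray,
                         point: dict[str, np.ndarray | float],
                         prior: HorseshoePrior | LaplacePrior) -> float:
    """Log posterior density up to a parameter-independent constant.

    ``point`` holds ``beta`` and ``intercept``, plus for the horseshoe the
    latents ``lambda`` (positive vector), ``tau`` and ``c`` (positive
    scalars).
    """
    beta = np.asarray(point["beta"], dtype=float)
    b0 = float(point.get("intercept", 0.0))
    lp = bernoulli_loglik(X, y, beta, b0)
    lp += -0.5 * (b0 / INTERCEPT_SD) ** 2  # intercept prior kernel

    if isinstance(prior, HorseshoePrior):
        lam = np.asarray(point["lambda"], dtype=float)
        tau = float(point["tau"])
        c = float(point["c"])
        if np.any(lam <= 0) or tau <= 0 or c <= 0:
            raise ValueError("latent scales must be positive")
        lt2 = regularized_scale_sq(lam, tau, c)
        var = tau * tau * lt2
        lp += float(np.sum(-0.5 * np.log(var) - 0.5 * beta ** 2 / var))
        lp += float(np.sum(-np.log1p(lam ** 2)))          # half-Cauchy(0,1)
        lp += -math.log1p((tau / prior.global_scale) ** 2)  # half-Cauchy(0,tau0)
        # InvGamma(nu/2, nu s^2/2) on c^2, with Jacobian-free c^2 argument
        nu, s = prior.slab_df, prior.slab_scale
        c2 = c * c
        lp += -(nu / 2.0 + 1.0) * math.log(c2) - nu * s * s / (2.0 * c2)
        return lp
    if isinstance(prior, LaplacePrior):
        lp += float(np.sum(-np.abs(beta) / prior.scale)) - beta.size * math.log(prior.scale)
        return lp
    raise TypeError(f"unsupported prior type {type(prior).__name__}")
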