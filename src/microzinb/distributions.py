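"""Zero-inflated negative binomial (ZINB) distribution primitives.

The ZINB mixes a point mass at zero (weight ``phi``, the "extra zeros"
arising from biological absence and technical dropout) with a negative
binomial count component NB(mu, theta), where ``mu`` is the NB mean and
``theta`` the size parameter (overdispersion is ``1/theta``; the NB
variance is ``mu + mu**2/theta``).  Setting ``phi = 0`` recovers the plain
NB, and ``theta -> inf`` recovers the zero-inflated Poisson.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "ZinbParams",
    "zinb_logpmf",
    "pmf_normalization_check",
    "phi_from_tau",
    "zinb_mean_var",
    "zinb_rvs",
]


@dataclass(frozen=True)
class ZinbParams:
    """Distribution-level ZINB parameters.

    Attributes
    ----------
    mu : float
        Mean of the negative binomial component, > 0.
    theta : float
        NB size parameter, > 0; the overdispersion is ``1/theta``.
    phi : float
        Weight of extra zeros, in [0, 1].
    """

    mu: float
    theta: float
    phi: float

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError(f"mu must be > 0, got {self.mu}")
        if not self.theta > 0:
            raise ValueError(f"theta must be > 0, got {self.theta}")
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError(f"phi must be in [0, 1], got {self.phi}")


def _nb_logpmf(y, mu, theta):
    # NB in mean/size parameterization: p = theta / (theta + mu)
    return (
        special.gammaln(theta + y)
        - special.gammaln(theta)
        - special.gammaln(y + 1.0)
        + theta * (np.log(theta) - np.log(theta + mu))
        + y * (np.log(mu) - np.log(theta + mu))
    )


def zinb_logpmf(y, params: ZinbParams | None = None, *, mu=None, theta=None, phi=None):
    """Log pmf of the ZINB distribution.

    ``P(0) = phi + (1 - phi) * (theta/(theta+mu))**theta`` and
    ``P(y>0) = (1 - phi) * NB(y; mu, theta)``.  The zero branch is
    evaluated with log-sum-exp so it is stable for phi near 0 or 1.

    Parameters may be given as a :class:`ZinbParams` bundle or as
    keyword scalars/arrays (broadcast against ``y``).
    """
    if params is not None:
        mu, theta, phi = params.mu, params.theta, params.phi
    y = np.asarray(y)
    if not np.issubdtype(y.dtype, np.integer):
        yr = np.asarray(y, dtype=float)
        if np.any(yr != np.floor(yr)):
            raise ValueError("y must be integer-valued")
        y = yr
    if np.any(y < 0):
        raise ValueError("y must be non-negative")
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)

    with np.errstate(divide="ignore"):
        log_phi = np.log(phi)
        log_1mphi = np.log1p(-phi)
    nb_log0 = theta * (np.log(theta) - np.log(theta + mu))
    # log(phi + (1-phi) * nb0) via logaddexp; -inf branches are handled by numpy
    log_p0 = np.logaddexp(log_phi, log_1mphi + nb_log0)
    log_ppos = log_1mphi + _nb_logpmf(y, mu, theta)
    return np.where(y == 0, log_p0, log_ppos)


def pmf_normalization_check(params: ZinbParams, ymax: int) -> float:
    """Sum exp(zinb_logpmf) over y = 0..ymax (brute-force test oracle).

    ``ymax`` must be large enough that the truncated tail mass is
    negligible for the check being performed.
    """
    y = np.arange(ymax + 1)
    return float(np.sum(np.exp(zinb_logpmf(y, params))))


def phi_from_tau(mu, tau):
    """Zero-inflation probability under the tau link.

    logit(phi) = -tau * log(mu), i.e. ``phi = 1 / (1 + mu**tau)``: when
    the mean model is log(mu) = B beta, this is logit(phi) = -tau*B*beta,
    tying the extra-zero probability to the mean — abundant taxa get
    fewer extra zeros for tau > 0.
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mu must be > 0")
    return special.expit(-np.asarray(tau, dtype=float) * np.log(mu))


def zinb_mean_var(params: ZinbParams) -> tuple[float, float]:
    """Moments: E[Y] = (1-phi)*mu, Var[Y] = (1-phi)*mu*(1 + mu/theta + phi*mu)."""
    mu, theta, phi = params.mu, params.theta, params.phi
    mean = (1.0 - phi) * mu
    var = (1.0 - phi) * mu * (1.0 + mu / theta + phi * mu)
    return mean, var


def zinb_rvs(params: ZinbParams, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ZINB samples: Bernoulli(phi) extra zeros over NB(mu, theta) counts."""
    mu, theta, phi = params.mu, params.theta, params.phi
    p = theta / (theta + mu)
    counts = rng.negative_binomial(theta, p, size=size)
    extra = rng.random(size) < phi
    counts[extra] = 0
    return counts


def zip_logpmf(y, mu, phi):
    """Zero-inflated Poisson log pmf (theta -> inf limit of the ZINB)."""
    y = np.asarray(y, dtype=float)
    with np.errstate(divide="ignore"):
        log_phi = np.log(np.asarray(phi, dtype=float))
        log_1mphi = np.log1p(-np.asarray(phi, dtype=float))
    log_p0 = np.logaddexp(log_phi, log_1mphi - mu)
    log_ppos = log_1mphi + stats.poisson.logpmf(y, mu)
    return np.where(y == 0, log_p0, log_ppos)
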