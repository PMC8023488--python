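"""Analytic functions of the Weibull-truncated-exponential (W-TEXPD) distribution.

The W-TEXPD arises by pushing a left-truncated exponential variable through a
Weibull generator.  Its density on the ray ``x > tau`` is

    g(x) = (beta / lam**beta) * (x - tau)**(beta - 1)
           * exp(-((x - tau) / lam)**beta),

with location/threshold ``tau``, shape ``beta > 0`` and an effective scale
``lam = alpha / theta > 0`` formed from the two raw scale components.  The pair
``(alpha, theta)`` enters every distributional quantity only through the ratio
``lam``, so the family coincides with a three-parameter (location-shifted)
Weibull; ``tau = 0, theta = beta = 1`` recovers the exponential with rate
``1/alpha``, and ``theta = 1`` the three-parameter Weibull.

This module provides the density, distribution, survival, hazard and quantile
functions, inverse-transform random variates, the first four moments,
standardized skewness and kurtosis, Shannon entropy and order-statistic
densities.  All evaluators are vectorized over the data argument.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "EULER_GAMMA",
    "ParameterError",
    "SupportError",
    "WTexpdParams",
    "OrderStatSpec",
    "pdf",
    "cdf",
    "sf",
    "hazard",
    "cumulative_hazard",
    "quantile",
    "rvs",
    "raw_moment",
    "mean",
    "variance",
    "skewness",
    "kurtosis",
    "entropy",
    "order_statistic_pdf",
]

#: Euler-Mascheroni constant, fixed to 15 significant digits.
EULER_GAMMA = 0.577215664901533


class ParameterError(ValueError):
    """Raised when a parameter vector violates the family's constraints."""


class SupportError(ValueError):
    """Raised when an evaluation point lies outside the support ``(tau, inf)``."""


@dataclass(frozen=True)
class WTexpdParams:
    """Parameter vector ``(tau, alpha, theta, beta)`` of the W-TEXPD.

    ``alpha`` and ``theta`` may individually be negative (as in some fitted
    tables) but their ratio ``lam = alpha / theta`` — the identifiable scale —
    must be positive.  ``beta`` is the dimensionless shape; ``tau`` the lower
    support endpoint in data units.
    """

    tau: float
    alpha: float
    theta: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("tau", "alpha", "theta", "beta"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ParameterError(f"{name} must be finite, got {v!r}")
        if self.beta <= 0:
            raise ParameterError(f"shape beta must be positive, got {self.beta}")
        if self.theta == 0:
            raise ParameterError("theta must be nonzero")
        if self.alpha / self.theta <= 0:
            raise ParameterError(
                "scale ratio alpha/theta must be positive, got "
                f"{self.alpha}/{self.theta}"
            )

    @property
    def lam(self) -> float:
        """Identifiable scale ``alpha / theta`` (data units)."""
        return self.alpha / self.theta

    @classmethod
    def from_scale(
        cls, tau: float, lam: float, beta: float, theta: float = 1.0
    ) -> "WTexpdParams":
        """Build from the identifiable triple ``(tau, lam, beta)``.

        ``theta`` pins the unidentifiable scale split; ``alpha = lam * theta``.
        """
        return cls(tau=tau, alpha=lam * theta, theta=theta, beta=beta)


@dataclass(frozen=True)
class OrderStatSpec:
    """Rank ``r`` out of a sample of size ``n``, with ``1 <= r <= n``."""

    r: int
    n: int

    def __post_init__(self) -> None:
        if not (1 <= self.r <= self.n):
            raise ValueError(f"rank must satisfy 1 <= r <= n, got r={self.r}, n={self.n}")


def _as_array(x):
    arr = np.asarray(x, dtype=float)
    return arr, arr.ndim == 0


def pdf(x, p: WTexpdParams):
    """Density g(x); zero below the threshold.

    At ``x == tau`` the density is continuous from the right only for
    ``beta > 1`` (value 0); for ``beta == 1`` the boundary value is ``1/lam``
    and for ``beta < 1`` the density diverges, in which case ``inf`` is
    returned with a warning.
    """
    arr, scalar = _as_array(x)
    y = arr - p.tau
    lam, beta = p.lam, p.beta
    out = np.zeros_like(y)
    pos = y > 0
    if np.any(pos):
        z = y[pos] / lam
        out[pos] = (beta / lam) * z ** (beta - 1.0) * np.exp(-(z**beta))
    at_tau = y == 0
    if np.any(at_tau):
        if beta > 1:
            out[at_tau] = 0.0
        elif beta == 1:
            out[at_tau] = 1.0 / lam
        else:
            warnings.warn(
                "density diverges at the threshold x = tau for beta < 1",
                RuntimeWarning,
                stacklevel=2,
            )
            out[at_tau] = np.inf
    return out.item() if scalar else out


def cdf(x, p: WTexpdParams):
    """Distribution function ``1 - exp(-((x - tau)/lam)**beta)``, 0 for x <= tau."""
    arr, scalar = _as_array(x)
    y = arr - p.tau
    out = np.zeros_like(y)
    pos = y > 0
    out[pos] = -np.expm1(-((y[pos] / p.lam) ** p.beta))
    return out.item() if scalar else out


def sf(x, p: WTexpdParams):
    """Survival function, computed directly as ``exp(-((x - tau)/lam)**beta)``."""
    arr, scalar = _as_array(x)
    y = arr - p.tau
    out = np.ones_like(y)
    pos = y > 0
    out[pos] = np.exp(-((y[pos] / p.lam) ** p.beta))
    return out.item() if scalar else out


def hazard(t, p: WTexpdParams):
    """Hazard ``beta * lam**-beta * (t - tau)**(beta - 1)`` for t > tau.

    Constant in ``t`` iff beta == 1, decreasing iff beta < 1, increasing iff
    beta > 1.
    """
    arr, scalar = _as_array(t)
    if np.any(arr <= p.tau):
        raise SupportError(f"hazard requires t > tau = {p.tau}")
    z = (arr - p.tau) / p.lam
    out = (p.beta / p.lam) * z ** (p.beta - 1.0)
    return out.item() if scalar else out


def cumulative_hazard(t, p: WTexpdParams):
    """Cumulative hazard ``((t - tau)/lam)**beta`` for t >= tau; equals -ln S."""
    arr, scalar = _as_array(t)
    if np.any(arr < p.tau):
        raise SupportError(f"cumulative hazard requires t >= tau = {p.tau}")
    out = ((arr - p.tau) / p.lam) ** p.beta
    return out.item() if scalar else out


def quantile(P, p: WTexpdParams):
    """Quantile function ``tau + lam * (-ln(1 - P))**(1/beta)`` for P in [0, 1).

    This is the exact inverse of :func:`cdf` on the support.
    """
    arr, scalar = _as_array(P)
    if np.any((arr < 0) | (arr >= 1)):
        raise ValueError("probability level must lie in [0, 1)")
    out = p.tau + p.lam * (-np.log1p(-arr)) ** (1.0 / p.beta)
    return out.item() if scalar else out


def rvs(p: WTexpdParams, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` variates by inverse-transform sampling of uniforms.

    ``seed`` is anything accepted by :func:`numpy.random.default_rng`
    (an int, a Generator, or None for OS entropy); a fixed integer makes the
    draw reproducible.
    """
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=int(n))
    return quantile(u, p)


def raw_moment(r: int, p: WTexpdParams) -> float:
    """r-th raw moment E(X^r), r in 1..4.

    With Z the unit-scale Weibull factor, X = tau + lam*Z and
    E(Z^k) = Gamma(k/beta + 1), so E(X^r) expands binomially.
    """
    if r not in (1, 2, 3, 4):
        raise ValueError(f"raw moments are implemented for r in 1..4, got {r}")
    lam, beta, tau = p.lam, p.beta, p.tau
    total = 0.0
    for k in range(r + 1):
        total += (
            math.comb(r, k)
            * tau ** (r - k)
            * lam**k
            * special.gamma(k / beta + 1.0)
        )
    return total


def mean(p: WTexpdParams) -> float:
    """E(X) = tau + lam * Gamma(1/beta + 1)."""
    return p.tau + p.lam * special.gamma(1.0 / p.beta + 1.0)


def variance(p: WTexpdParams) -> float:
    """Var(X) = lam**2 * (Gamma(2/beta + 1) - Gamma(1/beta + 1)**2); tau-free."""
    g1 = special.gamma(1.0 / p.beta + 1.0)
    g2 = special.gamma(2.0 / p.beta + 1.0)
    return p.lam**2 * (g2 - g1**2)


def _standardized_moments(beta: float) -> tuple[float, float]:
    # central moments of the unit-scale family; location and scale drop out
    g = [special.gamma(k / beta + 1.0) for k in range(1, 5)]
    m2 = g[1] - g[0] ** 2
    m3 = g[2] - 3.0 * g[0] * g[1] + 2.0 * g[0] ** 3
    m4 = g[3] - 4.0 * g[0] * g[2] + 6.0 * g[0] ** 2 * g[1] - 3.0 * g[0] ** 4
    return m3 / m2**1.5, m4 / m2**2


def skewness(p: WTexpdParams) -> float:
    """Standardized third central moment; a function of beta only."""
    return _standardized_moments(p.beta)[0]


def kurtosis(p: WTexpdParams) -> float:
    """Standardized fourth central moment (non-excess); a function of beta only."""
    return _standardized_moments(p.beta)[1]


def entropy(p: WTexpdParams) -> float:
    """Shannon entropy, invariant to tau.

    Equals ``euler_gamma * (1 - 1/beta) + ln(lam / beta) + 1`` — the familiar
    Weibull entropy, since the threshold only shifts the support.
    """
    beta, lam = p.beta, p.lam
    return EULER_GAMMA * (1.0 - 1.0 / beta) + math.log(lam / beta) + 1.0


def order_statistic_pdf(x, p: WTexpdParams, spec: OrderStatSpec):
    """Density of the r-th order statistic of an i.i.d. sample of size n.

    ``C(r, n) * g(x) * G(x)**(r-1) * (1 - G(x))**(n-r)`` with the multinomial
    constant ``C(r, n) = n! / ((r-1)! (n-r)!)``; integrates to one over the
    support.
    """
    if not isinstance(spec, OrderStatSpec):
        spec = OrderStatSpec(*spec)
    logc = (
        special.gammaln(spec.n + 1)
        - special.gammaln(spec.r)
        - special.gammaln(spec.n - spec.r + 1)
    )
    c = math.exp(logc)
    f = pdf(x, p)
    big_f = cdf(x, p)
    s = sf(x, p)
    return c * f * big_f ** (spec.r - 1) * s ** (spec.n - spec.r)
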