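"""The four comparison lifetime models: Weibull, Gamma, exponential, and the
left-truncated (shifted) exponential.

Each fit returns the same :class:`~wtexpd.estimation.FitResult` container as
the W-TEXPD fit so the comparison report can treat all five models uniformly.
The exponential and shifted-exponential MLEs are closed form; the Weibull and
Gamma shapes solve their standard one-dimensional profile equations by
safeguarded Newton iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .core import SupportError
from .estimation import EstimationError, FitResult, _values

__all__ = [
    "BaselineParams",
    "fit_exponential",
    "fit_texpd",
    "fit_weibull",
    "fit_gamma",
    "baseline_cdf",
]

_MODELS = ("weibull", "gamma", "exponential", "texpd")


@dataclass(frozen=True)
class BaselineParams:
    """Parameters of one comparison model.

    ``a`` is the shape for weibull/gamma and the rate for the one-parameter
    exponential models; ``b`` the Weibull scale or Gamma rate; ``tau`` the
    shift of the truncated exponential.
    """

    model: str
    a: float
    b: float | None = None
    tau: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {_MODELS}")
        if self.a <= 0 or (self.b is not None and self.b <= 0):
            raise ValueError("rate/shape/scale parameters must be positive")


def _require_positive(x: np.ndarray) -> None:
    if np.any(x <= 0):
        raise ValueError("all observations must be strictly positive")


def fit_exponential(s) -> FitResult:
    """Closed-form exponential MLE: rate = 1/mean, l = n (ln rate - 1)."""
    x = _values(s)
    _require_positive(x)
    n = x.size
    rate = 1.0 / float(np.mean(x))
    ll = n * (np.log(rate) - 1.0)
    return FitResult(
        model="exponential",
        params={"rate": rate},
        se={"rate": rate / np.sqrt(n)},
        loglik=float(ll),
        k=1,
        n=n,
        converged=True,
        free_names=("rate",),
    )


def fit_texpd(s, tau: float = 0.0) -> FitResult:
    """Shifted-exponential MLE: density theta * exp(-theta (x - tau)), x >= tau.

    theta-hat = 1 / (mean - tau) in closed form.  ``tau`` may equal the sample
    minimum (the density is finite and positive there); it must not exceed it.
    """
    x = _values(s)
    n = x.size
    if tau > float(np.min(x)):
        raise SupportError(
            f"tau = {tau} exceeds the smallest observation {float(np.min(x))}"
        )
    rate = 1.0 / float(np.mean(x) - tau)
    ll = n * (np.log(rate) - 1.0)
    return FitResult(
        model="texpd",
        params={"rate": rate, "tau": float(tau)},
        se={"rate": rate / np.sqrt(n), "tau": 0.0},
        loglik=float(ll),
        k=1,
        n=n,
        converged=True,
        free_names=("rate",),
        tau_fixed=True,
        tau_value=float(tau),
    )


def _weibull_profile_mle(x: np.ndarray, tol: float = 1e-12, max_iter: int = 200):
    """Solve the Weibull shape profile equation by safeguarded Newton.

    g(c) = 1/c + mean(ln x) - sum(x^c ln x)/sum(x^c) = 0; the scale then
    follows as (mean(x^c))**(1/c).
    """
    logx = np.log(x)
    mlog = float(np.mean(logx))
    sd = float(np.std(logx, ddof=1))
    if sd == 0.0:
        raise EstimationError("degenerate sample: all observations equal")
    c = np.pi / (np.sqrt(6.0) * sd)
    lo, hi = 1e-8, 1e8

    def g_and_dg(c):
        w = np.exp(c * (logx - logx.max()))  # stabilized x**c
        s0 = float(np.sum(w))
        s1 = float(np.sum(w * logx))
        s2 = float(np.sum(w * logx**2))
        g = 1.0 / c + mlog - s1 / s0
        dg = -1.0 / c**2 - (s2 * s0 - s1 * s1) / s0**2
        return g, dg

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g, dg = g_and_dg(c)
        if abs(g) < tol:
            converged = True
            break
        if g > 0:
            lo = max(lo, c)
        else:
            hi = min(hi, c)
        step = g / dg if dg != 0 else np.nan
        c_new = c - step
        if not np.isfinite(c_new) or not (lo < c_new < hi):
            c_new = 0.5 * (lo + hi)  # bisection safeguard
        if c_new == c:
            converged = True
            break
        c = c_new
    scale = float(np.mean(x**c)) ** (1.0 / c)
    return float(c), scale, converged, it


def fit_weibull(s) -> FitResult:
    """Two-parameter Weibull(shape, scale) MLE via the profile equation."""
    x = _values(s)
    _require_positive(x)
    n = x.size
    shape, scale, converged, iters = _weibull_profile_mle(x)
    z = x / scale
    ll = float(
        n * np.log(shape / scale)
        + (shape - 1.0) * np.sum(np.log(z))
        - np.sum(z**shape)
    )
    # asymptotic SEs from the observed information of the (shape, scale) chart
    w = z**shape
    lz = np.log(z)
    i_cc = n / shape**2 + float(np.sum(w * lz**2))
    i_ss = (shape / scale**2) * (
        (shape + 1.0) * float(np.sum(w)) - n
    )
    i_cs = (n - float(np.sum(w)) - shape * float(np.sum(w * lz))) / scale
    info = np.array([[i_cc, i_cs], [i_cs, i_ss]])
    vcov = np.linalg.pinv(info)
    return FitResult(
        model="weibull",
        params={"shape": shape, "scale": scale},
        se={
            "shape": float(np.sqrt(max(vcov[0, 0], 0.0))),
            "scale": float(np.sqrt(max(vcov[1, 1], 0.0))),
        },
        loglik=ll,
        k=2,
        n=n,
        converged=converged,
        iterations=iters,
        vcov=vcov,
        free_names=("shape", "scale"),
    )


def fit_gamma(s, tol: float = 1e-12, max_iter: int = 200) -> FitResult:
    """Gamma(shape, rate) MLE by Newton iteration on the digamma profile equation.

    The shape solves ln(shape) - psi(shape) = ln(mean) - mean(ln x); the rate
    is shape / mean.
    """
    x = _values(s)
    _require_positive(x)
    n = x.size
    m = float(np.mean(x))
    c = np.log(m) - float(np.mean(np.log(x)))
    if c <= 0:
        raise EstimationError("degenerate sample: zero log-moment gap")
    # classic starting value, then Newton on f(a) = ln a - psi(a) - c
    a = (3.0 - c + np.sqrt((c - 3.0) ** 2 + 24.0 * c)) / (12.0 * c)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        f = np.log(a) - special.digamma(a) - c
        if abs(f) < tol:
            converged = True
            break
        df = 1.0 / a - special.polygamma(1, a)
        a_new = a - f / df
        if not np.isfinite(a_new) or a_new <= 0:
            a_new = a / 2.0
        if a_new == a:
            converged = True
            break
        a = a_new
    rate = a / m
    ll = float(
        n * (a * np.log(rate) - special.gammaln(a))
        + (a - 1.0) * np.sum(np.log(x))
        - rate * np.sum(x)
    )
    info = np.array(
        [
            [n * float(special.polygamma(1, a)), -n / rate],
            [-n / rate, n * a / rate**2],
        ]
    )
    vcov = np.linalg.pinv(info)
    return FitResult(
        model="gamma",
        params={"shape": float(a), "rate": float(rate)},
        se={
            "shape": float(np.sqrt(max(vcov[0, 0], 0.0))),
            "rate": float(np.sqrt(max(vcov[1, 1], 0.0))),
        },
        loglik=ll,
        k=2,
        n=n,
        converged=converged,
        iterations=it,
        vcov=vcov,
        free_names=("shape", "rate"),
    )


def baseline_cdf(model: BaselineParams, x):
    """Distribution function of a comparison model; zero below its support."""
    arr = np.asarray(x, dtype=float)
    if model.model == "exponential":
        out = stats.expon.cdf(arr, scale=1.0 / model.a)
    elif model.model == "texpd":
        out = stats.expon.cdf(arr, loc=model.tau, scale=1.0 / model.a)
    elif model.model == "weibull":
        out = stats.weibull_min.cdf(arr, model.a, scale=model.b)
    else:  # gamma, (shape, rate)
        out = stats.gamma.cdf(arr, model.a, scale=1.0 / model.b)
    return out if out.ndim else float(out)
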