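"""Maximum-likelihood estimation of the W-TEXPD with asymptotic inference.

The log-likelihood of a sample x_1..x_n with threshold tau, shape beta and
raw scales (alpha, theta), writing y_i = x_i - tau and lam = alpha/theta, is

    l = n ln beta + n beta ln theta - n beta ln alpha
        + (beta - 1) * sum ln y_i - sum (y_i / lam)**beta.

(alpha, theta) enter only through lam, which makes the joint (theta, alpha)
score directions exactly proportional and the full 3x3 information singular.
Fitting therefore maximizes over the identifiable pair (lam, beta) with tau
held fixed, by Newton-Raphson on the analytic score in (ln lam, ln beta)
coordinates with step-halving, falling back to a Nelder-Mead simplex search
when the Newton iteration fails.  The raw pair is recovered afterwards by
pinning theta to a user-chosen value (default 1) so that alpha = lam * theta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .core import SupportError, WTexpdParams
from . import core

__all__ = [
    "Sample",
    "FitResult",
    "CiSpec",
    "EstimationError",
    "InferenceError",
    "loglikelihood",
    "score",
    "fit_wtexpd",
    "fisher_information",
    "confidence_interval",
]


class EstimationError(RuntimeError):
    """Raised when a fit cannot be carried out on the given sample."""


class InferenceError(RuntimeError):
    """Raised when asymptotic inference is requested from an unusable fit."""


@dataclass(frozen=True)
class Sample:
    """An observed univariate dataset with provenance metadata."""

    values: np.ndarray
    name: str = ""
    source: str = ""
    caveat: str | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float).ravel()
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValueError("sample values must all be finite")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return int(self.values.size)


def _values(s) -> np.ndarray:
    if isinstance(s, Sample):
        return s.values
    return np.asarray(s, dtype=float).ravel()


@dataclass
class FitResult:
    """A fitted parametric model: estimates, uncertainty, and fit criteria.

    ``params`` and ``se`` are keyed by parameter name; ``vcov`` covers the
    free (identifiable) parameters in ``free_names`` order.  ``k`` counts the
    free parameters entering AIC/BIC.
    """

    model: str
    params: dict
    se: dict
    loglik: float
    k: int
    n: int
    converged: bool
    iterations: int = 0
    vcov: np.ndarray | None = None
    free_names: tuple = ()
    tau_fixed: bool = False
    tau_value: float | None = None
    pinned: tuple = ()
    message: str = ""

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik

    @property
    def bic(self) -> float:
        return self.k * np.log(self.n) - 2.0 * self.loglik

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": dict(self.params),
            "se": dict(self.se),
            "loglik": float(self.loglik),
            "k": int(self.k),
            "n": int(self.n),
            "aic": float(self.aic),
            "bic": float(self.bic),
            "converged": bool(self.converged),
        }


@dataclass(frozen=True)
class CiSpec:
    """Confidence-interval request: level = 1 - xi, method normal|lognormal."""

    level: float = 0.95
    method: str = "normal"

    def __post_init__(self) -> None:
        if not (0.0 < self.level < 1.0):
            raise ValueError(f"confidence level must lie in (0, 1), got {self.level}")
        if self.method not in ("normal", "lognormal"):
            raise ValueError(f"unknown CI method {self.method!r}")


def _check_support(x: np.ndarray, tau: float) -> np.ndarray:
    if x.size < 1:
        raise ValueError("empty sample")
    i = int(np.argmin(x))
    if tau >= x[i]:
        raise SupportError(
            f"tau = {tau} must lie strictly below the smallest observation "
            f"x[{i}] = {x[i]}"
        )
    return x - tau


def loglikelihood(s, p: WTexpdParams) -> float:
    """Log-likelihood of the sample under parameters ``p``.

    Requires ``p.tau`` strictly below the sample minimum.
    """
    x = _values(s)
    y = _check_support(x, p.tau)
    n = x.size
    lam, beta = p.lam, p.beta
    return float(
        n * np.log(beta)
        - n * beta * np.log(lam)
        + (beta - 1.0) * np.sum(np.log(y))
        - np.sum((y / lam) ** beta)
    )


def score(s, p: WTexpdParams) -> np.ndarray:
    """Analytic score (gradient of the log-likelihood) over (theta, alpha, beta).

    The theta- and alpha-components satisfy theta*d/dtheta = -alpha*d/dalpha
    identically — the unidentifiable scale-split direction.
    """
    x = _values(s)
    y = _check_support(x, p.tau)
    n = x.size
    alpha, theta, beta = p.alpha, p.theta, p.beta
    lam = p.lam
    yb = y**beta
    s0 = float(np.sum(yb))
    c = lam ** (-beta)  # (theta/alpha)**beta
    d_theta = n * beta / theta - (beta / theta) * c * s0
    d_alpha = -n * beta / alpha + (beta / alpha) * c * s0
    d_beta = (
        n / beta
        - n * np.log(lam)
        + float(np.sum(np.log(y)))
        - c * float(np.sum(yb * np.log(y)))
        + c * np.log(lam) * s0
    )
    return np.array([d_theta, d_alpha, d_beta])


def _score_hess_uv(y: np.ndarray, u: float, v: float):
    """Score and Hessian of the log-likelihood in (u, v) = (ln lam, ln beta)."""
    n = y.size
    lam, beta = np.exp(u), np.exp(v)
    z = np.log(y) - u  # ln(y/lam)
    w = np.exp(beta * z)  # (y/lam)**beta
    t0 = float(np.sum(w))
    t1 = float(np.sum(w * z))
    t2 = float(np.sum(w * z * z))
    sz = float(np.sum(z))
    ll = n * np.log(beta) + (beta - 1.0) * float(np.sum(np.log(y))) - n * beta * u - t0
    g = np.array([beta * (t0 - n), n + beta * sz - beta * t1])
    h = np.array(
        [
            [-(beta**2) * t0, beta * (t0 - n) + beta**2 * t1],
            [beta * (t0 - n) + beta**2 * t1, beta * sz - beta * t1 - beta**2 * t2],
        ]
    )
    return float(ll), g, h


def _mle_lam_beta(y: np.ndarray, tol: float, max_iter: int):
    """Newton-Raphson MLE of (lam, beta) for threshold-free data y > 0."""
    n = y.size
    logy = np.log(y)
    sd = float(np.std(logy, ddof=1)) if n > 1 else 0.0
    if sd == 0.0:
        raise EstimationError("degenerate sample: all observations equal")
    beta0 = np.pi / (np.sqrt(6.0) * sd)
    u = float(np.log(np.mean(y**beta0)) / beta0)
    v = float(np.log(beta0))
    ll, g, h = _score_hess_uv(y, u, v)
    converged = False
    iters = 0
    for iters in range(1, max_iter + 1):
        if np.max(np.abs(g)) < tol * max(1.0, abs(ll)):
            converged = True
            break
        try:
            step = np.linalg.solve(h, -g)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        # step-halving: accept only likelihood-increasing moves
        t = 1.0
        improved = False
        for _ in range(40):
            ll_new, g_new, h_new = _score_hess_uv(y, u + t * step[0], v + t * step[1])
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                u, v = u + t * step[0], v + t * step[1]
                ll, g, h = ll_new, g_new, h_new
                improved = True
                break
            t *= 0.5
        if not improved:
            break
    if not converged:
        # simplex fallback on the negative log-likelihood
        res = optimize.minimize(
            lambda p_: -_score_hess_uv(y, p_[0], p_[1])[0],
            np.array([u, v]),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
        )
        u, v = res.x
        ll, g, h = _score_hess_uv(y, u, v)
        iters += int(res.nit)
        converged = bool(res.success) and np.max(np.abs(g)) < 1e-5 * max(1.0, abs(ll))
    return np.exp(u), np.exp(v), ll, converged, iters


def _obs_info_lam_beta(y: np.ndarray, lam: float, beta: float) -> np.ndarray:
    """Observed information (negative Hessian of l) in the (lam, beta) chart."""
    n = y.size
    z = np.log(y) - np.log(lam)
    w = np.exp(beta * z)
    t0, t1, t2 = float(np.sum(w)), float(np.sum(w * z)), float(np.sum(w * z * z))
    d2_ll = -(beta / lam**2) * (t0 - n) - (beta**2 / lam**2) * t0
    d2_lb = (1.0 / lam) * (t0 - n) + (beta / lam) * t1
    d2_bb = -n / beta**2 - t2
    return -np.array([[d2_ll, d2_lb], [d2_lb, d2_bb]])


def fit_wtexpd(
    s,
    tau: float | None = None,
    theta_pin: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> FitResult:
    """Fit the W-TEXPD by maximum likelihood with the threshold held fixed.

    When ``tau`` is omitted it defaults to ``min(x) - 0.001 * (max - min)``:
    the threshold must sit strictly below the smallest observation or the
    likelihood is unbounded for beta < 1.  The free parameters are the
    identifiable pair (lam, beta); the raw scales are reported with theta
    pinned at ``theta_pin`` so alpha = lam * theta_pin, and k = 3 parameters
    are charged in AIC/BIC (tau is not counted).
    """
    x = _values(s)
    if x.size < 2:
        raise EstimationError("need at least 2 observations to fit")
    if tau is None:
        rng_ = float(np.max(x) - np.min(x))
        if rng_ == 0.0:
            raise EstimationError("degenerate sample: all observations equal")
        tau = float(np.min(x)) - 1e-3 * rng_
    y = _check_support(x, tau)
    lam, beta, ll, converged, iters = _mle_lam_beta(y, tol, max_iter)
    info = _obs_info_lam_beta(y, lam, beta)
    try:
        vcov = np.linalg.pinv(info)
    except np.linalg.LinAlgError:
        vcov = np.full((2, 2), np.nan)
    se_lam = float(np.sqrt(max(vcov[0, 0], 0.0)))
    se_beta = float(np.sqrt(max(vcov[1, 1], 0.0)))
    params = {
        "tau": float(tau),
        "alpha": lam * theta_pin,
        "theta": float(theta_pin),
        "beta": beta,
        "lam": lam,
    }
    se = {
        "tau": 0.0,
        "alpha": abs(theta_pin) * se_lam,
        "theta": 0.0,
        "beta": se_beta,
        "lam": se_lam,
    }
    return FitResult(
        model="wtexpd",
        params=params,
        se=se,
        loglik=ll,
        k=3,
        n=x.size,
        converged=converged,
        iterations=iters,
        vcov=vcov,
        free_names=("lam", "beta"),
        tau_fixed=True,
        tau_value=float(tau),
        pinned=("theta", "tau"),
        message="" if converged else "optimizer did not meet the score tolerance",
    )


def profile_threshold(
    s,
    taus=None,
    theta_pin: float = 1.0,
    n_grid: int = 50,
) -> FitResult:
    """Profile the threshold over a grid and return the best fit.

    The likelihood is unbounded as tau approaches the sample minimum when
    beta < 1, so the default grid spans (min - range, min - 1e-3 * range)
    rather than touching the minimum itself.  Pass ``taus`` explicitly to
    profile a custom region.
    """
    x = _values(s)
    lo, hi = float(np.min(x)), float(np.max(x))
    if taus is None:
        rng_ = hi - lo
        if rng_ == 0.0:
            raise EstimationError("degenerate sample: all observations equal")
        taus = np.linspace(lo - rng_, lo - 1e-3 * rng_, n_grid)
    best = None
    for tau in np.asarray(taus, dtype=float):
        if tau >= lo:
            continue
        fit = fit_wtexpd(s, tau=float(tau), theta_pin=theta_pin)
        if fit.converged and (best is None or fit.loglik > best.loglik):
            best = fit
    if best is None:
        raise EstimationError("no grid point produced a converged fit")
    return best


def fisher_information(s, p: WTexpdParams) -> np.ndarray:
    """Observed information over (alpha, beta, theta): the negative Hessian of l.

    The (alpha, theta) block is singular along the scale-split direction
    (only the ratio alpha/theta is identified), so the matrix has a null
    eigendirection by construction; standard errors must come from the
    pseudo-inverse restricted to identifiable directions.
    """
    x = _values(s)
    y = _check_support(x, p.tau)
    n = x.size
    alpha, theta, beta = p.alpha, p.theta, p.beta
    lam = p.lam
    logy = np.log(y)
    ell = -np.log(lam)  # ln(theta/alpha)
    w = (y / lam) ** beta
    s0 = float(np.sum(w))
    s1 = float(np.sum(w * logy))
    s2 = float(np.sum(w * logy * logy))
    d2_aa = n * beta / alpha**2 - beta * (beta + 1.0) / alpha**2 * s0
    d2_tt = -n * beta / theta**2 - beta * (beta - 1.0) / theta**2 * s0
    d2_ta = beta**2 / (theta * alpha) * s0
    d2_bb = -n / beta**2 - (ell**2 * s0 + 2.0 * ell * s1 + s2)
    d2_tb = (n - (s0 + beta * ell * s0 + beta * s1)) / theta
    d2_ab = (-n + (s0 + beta * ell * s0 + beta * s1)) / alpha
    hess = np.array(
        [
            [d2_aa, d2_ab, d2_ta],
            [d2_ab, d2_bb, d2_tb],
            [d2_ta, d2_tb, d2_tt],
        ]
    )
    return -hess


def confidence_interval(fit: FitResult, spec: CiSpec | None = None) -> dict:
    """Asymptotic confidence intervals for the free parameters of a fit.

    ``normal``: estimate +- z * se.  ``lognormal``: estimate * exp(+- z *
    se / estimate), guaranteeing positive endpoints for positive estimates.
    """
    if spec is None:
        spec = CiSpec()
    if not fit.converged:
        raise InferenceError("cannot form asymptotic intervals from a non-converged fit")
    z = float(stats.norm.ppf(0.5 + spec.level / 2.0))
    out = {}
    names = fit.free_names or tuple(fit.params)
    for name in names:
        est = float(fit.params[name])
        se = float(fit.se.get(name, np.nan))
        if not np.isfinite(se):
            raise InferenceError(f"standard error for {name!r} is not finite")
        if spec.method == "normal":
            lo, hi = est - z * se, est + z * se
        else:
            if est == 0.0:
                lo = hi = 0.0
            else:
                half = np.exp(z * se / abs(est))
                lo, hi = est / half, est * half
                if lo > hi:
                    lo, hi = hi, lo
        out[name] = (lo, hi)
    return out
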