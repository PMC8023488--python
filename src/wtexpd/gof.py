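"""Model comparison: information criteria and empirical-distribution
goodness-of-fit statistics (Kolmogorov-Smirnov, Cramer-von Mises,
Anderson-Darling) with estimated parameters plugged in.

The statistics are reported bare, without p-values: with parameters estimated
from the same data the textbook critical values do not apply.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import core
from .baselines import (
    BaselineParams,
    baseline_cdf,
    fit_exponential,
    fit_gamma,
    fit_texpd,
    fit_weibull,
)
from .core import WTexpdParams
from .estimation import FitResult, Sample, _values, fit_wtexpd

__all__ = [
    "GofStats",
    "ComparisonReport",
    "ks_statistic",
    "cvm_statistic",
    "ad_statistic",
    "aic",
    "bic",
    "compare_models",
]


@dataclass(frozen=True)
class GofStats:
    """The three empirical-distribution discrepancies for one fitted model."""

    ks: float
    cvm: float
    ad: float

    def to_dict(self) -> dict:
        return {"ks": float(self.ks), "cvm": float(self.cvm), "ad": float(self.ad)}


def _fitted_u(s, cdf_fn) -> np.ndarray:
    x = np.sort(_values(s))
    u = np.asarray(cdf_fn(x), dtype=float)
    if np.any((u < 0) | (u > 1)):
        raise ValueError("cdf_fn returned values outside [0, 1]")
    return u


def ks_statistic(s, cdf_fn) -> float:
    """Kolmogorov-Smirnov D = sup |F_n - F| over the 2n ECDF jump candidates."""
    u = _fitted_u(s, cdf_fn)
    n = u.size
    i = np.arange(1, n + 1)
    return float(np.max(np.maximum(i / n - u, u - (i - 1) / n)))


def cvm_statistic(s, cdf_fn) -> float:
    """Cramer-von Mises W^2 = 1/(12n) + sum (F(x_(i)) - (2i-1)/(2n))^2."""
    u = _fitted_u(s, cdf_fn)
    n = u.size
    i = np.arange(1, n + 1)
    return float(1.0 / (12.0 * n) + np.sum((u - (2.0 * i - 1.0) / (2.0 * n)) ** 2))


def ad_statistic(s, cdf_fn) -> float:
    """Anderson-Darling A^2 = -n - (1/n) sum (2i-1)[ln u_i + ln(1 - u_{n+1-i})].

    Requires every fitted-cdf value strictly inside (0, 1); a boundary value
    usually means the model's threshold coincides with an observation.
    """
    u = _fitted_u(s, cdf_fn)
    n = u.size
    if np.any((u <= 0.0) | (u >= 1.0)):
        raise ValueError(
            "fitted cdf hit 0 or 1 at an observation; place the threshold "
            "strictly below the sample minimum"
        )
    i = np.arange(1, n + 1)
    return float(-n - np.mean((2.0 * i - 1.0) * (np.log(u) + np.log1p(-u[::-1]))))


def aic(fit: FitResult) -> float:
    """Akaike information criterion 2k - 2 l-hat."""
    return 2.0 * fit.k - 2.0 * fit.loglik


def bic(fit: FitResult) -> float:
    """Bayesian information criterion k ln n - 2 l-hat."""
    return fit.k * float(np.log(fit.n)) - 2.0 * fit.loglik


def gof_stats(s, cdf_fn) -> GofStats:
    """All three statistics for one fitted cdf; AD is NaN at boundary hits."""
    try:
        ad = ad_statistic(s, cdf_fn)
    except ValueError:
        ad = float("nan")
    return GofStats(ks=ks_statistic(s, cdf_fn), cvm=cvm_statistic(s, cdf_fn), ad=ad)


@dataclass
class ComparisonReport:
    """Five-model comparison: fits, GoF statistics and an AIC ranking."""

    sample: Sample
    fits: dict
    gof: dict
    errors: dict = field(default_factory=dict)

    @property
    def ranking(self) -> list:
        """Model labels ordered by AIC, ties broken by BIC then label."""
        return sorted(self.fits, key=lambda m: (self.fits[m].aic, self.fits[m].bic, m))

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for name, fit in self.fits.items():
            g = self.gof.get(name)
            rows.append(
                {
                    "model": name,
                    "loglik": fit.loglik,
                    "params": ", ".join(
                        f"{k}={v:.4g}({fit.se.get(k, float('nan')):.3g})"
                        for k, v in fit.params.items()
                    ),
                    "aic": fit.aic,
                    "bic": fit.bic,
                    "ks": g.ks if g else np.nan,
                    "cvm": g.cvm if g else np.nan,
                    "ad": g.ad if g else np.nan,
                }
            )
        df = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
        return df

    def to_text(self) -> str:
        with pd.option_context("display.width", 200, "display.max_colwidth", 60):
            return self.to_dataframe().to_string(
                index=False, float_format=lambda v: f"{v:.4f}"
            )

    def to_json_dict(self) -> dict:
        out = {"sample": {"name": self.sample.name, "n": len(self.sample)}, "models": {}}
        for name, fit in self.fits.items():
            d = fit.to_dict()
            g = self.gof.get(name)
            d["gof"] = g.to_dict() if g else None
            out["models"][name] = d
        out["ranking"] = self.ranking
        out["errors"] = {k: str(v) for k, v in self.errors.items()}
        return out


def _wtexpd_cdf_fn(fit: FitResult):
    p = WTexpdParams.from_scale(
        tau=fit.params["tau"], lam=fit.params["lam"], beta=fit.params["beta"]
    )
    return lambda x: core.cdf(x, p)


def _baseline_cdf_fn(fit: FitResult):
    if fit.model == "weibull":
        bp = BaselineParams("weibull", fit.params["shape"], fit.params["scale"])
    elif fit.model == "gamma":
        bp = BaselineParams("gamma", fit.params["shape"], fit.params["rate"])
    elif fit.model == "exponential":
        bp = BaselineParams("exponential", fit.params["rate"])
    else:
        bp = BaselineParams("texpd", fit.params["rate"], tau=fit.params["tau"])
    return lambda x: baseline_cdf(bp, x)


def compare_models(s, tau: float | None = None, theta_pin: float = 1.0) -> ComparisonReport:
    """Fit the W-TEXPD and the four baselines, score each, and rank by AIC.

    ``tau`` fixes the threshold of the W-TEXPD and the shifted exponential;
    when omitted the W-TEXPD uses its default (just below the sample minimum)
    and the shifted exponential anchors at the minimum itself.  Individual
    model failures are recorded in ``errors`` without aborting the report.
    """
    if not isinstance(s, Sample):
        s = Sample(np.asarray(s, dtype=float))
    x = s.values
    fits: dict = {}
    gof: dict = {}
    errors: dict = {}
    texpd_tau = tau if tau is not None else float(np.min(x))
    recipes = {
        "wtexpd": lambda: fit_wtexpd(s, tau=tau, theta_pin=theta_pin),
        "weibull": lambda: fit_weibull(s),
        "gamma": lambda: fit_gamma(s),
        "exponential": lambda: fit_exponential(s),
        "texpd": lambda: fit_texpd(s, tau=texpd_tau),
    }
    for name, make in recipes.items():
        try:
            fit = make()
            fits[name] = fit
            cdf_fn = _wtexpd_cdf_fn(fit) if name == "wtexpd" else _baseline_cdf_fn(fit)
            gof[name] = gof_stats(s, cdf_fn)
        except Exception as exc:  # record per-row, keep the report going
            errors[name] = exc
    return ComparisonReport(sample=s, fits=fits, gof=gof, errors=errors)
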