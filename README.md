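# wtexpd

Parametric modeling of left-truncated, skewed, heavy-tailed lifetime and
measurement data with the **Weibull-truncated-exponential distribution**
(W-TEXPD) — a four-parameter family built by pushing a left-truncated
exponential variable through a Weibull generator.  It is aimed at
reliability engineers, biostatisticians and environmental scientists who
need a threshold (location) parameter together with a flexible
monotone-hazard shape, and who want the fitted model compared head-to-head
against the classical candidates.

## The model

With location `τ`, shape `β > 0` and raw scale components `(α, θ)` entering
only through the identifiable ratio `λ = α/θ > 0`, the density on `x > τ` is

    g(x) = (β / λ^β) (x − τ)^{β−1} exp{ −((x − τ)/λ)^β }

— a location-shifted Weibull.  Special cases: `τ = 0, θ = β = 1` gives the
exponential with rate `1/α`; `θ = 1` the three-parameter Weibull.  The hazard
`h(t) = (β/λ)((t − τ)/λ)^{β−1}` is decreasing, constant or increasing as
`β <, =, > 1`.

The package provides:

* `wtexpd.core` — pdf/cdf/survival/hazard/cumulative hazard, the exact
  quantile inverse `τ + λ(−ln(1−P))^{1/β}`, inverse-transform random
  variates, moments 1–4, skewness/kurtosis (functions of `β` only), Shannon
  entropy and order-statistic densities.
* `wtexpd.estimation` — log-likelihood, analytic score and observed
  information over `(α, β, θ)`, Newton–Raphson MLE of `(λ, β)` with the
  threshold fixed, and normal / log-normal asymptotic confidence intervals.
* `wtexpd.baselines` — Weibull, Gamma, exponential and shifted-exponential
  MLEs as comparison models.
* `wtexpd.gof` — Kolmogorov–Smirnov, Cramér–von Mises and Anderson–Darling
  statistics, AIC/BIC, and a five-model comparison report.
* `wtexpd.simulation` — Monte-Carlo bias/MSE study of the estimators.
* `wtexpd.datasets` + a `wtexpd` command-line tool with five bundled
  benchmark datasets.

## Worked example

Fit the family to the classic ball-bearing fatigue benchmark (23 lifetimes,
millions of revolutions) with the threshold fixed at 16.25, and compare it
with the four baselines:

```python
>>> import wtexpd
>>> bearings = wtexpd.load_dataset("ball_bearings")
>>> fit = wtexpd.fit_wtexpd(bearings, tau=16.25)
>>> round(fit.loglik, 2), round(fit.params["beta"], 2), round(fit.aic, 2)
(-112.91, 1.52, 231.81)
>>> print(wtexpd.compare_models(bearings, tau=16.25).to_text())
      model    loglik ...      aic      bic     ks    cvm     ad
      gamma -113.0272 ... 230.0544 232.3254 0.1232 0.0392 0.2157
    weibull -113.6887 ... 231.3773 233.6483 0.1513 0.0581 0.3291
     wtexpd -112.9061 ... 231.8122 235.2187 0.1099 0.0345 0.2402
      texpd -115.5783 ... 233.1565 234.2920 0.2328 0.2401 1.2704
exponential -121.4393 ... 244.8786 246.0141 0.3067 0.5369 2.8143
```

Reading the table: the W-TEXPD attains the largest log-likelihood of the
five candidates (−112.91) and the smallest Kolmogorov–Smirnov and
Cramér–von Mises discrepancies (0.110, 0.034), i.e. its fitted cdf tracks
the empirical cdf most closely; the two-parameter Gamma wins on AIC/BIC
because it spends one parameter fewer.  The same comparison is available
from the shell:

```sh
wtexpd compare --dataset ball_bearings --tau 16.25
wtexpd simulate --lam 2 --beta 1.5 --tau 0 --n-list 20,50,100,200 --reps 1000 --seed 1 --out study.csv
```

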