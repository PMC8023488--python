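# Methods

## The family and its parameterization

The W-TEXPD density on `x > τ` is `g(x) = (β/λ^β)(x−τ)^{β−1} exp{−((x−τ)/λ)^β}`
with shape `β > 0`, threshold `τ`, and scale `λ = α/θ > 0`.  The raw pair
`(α, θ)` is jointly unidentifiable: the likelihood depends on it only through
the ratio, so `θ·∂ℓ/∂θ = −α·∂ℓ/∂α` holds identically and the 3×3 observed
information over `(α, β, θ)` has an exact null direction `(α, 0, θ)` at any
stationary point.  All internal computation therefore works in the
identifiable chart `(τ, λ, β)`; the raw pair is reported by pinning `θ` to a
user-chosen value (default 1, so `α = λ`), with the pinned parameter's
standard error reported as 0 and flagged.  Every ratio-dependent quantity
(density, quantiles, likelihood, AIC, GoF statistics) is invariant to the
pin, and `pdf`/`cdf`/`quantile` are invariant under `(α, θ) → (cα, cθ)` for
any `c ≠ 0`.

Closed forms used throughout, with `Γ` the gamma function and
`C ≈ 0.577215664901533` the Euler–Mascheroni constant:

* quantile: `x_P = τ + λ(−ln(1−P))^{1/β}` — the exact inverse of the cdf,
  validated by the round-trip `cdf(quantile(P)) = P` to 1e−10;
* raw moments: `E(X^r) = Σ_k C(r,k) τ^{r−k} λ^k Γ(k/β+1)`, `r ≤ 4`;
* central moments via the standard identities on raw moments, making
  skewness and kurtosis location- and scale-free functions of `β` alone
  (`β = 1` gives the exponential values 2 and 9);
* entropy: `C(1−1/β) + ln(λ/β) + 1`, independent of `τ`.

Boundary convention at `x = τ`: the density limit is 0 for `β > 1`, `1/λ`
for `β = 1`, and `+∞` for `β < 1` (returned with a runtime warning); cdf and
survival are continuous there regardless.

## Maximum likelihood

The log-likelihood with `y_i = x_i − τ` is
`ℓ = n ln β − nβ ln λ + (β−1)Σ ln y_i − Σ(y_i/λ)^β`.  `fit_wtexpd` holds `τ`
fixed and maximizes over `(ln λ, ln β)` — the log chart enforces positivity —
by Newton–Raphson on the analytic score with the analytic Hessian,
step-halving to guarantee likelihood ascent, and a Nelder–Mead fallback if
the Newton iteration stalls.  Starting values come from the Gumbel moments of
`ln y`: `β₀ = π/(√6·sd(ln y))`, `λ₀ = (mean(y^{β₀}))^{1/β₀}`.  Convergence is
declared when the score sup-norm falls below `tol·max(1, |ℓ|)`
(default `tol = 1e−8`); the `converged` flag is honest and non-convergence is
reported, not raised.

**Threshold handling.**  The likelihood is unbounded as `τ ↑ min(x)` whenever
`β < 1`, so `τ` must sit strictly below the smallest observation and is not
estimated by unconstrained ascent.  It is user-specifiable (the application
tables fix it explicitly); the default is `min(x) − 0.001·(max − min)`.  `τ`
is not counted in `k`: the family is charged `k = 3` parameters in AIC/BIC,
which is the convention that makes the information criteria of the reference
application tables internally consistent.

**Inference.**  The covariance of `(λ̂, β̂)` is the inverse of the 2×2
observed information in the `(λ, β)` chart; `se(α̂) = |θ_pin|·se(λ̂)`.
Confidence intervals are normal (`est ± z·se`) or log-normal
(`est·exp(±z·se/est)`), the latter keeping positive parameters positive.
The full 3×3 observed information over `(α, β, θ)` is exposed separately and
agrees with the numeric Hessian of `−ℓ` to 1e−4 relative; because of the
scale-split null direction its inversion must go through a pseudo-inverse.

## Baselines and goodness of fit

Weibull: shape from the profile equation
`1/c + mean(ln x) − Σx^c ln x / Σx^c = 0` by safeguarded (bracketed) Newton;
scale `= (mean(x^c))^{1/c}`.  Gamma: shape from
`ln a − ψ(a) = ln(mean) − mean(ln x)` by Newton with the classical
closed-form start; rate `= a/mean`.  Exponential and shifted exponential are
closed form (`rate = 1/(mean − τ)`, log-likelihood `n(ln rate − 1)`).  The
shifted exponential accepts `τ = min(x)` — its density is finite there — and
that is its default anchor; the Anderson–Darling statistic is then undefined
(a fitted-cdf value of exactly 0) and is reported as NaN rather than
aborting the comparison.

GoF statistics, with `u_i` the fitted cdf at the sorted data:

* KS: `D = max_i max(i/n − u_i, u_i − (i−1)/n)` (handles ties through the
  ECDF jumps);
* Cramér–von Mises: `W² = 1/(12n) + Σ(u_i − (2i−1)/(2n))²`;
* Anderson–Darling: `A² = −n − (1/n)Σ(2i−1)[ln u_i + ln(1−u_{n+1−i})]`.

All three are computed with estimated parameters plugged in and reported
without p-values: the tabulated critical values do not apply in that case,
and simulation-based calibration is out of scope.  `compare_models` ranks the
five fits by AIC with ties broken by BIC then label; per-model failures are
recorded and do not abort the report.

## Monte-Carlo study

`run_study` draws replicated samples by inverse-transform sampling of the
quantile function, refits with `τ` known, and tabulates mean estimate,
Monte-Carlo SE, bias (`mean − truth`) and MSE per `(parameter, n)` cell.
MSE is decomposed as `variance + bias²` with the variance divisor equal to
the replication count (not `reps − 1`); with this convention `MSE ≥ bias²`
holds exactly.  Failed or non-converged replications are excluded, not
imputed, and the exclusion rate is reported per sample size.  The default
design uses sample sizes 20/50/100/200 with 1000 replications; the test
suite runs 200 replications, at which size the bias of `λ̂` is comparable to
its Monte-Carlo standard error, so bias comparisons across `n` are made
within 3 Monte-Carlo SEs while MSE comparisons are strict.  Streams are
seeded per `(seed, n)` so tables are bit-for-bit reproducible.

What the generator emulates — and does not.  Synthetic samples are exact
i.i.d. draws from the family itself, so the study measures estimator
behavior under a correctly specified model with a known threshold.  It says
nothing about misspecification, censoring (unsupported here), measurement
rounding, or threshold uncertainty; real-data performance is probed instead
through the five bundled benchmark datasets.

## Bundled data and known discrepancies

Five published datasets ship verbatim as printed in their source listings.
Two listings are internally inconsistent — the air-conditioner data print 30
values while claiming 31 (the listed values' mean does not match the quoted
58.03), and the wind-loss data print 38 while claiming 40 — and are shipped
exactly as printed with machine-readable caveats rather than repaired from
external sources.

Reference-table notes established while validating against the published
application tables:

* Ball bearings (n = 23, `τ = 16.25`): every fitted log-likelihood, the
  W-TEXPD shape 1.52 and AIC 231.81, the printed standard errors, and the
  exponential KS statistic 0.307 reproduce to printed precision.
* Vinyl chloride (n = 34): the exponential, Weibull and Gamma rows
  reproduce, but the published W-TEXPD log-likelihood −53.19 at the printed
  threshold 0.09 exceeds the likelihood supremum at that threshold, which is
  −53.24; the printed value corresponds to a threshold near 0.093, i.e. the
  printed `(τ, ℓ̂)` pair is mutually inconsistent at 2-decimal rounding.
  This package reports the true maximum for the threshold actually supplied.

## Limitations

No censoring or truncation-from-the-right support; no profile or joint
estimation of `τ` beyond a user-driven grid; asymptotic inference only (no
bootstrap); GoF statistics uncalibrated for estimated parameters.
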