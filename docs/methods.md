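# Methods

## Model

Head circumference `y > 0` at age `t` (days) is modelled, separately per
sex, as Box–Cox Power Exponential:

    z = ((y/μ(t))^ν(t) − 1) / (ν(t)·σ(t))     (ν ≠ 0; log branch at ν = 0)
    z ~ standardized power exponential with kurtosis parameter τ(t)

where μ is the median (cm), σ the approximate coefficient of variation,
ν the Box–Cox skewness power and τ the power-exponential kurtosis
(τ = 2 gives the Box–Cox normal model of the LMS method; τ < 2 heavier,
τ > 2 lighter tails). The standardized PE density is

    f(z) = τ · exp(−|z/c|^τ / 2) / (c · 2^(1+1/τ) · Γ(1/τ)),
    c² = 2^(−2/τ) Γ(1/τ) / Γ(3/τ),

zero-mean and unit-variance, so τ = 2 is exactly N(0,1). CDF and quantile
use |Z/c|^τ/2 ~ Gamma(1/τ): both are closed forms through the regularized
incomplete gamma and its inverse, so quantiles are exact (no root finding)
and the 99-point round-trip identity holds to ~1e-15.

**Truncation.** The exact BCPE renormalizes over y > 0. For anthropometric
parameter magnitudes the missing mass is astronomically small (it is
`F_PE(−1/(|ν|σ))`; with σ ≈ 0.03, ν ≈ 1 this is below 1e-200), so the
untruncated form is used, which keeps the normal-limit identities exact. A
guard raises if the truncation mass of supplied parameters exceeds 1e-6.
|ν| < 1e-6 is routed to the log branch of the transform.

## Estimation

Each parameter curve gets a link (log for μ, σ, τ; identity for ν) and a
cubic P-spline on `x = (t/1800)^ξ` with 16 equispaced interior knots on
[0, 1] and a squared second-difference penalty. The power transform ξ
stretches infancy, where HC growth is steepest; ξ is searched over a
configured set (0.35 works well for birth-to-five charts; 1.0 is the
untransformed axis).

Fitting is the cyclic local-scoring scheme standard for distributional
regression: for one parameter at a time, per-record score u and curvature w
with respect to its predictor η are computed by central finite differences
(h = 1e-4) of the exact log-density, a penalized weighted least-squares
step on the working response η + u/w updates the curve, and the cycle
repeats until the global deviance GD = −2·logL improves by less than 0.01
between outer cycles (max 50 cycles; non-convergence is an error, not a
silent result). Every update is step-halved until it does not increase GD,
so the deviance trajectory is monotone; this also makes the fit robust to
the occasional negative observed curvature (replaced by the median positive
weight).

**Degrees of freedom.** The penalty weight λ for each curve is bisected (on
log λ) until the trace of its smoother matrix equals the per-curve df
target; the reported effective df is that trace at convergence, and
AIC = GD + 2·(total df) holds exactly by construction. Target semantics:
0 = constant (for τ: fixed at 2, the LMS case), 1 = fitted constant,
2 = straight line in x, ≥ 3 = smooth curve. Because the second-difference
penalty has a constant+linear null space, the P-spline edf range is (2, 20]
and the bisection always brackets.

The default search grid (μ ∈ {6, 8, 10, 12}, σ ∈ {3, 4, 5, 6}, ν ∈ {0, 2},
τ ∈ {0, 2}, ξ ∈ {0.35, 1.0}) spans the complexity typical of HC-for-age
charts while keeping a grid sweep to ~128 fits (each fit takes well under a
second at 10⁴ records); tests and the acceptance run use smaller explicit
grids matched to their truth models. AIC ties break toward fewer df.
Repeat visits of the same child are weighted equally — pooling longitudinal
and cross-sectional records without a dependence correction, which slightly
understates parameter uncertainty but is unbiased for the curves
themselves; no centile confidence bands are produced, so nothing downstream
consumes the understated variance.

Initialization: μ from a penalized fit to log y, σ from the residual CV,
ν = 1, τ = 2. Degenerate inputs (all y equal, fewer than 50 records, a
single 120-day age bin, mixed sexes) raise immediately.

## Cleaning semantics

* Health filter first (missing flag = excluded, counted as unhealthy);
  exact-duplicate rows next (all fields equal; first kept); age window
  [0, 1800] inclusive; outlier flags last. Dispositions partition the
  input by construction and are asserted to.
* Outlier z-scores come from an **external** reference chart (never the
  data being fitted, which would be circular), with L, M, S linearly
  interpolated in age; a record is removed iff z > +5 or z < −5 strictly,
  so z = ±5.0 exactly is retained.
* The Mann–Whitney sex comparison is exact by full enumeration for combined
  n ≤ 10 (two-sided: labelings at least as far from n₁n₂/2 as observed) and
  the tie-corrected normal approximation otherwise.

## Synthetic cohort

The generator defines the study conditions the tests run under: 51.6% boys;
ages 0–1800 days drawn as `1800·u^1.6` (front-loaded toward infancy, as in
screening programs where older children visit less); visit counts
{1: .50, 2: .20, 3: .15, 4: .10, 5: .05} so half the cohort is
cross-sectional; sex-specific truth curves with median
`μ(t) = m0 + m1·log(1+t/m2)` rising ≈ 34 → 50 cm, CV falling linearly
0.036 → 0.024, ν = 1, τ = 2, boys 0.5 cm above girls; the recorded HC is
the mean of two simulated tape readings (SD 0.1 cm, re-measured until they
agree within 0.2 cm, rounded to the 0.1 cm tape resolution). Injected
artifacts are exact row copies and HC values displaced to reference
|z| = 8, with a ground-truth manifest.

What this does **not** emulate: within-child correlation of repeat visits
(each visit is an independent draw from the age-specific distribution),
secular trends, digit preference beyond 0.1 cm rounding, missing fields,
or age-dependent skewness/kurtosis. Passing tests therefore demonstrate
correct recovery under the model's own assumptions — the right bar for a
method implementation — not robustness to every pathology of real
registry data.

## Numerical choices and problem sizes

* Reference lookup: linear interpolation of coefficients in age.
* Centile tables are validated to be strictly increasing across levels on
  their evaluation grid (non-crossing).
* Divergence between charts is operationalized as: onset = earliest day on
  the common daily grid from which |fitted − reference| > 0.2 cm holds
  continuously for ≥ 120 days (defaults: the tape-protocol agreement
  tolerance and one age bin). A visual "the curves part after day d"
  judgment becomes reproducible this way; identical charts report nothing.
* Head-size classification uses strict inequalities: strictly above the
  97th centile is macrocephalic, strictly below the 3rd microcephalic,
  boundaries typical.
* Test and acceptance problem sizes — 10³–10⁴ children for cleaning and
  recovery experiments, 2·10⁴ records for the parameter-recovery check —
  were chosen as the smallest sizes at which the binomial coverage
  intervals and the 0.3 cm median-recovery criterion are informative; the
  full suite runs in well under a minute.

## Known limitations

* No bootstrap/analytic confidence bands on centiles; no worm plots or
  Q-statistics beyond empirical centile coverage.
* Only BCPE (and its LMS special case); no Box–Cox t family.
* No CDC-dialect reference files; LMS and BCPE tab-delimited dialects only.
* Fitted curves do not extrapolate outside the fitted age range by design.
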