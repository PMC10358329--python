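# Methods

## Scope and data model

`germkin` models two halves of a seed-physiology experiment. The
**germination/vigor** half scores the same replicate repeatedly: `n_seeds`
seeds per repetition, cumulative germinated counts at a fixed set of scoring
times (hours). The **longevity** half stores seed lots under controlled
conditions and germinates a fresh sub-sample at each storage time (days), so
the series is a set of independent assays whose germination percentage
declines over time. A `TimeCourse` holds one series (counts + `n_seeds`, or
percentages); an `ExperimentSet` holds the repetitions parsed from one file.
Cumulative germination counts must be non-decreasing; scoring slips are
repaired by a running maximum when the caller opts in (`repair=True`), never
silently. Longevity series are exempt from the monotonicity check because
they decline by nature.

The table format is a wide layout of adjacent column pairs — a measurement
column plus its own `Time` column, either order, the time member recognised
by the token "time" in the header — so a single CSV carries several
measurements on heterogeneous grids. The dialect is fixed (comma separator,
`.` decimal mark, UTF-8, header required); a `decimal_comma` switch accepts
semicolon-separated files with `,` as the decimal mark. XLSX import (first
sheet) is a convenience path through pandas/openpyxl; CSV is the contract.

## Nonparametric indices

All indices are computed per repetition from the cumulative curve:

- **Germinability** G: final cumulative value as a percent of seeds sown.
- **Mean germination time** t̄ = Σ nᵢtᵢ / Σ nᵢ, where nᵢ are the new
  germinations in the interval ending at tᵢ. Events are attributed to the
  interval's **right endpoint**: with daily (or coarser) scoring the exact
  event time is unknown and the scoring time is the conventional choice.
  The mean rate is v̄ = 1/t̄ by construction, so v̄·t̄ = 1 holds exactly per
  repetition; pooled values average the per-repetition indices, which is why
  a pooled v̄ is generally not the reciprocal of the pooled t̄.
- **Level-crossing times** (t10, t16, t50, t84): linear interpolation of the
  cumulative curve at level q·(final count) (`of_final`, the default) or
  q·(seeds sown) (`of_sample`). When the level coincides with an observed
  plateau value the earliest time attaining it is returned. t50 is the
  median germination time of the germinated fraction; t10 defaults to
  `of_final` with `of_sample` available by flag, since "10% of the sample"
  and "10% of the germinated seeds" are both in use in the literature.
- **Uniformity** u_8416 = t84 − t16. Note that under linear interpolation a
  single-interval jump gives u = 0.68·Δt, not 0; u = 0 only when the final
  level is already attained at the first scoring.
- **AUC**: trapezoidal area of the cumulative-percent curve on [0, cutoff]
  (default 120 h), with (0, 0) prepended when the first scoring time is
  positive, flat extension past the last observation, and interpolation at
  the cutoff when observations extend beyond it. Both the raw area
  (percent·time) and the cutoff-normalized area (raw/cutoff, ≤ 100) are
  reported because the community is not consistent about the scaling.

Pooling across repetitions is either `mean_of_repetitions` (average each
index; repetitions where an index is undefined are skipped for that index)
or `pooled_counts` (sum counts on a common grid, then compute once).

## Sigmoid models and derived half-times

Four model functions, all returning percentages:

| model | form | half-time (t50/P50) |
|---|---|---|
| Boltzmann | (A1 − A2)/(1 + e^((t−t0)/dt)) + A2 | t0 |
| Gompertz | a·e^(−e^(−k(t−tc))) | tc − ln(ln 2)/k |
| Hill | y0 + a·xᵇ/(cᵇ + xᵇ) | c |
| logistic | A/(1 + e^((t−t_half)/s)) | t_half |

The half-time is defined as the time at which the curve crosses the lower
plateau plus half the plateau span. For Hill with y0 ≠ 0 the "50%" level is
referred to the span a above y0, so the answer remains c. The Gompertz
inflection time tc satisfies y(tc) = a/e ≈ 0.368a, *not* a/2, so the
half-maximum time is derived analytically; both values are reported (the
analytic one as the half-time, tc labelled as the inflection time). The
logistic scale s is sign-coded: s > 0 declines (longevity), s < 0 rises
(germination). Exponents are clamped at ±700 before exponentiation (the
float64 overflow edge is ≈709), which saturates the curve at its plateaus
continuously; the Hill ratio xᵇ/(cᵇ+xᵇ) is evaluated in log space for the
same reason.

## Nonlinear fitting

Fits are unweighted least squares of the cumulative percent curve — the
convention for this kind of tool; binomial weighting is a deliberate
non-goal. The optimizer is a self-contained Levenberg–Marquardt iteration
with a forward-difference Jacobian (relative step 1e−6 with the same
absolute floor), solving (JᵀJ + λ·diag(JᵀJ))δ = Jᵀr, accepting a step only
when the SSE decreases: λ ← λ/10 on acceptance, λ ← 10λ on rejection,
starting at λ = 1e−3. Termination: relative SSE improvement < 1e−10,
gradient max-norm < 1e−8, or 1000 iterations. Trial parameter vectors
outside a model's domain (e.g. Hill b ≤ 0) or producing non-finite
predictions are rejected like any uphill step, so the iteration cannot
leave the valid region. The returned SSE is never above the SSE of the
initialization. If the first run does not converge, up to 5 restarts jitter
the initial parameters by seed-controlled multiplicative factors in
[0.5, 2] (sigmoid SSE surfaces are multimodal in the shape parameters);
the best solution is kept and flagged `converged=False` if none converged.

Initialization is data-driven: asymptotes from the observed extremes (the
first observation anchors the upper plateau of a declining series), the
half-time parameter from the interpolated 50%-of-span crossing (median
observation time as fallback for flat data), the width scale from the
16–84% crossing spread (a quarter of the time range as fallback), and
Hill b = 4 as a generic steepness.

Quality metrics: SSE, SST, MSE = SSE/n, residual standard deviation
SDR = sqrt(SSE/(n−p)), R² = 1 − SSE/SST and
R²adj = 1 − (1−R²)(n−1)/(n−p). R² is undefined (NaN) for constant
observations; SDR is still reported. The parameter covariance is
SDR²·(JᵀJ)⁻¹ at the optimum (pseudo-inverse fallback when JᵀJ is singular);
confidence intervals are Wald intervals with Student-t quantiles on n−p
degrees of freedom, and the half-time interval is propagated by the delta
method using a numerical gradient of the half-time in the parameters.
Wald intervals are the documented choice; profile or replicate-based
intervals are out of scope.

## Linearized viability models

The longevity cross-check transforms observed proportions with the probit
(Φ⁻¹) or logit (log-odds) link and fits F(pᵢ) = β0 + β1·tᵢ by ordinary
least squares (statsmodels OLS). P50 = −β0/β1 is the storage time at which
the fitted probability is 0.5 absolutely — consistent with "lost 50% of
viability" when initial viability is ≈100%. Boundary proportions (0 or 1)
are undefined under either link: the default drops them (recording them in
the result), and `boundary="adjust"` applies the empirical-probit shrinkage
(n·p + 0.5)/(n + 1), which requires counts. This is deliberately the
textbook linearized fit, not a binomial GLM with IRLS, to stay faithful to
how such two-step analyses are actually run; quality metrics therefore live
on the transformed scale.

The normality check is the one-sample Kolmogorov–Smirnov statistic against
a normal with the sample mean and standard deviation, rejected when
D > c(α)/√n with c(α) = sqrt(−ln(α/2)/2) (c(0.05) ≈ 1.358). Using the
plain-KS critical value with estimated parameters is anticonservative; the
Lilliefors correction is noted but intentionally not applied, matching the
plain-KS convention of the workflow this package mirrors.

## Synthetic experiments

The generator reproduces the standard bench design — by default 4
repetitions of 50 seeds (100–400 in the heavier validation runs) on a fixed
scoring grid — around a latent sigmoid. Germination noise is a **counting
process**: the increment over each interval is binomial in the seeds that
have not yet germinated, with conditional hazard
(pᵢ − pᵢ₋₁)/(1 − pᵢ₋₁). This guarantees monotone counts bounded by
`n_seeds` (each seed germinates once), unlike independent per-time
binomials. Longevity noise draws independent binomials per storage time,
matching the independent-assay design. Noiseless mode rounds n·pᵢ half-up
(for cross-platform determinism) and re-monotonizes. Streams are
deterministic under (`rng_seed`, repetition index).

What the generator does *not* emulate: between-replicate heterogeneity
(seed-lot mixtures), dormancy plateaus and secondary dormancy, scoring-time
jitter, temperature/RH covariate response, or overdispersion beyond
binomial. Recovery and coverage results on these simulations therefore
demonstrate correctness of the estimators under the stated sampling model,
not robustness to those real-data features.

## Validation conditions

The stochastic checks use: Hill truth (y0=0, a=90, b=4, c=63 h) scored at
12 times 12 h apart with 100 seeds per repetition; probit-linear viability
truth Φ(2 − 0.04t) (P50 = 50 days) assayed at 9 storage times with 400
seeds; Wald coverage on 500 refits with homoscedastic Gaussian noise
(sd = 2 percentage points), a design where the linearization behind Wald
intervals is accurate. Problem sizes (200–500 replicates) keep the whole
validation in the order of seconds while leaving binomial Monte-Carlo error
well below the tolerances checked.

## Known limitations

- Unweighted LS on cumulative percentages ignores the binomial variance
  structure and the serial correlation of cumulative counts; standard
  errors are conditional on that working model.
- The linearized P50 is biased when the true viability curve is not
  probit/logit-linear (model mismatch, e.g. a logistic latent with plateau
  below 100%).
- The plain-KS critical value over-rejects slightly with estimated
  parameters.
- No analytic Jacobians; very flat or unidentified fits end with
  `converged=False` and the best point found.
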