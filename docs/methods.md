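# Methods

## Model

Stunting prevalence in under-fives at level *k* (2 = moderate, > 2 SD
below the reference height-for-age; 3 = severe, > 3 SD) in a country is
modelled as a bilinear function of two aggregate causes:

    y_k = α_k + β_k x + γ_k w + θ_k x w ,      y_1 = 1 − y_2 − y_3

* *x* — food causes, proxied by the prevalence of undernourishment
  (PoU), the model-based share of the population whose habitual calorie
  intake falls below the minimum dietary energy requirement.
* *w* — nonfood causes (sanitation, maternal education, care, health
  services …), collapsed into a 0–1 development score driven by per
  capita GDP and the Gini coefficient.
* β_k is interpreted as a physiological constant: the stunting risk a
  calorie deficit carries even under otherwise optimal socioeconomic
  conditions. It is assumed stable over decades, which is what makes the
  model usable for projection; γ_k and θ_k, which depend on social and
  political mediation, are re-estimated from data and carry standard
  errors.

No/mild stunting is the complement, so the three levels always sum to 1
by construction; the two modelled levels are fitted independently, which
is a deliberate first approximation — a simultaneous constrained fit
could trade goodness of fit between levels.

## Fitting: stepwise attribution

1. **β_k** is estimated from the distribution of observed ratios
   y_k/x over the *entire* panel (records with x = 0 are excluded and
   counted). The conceptual estimator is the minimum of the ratio — the
   country where nonfood causes contribute least — but the minimum is
   fragile to data error, so the 5th percentile is used as the central
   value with the 1st and 10th percentiles as a plausible range.
   Percentiles are linear interpolations between closest order
   statistics (`numpy.percentile`, method `"linear"`: rank
   h = (n−1)q/100); the rule is pinned by a brute-force order-statistic
   oracle in the tests.
2. The food-attributable share r = β_k·x is subtracted; the residual
   s = y − r (nonfood + interaction) may be negative and is retained —
   truncating it would bias the regression.
3. **α_k, γ_k, θ_k** come from OLS of s on (1, w, x·w) on a training
   split (default four fifths of the panel; the holdout fraction uses
   round-half-up, so 186 records at 0.2 reserve exactly 37). x and x·w
   are correlated regressors; this is accepted as an approximation and
   the design's condition number is logged. A rank-deficient design
   (e.g. constant w) is fatal.
4. Validation reports Pearson correlations between predicted and
   observed proportions per level on the holdout, with observed no/mild
   stunting taken as the complement of the two observed levels.

## The development score

The score must be 0 where socioeconomic conditions stop contributing to
stunting — taken to be per capita GDP of $10,000 (2000 US$) with an
associated Gini of 0.38 — and 1 at the worst baseline conditions in the
calibration panel. Between those anchors the functional form is this
package's own construction: GDP and Gini are collapsed into
inequality-adjusted income a = GDP·(1 − Gini) and the score
interpolates linearly in ln a,

    w = clamp( [ln a_opt − ln a] / [ln a_opt − ln a_worst], 0, 1 )

with a_opt = 10000·(1 − 0.38) = 6200 and a_worst the panel minimum of
a. Log income is the standard scale for income–health gradients, and the
form satisfies every property required of the score (range, endpoints,
saturation, monotonicity in both drivers). It is deliberately kept
behind the module surface so an alternative index can be swapped in.
`unsaturated_anchors` replaces the fixed optimum with the best adjusted
income observed in the panel, and
`projection.saturation_sensitivity_report` tabulates regional means
under both choices side by side; this is a comparison report, not a
thresholded check. Gini is held at baseline in projections (no credible
projections of inequality exist).

## Undernourishment

Within-population habitual intake is lognormal with mean equal to per
capita dietary energy supply (DES, kcal/person/day) and a given CV:
σ² = ln(1 + CV²), μ = ln DES − σ²/2, and PoU = F(MDER). The CV and the
population-average MDER are held at baseline in all scenarios — only
calorie availability is scenario-dependent. The MDER is a scalar per
country, not an age–sex composition model. `solve_des` inverts the CDF
by Brent root-finding (rather than the lognormal closed form) so it
remains valid if the distribution family is swapped; the closed form
serves as an independent oracle in the tests.

## Monte Carlo projection

Parameter uncertainty: α, γ, θ ~ Normal(point, SE); β ~ Uniform(1st,
10th percentile). Each draw is pushed through the surface at the
scenario's (x, w); draws are accepted iff 0 < y < 1 and sampling
continues until 100,000 (default) are accepted — the stream is "the
first N accepted", implemented in batches with the cut placed exactly at
the draw yielding the Nth acceptance, so it is bit-reproducible.
Rejections below 0 and above 1 are counted separately and always
reported: rejecting the left tail biases the accepted mean upward (and
the right tail downward), so the counts are the truncation-bias
diagnostic. If fewer than 1% of a first probe batch are accepted the run
aborts — essentially all parameter mass maps outside (0, 1), meaning the
inputs are far outside the fitted range. Projected undernourishment
above 0.76, the calibration maximum, triggers a logged caution.

Reproducibility: every (country, scenario) gets a seed derived from the
master seed and CRC-32 hashes of its identifiers, with one spawned child
sequence per level, so streams are independent and identical regardless
of iteration order. Levels are sampled independently; implied no/mild
stunting is computed on summary means and a negative value would be a
reported diagnostic, not an error.

Aggregation: regional sample t is the population-weighted mean of the
country samples at draw index t (projected under-5 population by
default), so the regional mean is exactly the weighted mean of country
means. Summaries report the arithmetic mean, sample SD (n−1),
percentiles, and a 50-bin histogram over [0, max]. The headline
comparison is the relative increase 100·((m_a + m_b)/2 / m_ref − 1) of
the two climate-scenario means over the reference mean, reported both
unrounded and rounded half-up — rounding inputs before comparing can
shift the printed percent by a point, which is why the unrounded value
is retained.

## Synthetic data

The generator draws panels with the structure the model assumes, with
known ground truth, so fitting and projection are testable end to end
without any data download. Choices, made once:

* **Size and ranges.** 186 records over 62 countries in 5 regions,
  years 1988–2008; undernourishment 5–70%, GDP $81–$5,513, Gini
  0.17–0.74 — the observed global calibration ranges.
* **Covariate draws.** Independent; uniform for undernourishment and
  Gini, log-uniform for GDP (income is right-skewed: the log-uniform
  mean ≈ $1,290 is near the observed panel mean ≈ $900, a uniform draw's
  ≈ $2,800 is not).
* **Noise.** Gaussian per level, SD 0.02 on the proportion scale
  (the residual dispersion left after the bilinear surface), truncated
  by resampling — not clipping — so there are no point masses at the
  bounds. Records whose severe-level surface sits within ~2 SD of zero
  acquire a small upward truncation bias; with these defaults the
  2-SE coverage of the regression estimates stays ≈ 95% (≈ 93% for the
  severe intercept), which the replication test verifies.
* **Scenarios.** Baseline calories are back-solved from each country's
  latest panel undernourishment; climate scenarios apply multiplicative
  calorie shifts (defaults 0.87 and 0.88 vs 1.0 for the reference) —
  a 12–13% calorie deficit, enough to roughly double undernourishment in
  poor regions, the magnitude the model is meant to interrogate. GDP is
  grown by a per-region multiplier drawn from 2–6×, identical across
  scenarios for within-scenario consistency. Scenario generation covers
  only countries with baseline GDP ≤ $800: projection focuses on
  low-income regions, and high-income countries grow past
  development-score saturation where the model is explicitly outside its
  fitted range (their severe-stunting surface turns negative and the
  engine would correctly refuse to sample).

What the generator does *not* emulate: correlation between covariates
(an optional realism knob for GDP–undernourishment correlation was
considered and left out for test transparency), survey measurement
error, reference-standard changes between growth curves, or any
geographic realism beyond region labels. Passing tests therefore show
that the estimators recover the model's own data-generating process at
realistic sizes and noise — not that the model is correct for real
populations.

## Numerical choices and degenerate inputs

* Percentile rule as above; with percentiles (0, 0, 0) the β estimator
  degenerates to the pure minimum.
* Proportion columns supplied as percentages are auto-detected (most
  values > 1, none > 100) and divided by 100 with a warning; a lone
  value just above 1 is treated as a validation error instead.
* CSVs are written with `%.17g` and parsed with round-trip float
  precision, so write → read is lossless.
* Zero standard errors and a collapsed β range are valid and reproduce
  point estimates exactly (used for degenerate-mode checks).
* A Gini of 1, zero variance in validation observations, empty panels,
  mismatched sample counts in aggregation, and a zero reference mean in
  the relative increase are all rejected or flagged rather than
  silently propagated.

## Problem sizes

Default test and example runs use the generator's native sizes (186
records; 100,000 accepted draws per level where the full-scale engine is
exercised, a few thousand in pipeline round-trips; 200 replications for
coverage; 10⁶ draws for the undernourishment Monte Carlo oracle).

## Known limitations

* The development-score functional form between its anchors is a
  reconstruction; conclusions sensitive to its curvature should use the
  sensitivity report.
* β percentile estimation is biased toward the low tail by design (it
  is meant to approximate the food-only floor); errors in β propagate
  into α through the stepwise attribution, so α is only interpretable
  jointly with the β used.
* Upstream uncertainty in calorie and GDP projections is not
  propagated — only stunting-model parameter uncertainty is.
* The intake distribution's shape (lognormal, fixed CV) and the Gini
  are frozen at baseline; distributional change is future work.
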