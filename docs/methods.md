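# Methods

## The analysis model

The package tests whether mean self-referent response latency is an
inverted-U function of depression severity. The explicit measure is the
converted mobile total `T_p` (0–80); the implicit measure is the mean
item-centered latency `r̄_p` in milliseconds. Two nested OLS models are fit:

    linear:     r̄_p = β0 + β1 T_p + ε_p
    quadratic:  r̄_p = β0 + β1 T_p + β2 T_p² + ε_p

Each model's own overall F is reported, and the models are compared with the
hierarchical increment test

    F(1, n−3) = (R²_q − R²_l) / ((1 − R²_q) / (n − 3)).

The two per-model F statistics are the headline comparison customary in this
literature; the increment test is the statistically correct adjudication
between nested models, so both are computed and labelled. The quadratic is
"preferred" only when the increment is significant at the configured alpha
(default .05), and the sign of β2 is reported separately: an inverted U
requires a *negative* quadratic coefficient, not merely a significant one.

Assumptions: one latency summary per participant (no item-level modelling),
homoscedastic errors, independence across participants. Normality of both
variables is screened with a one-sample Kolmogorov–Smirnov test in the
legacy-SPSS convention: D against Normal(x̄, s) with s on n−1, "Z" = √n·D,
p from the asymptotic Kolmogorov distribution, no Lilliefors correction
(available behind a flag). Because it is ambiguous which variable such a
screen should target, the pipeline applies it to both the score and the
latency summary and reports both.

## Scoring conventions

* A day is completed only when all `n_items` items were answered; partial
  days can only arise from corrupted exports (the app forces full traversal
  before saving) and never enter P or Q.
* Conversion bins are left-closed with the top bin closed at 1, so
  Yes-fractions above 13/14 — which arise whenever P < 14 — remain scorable.
* The P denominator counts completed days regardless of whether a session
  fell inside the ±6 h daily window; window compliance is a quality metric,
  not a scoring rule.
* Participants with fewer than 7 completed days are retained in the output
  with `eligible=False` and no total, rather than dropped silently, so
  exclusion accounting is visible downstream.
* The either-scale risk rule flags a participant when any supplied total
  (mobile or retrospective) reaches the cutoff (default 13).

## Latency centering

Only the item effect is removed: `rt − μ̂_i`, with `μ̂_i` the pooled mean
latency of item i over the analysis sample (eligible participants, all 14
sessions pooled — restricting to a session subset is exposed as a switch but
not endorsed). Person effects are deliberately preserved; double
standardization (also removing person mean/variance) induces artefactual
negative correlations between items differing in mean latency and removes
severity-related psychomotor slowing that belongs to the signal. Useful
identities that the tests rely on: the pooled per-item mean of centered
latencies is 0; the response-weighted sum of `r̄_p` over the centering
sample is 0; holding item means fixed, shifting one participant's latencies
by +c shifts their `r̄_p` by exactly +c. No latency trimming is applied by
default; a winsorizing cap is available but off, because outliers are meant
to surface in residual diagnostics (|standardized residual| > 3).

## Psychometric statistics

All implemented to match the conventions of the legacy SPSS platform these
analyses are usually reported from: percentiles by the weighted-average
HAVERAGE definition at (n+1)p; bias-adjusted skewness G1 and excess
kurtosis G2 with standard errors

    SE_skew = sqrt(6n(n−1) / ((n−2)(n+1)(n+3)))
    SE_kurt = 2·SE_skew·sqrt((n²−1) / ((n−3)(n+5)))

(0.30 and 0.59 at n=65); Cronbach alpha on the converted 0–4 item scores of
eligible participants with n−1 variances (the binary daily matrix is the
other candidate input; the converted matrix is the only per-item variable on
the 5-point metric, so it is the default and the choice is recorded here);
Spearman rho as the Pearson correlation of midranks with a t-approximate
p on n−2 df; Wilcoxon signed-rank with zero-difference removal, midranks on
|d|, tie-corrected variance, no continuity correction, and an exact
sign-enumeration p (valid under ties by symmetry) whenever ≤ 12 nonzero
differences remain.

## The synthetic cohort generator

The generator emulates the study design the analysis assumes: ~70
participants, 20 items, 14 daily sessions, day-level missingness, binary
responses driven by a latent severity, and latencies with item, person and
severity components. Defaults, with rationale:

| parameter | default | why |
|---|---|---|
| `n_participants` | 70 | typical enrolment for this design |
| `n_items`, `n_days` | 20, 14 | the instrument and protocol |
| `severity_mean/sd` | 0, 1 | standardised latent severity |
| `item_difficulty b_i` | 0.8 … 4.0 | non-clinical cohorts endorse few symptoms (median total ≈ 2, strongly right-skewed); the hardest items stay unendorsed even at severe θ, keeping expected totals where the latency law is physically sensible |
| `item_discrimination a_i` | 2.0 | gives converted-score internal consistency (alpha ≈ .92) in the range reported for this instrument family |
| `rt_item_mean μ_i` | 2400 … 4000 ms | realistic self-report item latencies; spread stands in for item length/vocabulary effects |
| `rt_person_sd` | 300 ms | person speed spread; with the curve below this reproduces the reported effect-size regime (quadratic R² ≈ .4, linear ≈ .25 at n = 70) |
| `rt_noise_sd` | 600 ms | trial-to-trial noise; averaged over ~250 responses it contributes little to `r̄_p` |
| `f(T) = h − c(T − v)²` | h=400, v=8, c=2 | concave latency component on the *expected* total score, so the generative truth lives on the same axis the regression uses; the vertex sits at mild severity, below the risk cutoff |
| `miss_prob` | 0.1 | ~93% adherence at the ≥7-day rule |
| `mnar_slope` | 0 (MCAR) | severity-dependent nonresponse is a documented bias risk of ratio scoring; positive values emulate it |
| `rt_floor_ms` | 50 ms | physical plausibility floor |

Timestamps are placed at 24 h spacing with uniform ±6 h jitter, matching the
app's completion window. Days are independent Bernoulli draws — no
day-to-day symptom autocorrelation, no practice effects on latency, no
device/OS latency differences, no item-order effects. Auxiliary scale totals
(retrospective 0–80, QIDS-like 0–26, PHQ-9-like 0–27) are strictly monotone
noisy transforms of θ clipped to range and kept real-valued so that the
noiseless map is tie-free.

A constraint worth stating explicitly: the quadratic latency law is only
meaningful where it predicts positive latencies. Parameter sets whose
curvature drives `μ_i + f(T)` far below zero at attainable scores make the
positivity floor, not the parabola, the operative model — fits then recover
neither. The defaults keep predicted latencies positive over the realistic
score range (floored trials ≈ 0.1%).

What passing tests on these cohorts do **not** show: that real diary data
satisfy the 2PL response model, MCAR missingness, or a severity-latency link
of this parametric form. The generator establishes that the *pipeline*
detects the structure when present, at the correct false-positive rate when
absent — not that the structure exists in any particular population.

## Monte-Carlo experiments and problem sizes

* Nested-model preference and coefficient sign: 200 replicate cohorts of 500
  participants under default (concave) settings; the quadratic should be
  preferred in ≥ 90% and β2 < 0 in ≥ 95%.
* Type-I error: 400 replicate cohorts of 120 participants with the
  severity-latency link removed (`rt_quad_curvature = rt_quad_height = 0`);
  the increment test at alpha .05 should reject at its nominal rate.
* Vertex recovery: the OLS quadratic on the *observed* total is not a
  consistent estimator of the generative vertex — day-sampling noise in the
  total, under a heavily right-skewed score distribution, warps the
  regression function away from the generative parabola by more than the
  vertex's standard error at n = 500. Recovery is therefore assessed on the
  axis the curve is defined on: profiles are regressed on the sidecar's
  expected total, with severity spread 0.75 so the latency law stays in its
  positive range, and the known vertex must fall inside the delta-method 95%
  band in ≥ 90% of 40 replicates of 500 participants.

## Numerical choices

* Bin lookup by `searchsorted(..., side="right")` — exactly the left-closed
  printed intervals; boundary behaviour is tested at ±1e−9.
* Expected total `T̂(θ)` sums, over items, the expectation of the converted
  bin score under Binomial(n_days, π_i(θ)) — full adherence assumed.
* OLS through statsmodels on a Vandermonde design; rank deficiency (≤ degree
  distinct scores) is rejected before fitting. A perfect quadratic fit makes
  the increment F infinite with p = 0; a perfect fit also yields standardized
  residuals of 0 rather than 0/0.
* Exact Wilcoxon enumeration switches on at ≤ 12 nonzero differences
  (4096 sign vectors).
* Determinism: all generator draws flow from one `numpy` Generator seeded by
  the config; pipeline outputs are byte-identical across runs for a fixed
  seed.

## Limitations

* One latency summary per participant discards within-person information; no
  mixed-effects or item-level latency modelling, and no IRT fitting.
* The converted total's measurement error is score-dependent; plain OLS
  ignores it (by design, to mirror the analysis being reimplemented).
* No confidence interval for Cronbach alpha; no test–retest reliability.
* The generator's auxiliary scales share the single latent θ with the diary,
  so concurrent-validity correlations on synthetic data are upper bounds on
  what heterogeneous real instruments would show.
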