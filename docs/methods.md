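# Methods

`coldrange` models how winter cold limits the overwintering range of a
chill-sensitive insect pest (the motivating case is the diamondback moth,
*Plutella xylostella*, a crucifer specialist) and how overwintering
persistence relates to pesticide-resistance levels across sites. This
note documents the models, the tunable parameters, the synthetic-data
assumptions, and the numerical choices.

## Thermal predictors

The package's central metric is the **low-temperature degree-day sum**

    LTDD = Σ_j max(0, x0 − T_j)        [°C·day]

over the days *j* of a window, with cold threshold `x0 = 11.0 °C` —
the temperature below which larval and pupal survival of the focal pest
is reduced. Chronic chill injury accumulates roughly linearly in
time-below-threshold, which motivates the degree-day form; acute limits
(supercooling points, CTmin) are deliberately not modelled, because
field mortality occurs well above them.

Annual accounting windows are hemisphere-aware: in the northern
hemisphere the cold season straddles the calendar year, so the window
for label year *i* runs 1 July *i* – 30 June *i+1*; in the southern
hemisphere it is calendar year *i*. Cells exactly on the equator use
the northern window (a deterministic tie-break). Windows are defined by
calendar dates, so leap years contribute 366 days — the quantity is a
sum over physical days, not a fixed-length vector.

Companion predictors: `MinDTmean` (lowest daily mean in the window),
`DTmean` + exposure days (window mean temperature paired with duration;
the mean is taken over *all* days of the window, duration being carried
by the separate covariate), and the growing-season covariate **ETDD**,

    ETDD = Σ_j max(0, min(T_j, 33.0) − 7.4)   [°C·day]

accumulated over the calendar year at all latitudes (no hemisphere
split: it is a growing-season heat proxy, not a cold-season one).

Missing days: up to 2% of a window (configurable) may be absent and is
filled by linear interpolation in time, using neighbouring observed
days (which may lie just outside the window); more raises a coverage
error. Gridded inputs are assumed gap-free.

## Winter-survival models

Nine candidates: three predictors × three forms, with survival
proportion S and predictor X:

| form        | S(X) |
|-------------|------|
| linear      | a + bX |
| exponential | a·exp(bX) |
| sigmoid     | a / (1 + exp(−(X − c)/d)) |

For the two-covariate predictor (DTmean, days) the term bX is replaced
by b₁·DTmean + b₂·days (the sigmoid then uses that linear predictor
against a threshold c). These are the simplest standard members of each
family. Predictions are clipped to [0, 1]; fitting uses the unclipped
response so gradients stay informative.

Fits are nonlinear least squares on raw survival proportions
(Levenberg–Marquardt, five deterministic starts from a coarse grid over
plausible coefficient ranges, RSS tolerance 1e-10), not a binomial GLM —
matching how such curves are conventionally fitted in this literature.
Observations are internally sorted before fitting so results are
invariant to input order. Model comparison uses the least-squares AIC

    AIC = n·ln(RSS/n) + 2k,

ranked ascending with ties broken by higher R², then fewer
coefficients; the additive constant from the error-variance parameter
is common to all models on the same data and omitted. RSS = 0 yields a
−∞ sentinel.

Coefficient standard errors use a heteroscedasticity-robust (sandwich)
covariance, (JᵀJ)⁻¹ Jᵀdiag(r²)J (JᵀJ)⁻¹ · n/(n−k): proportions carry
binomial variance p(1−p)/n that varies strongly along the survival
curve, so the constant-variance NLS covariance would be miscalibrated.

A caveat the package's own simulations make explicit: the sigmoid
family contains the exponential as a tail limit (c → ∞ at fixed
a·e^{c/d}), i.e. the families are effectively nested with one extra
parameter. Even when data are generated exactly from the exponential
law at the chamber design scale (220 observations), AIC prefers the
sigmoid in roughly 6–11% of replicates — the familiar overselection
rate of a one-parameter-richer nested rival. Users ranking models on a
single data set should read small AIC gaps between these two forms
accordingly.

**Field validation** regresses observed field survival on model
predictions (OLS): slope, intercept, R², and bias = |slope − 1|.
Field records whose exposure window accumulated no cold (LTDD = 0) are
excluded by default — winters warm enough for continuous development
produce survival unrelated to chill load.

## Range mapping

The selected LTDD model is projected per grid cell: yearly LTDD →
yearly predicted survival → the *n*-year mean of yearly survivals
(means of predictions, not prediction at the mean — the distinction
matters because the curve is convex). Cells are classified:

- **permanent**: 5-year mean winter survival ≥ 5%
- **marginal**: survival in [1%, 5%) (left-closed, so the three classes
  partition [0, 1])
- **transient**: survival < 1%
- **masked**: host-plant presence probability < 0.3, overriding climate
  (no host, no overwintering) — the host surface is an input product
  from a species-distribution model; a smooth synthetic stand-in is
  generated for testing.

Cell areas use spherical cos-latitude weighting, (111.195 km·d)²·cos φ
for a d°×d° cell (mean Earth radius 6371 km) — this reproduces
global-area magnitudes without a projection library. Area summaries
count unmasked cells at the ≥1% and ≥5% cutoffs; expansion series
difference each year against a baseline year and aggregate in
non-overlapping 5-year blocks anchored at the baseline. Warming
scenarios shift every daily temperature by a constant ΔT (+1…+6 °C by
default). The marginal-belt trend selects the cells classified marginal
in the baseline year and regresses their mean annual LTDD on year by
OLS; the p-value is the slope's two-sided t-test (equivalently the
one-predictor regression F-test).

## Resistance meta-analysis

Each record is a leaf-dip bioassay comparing a field population's LC50
with a susceptible reference; RR = LC50_field / LC50_susceptible.
Effect sizes follow the log response-ratio convention (natural log;
log₁₀ appears only where stated):

    logRR = ln RR
    SE    = (CI_upper − CI_lower) / (2·1.96)          per population
    V     = SE_f²/(n_f·LC50_f²) + SE_s²/(n_s·LC50_s²)
    w     = 1/√V,   wlogRR = logRR · w

Records missing any variance ingredient get the arithmetic mean V of
complete records (prognostic imputation), flagged. Zero variances
(zero-width CIs) would give infinite weight and are floored at the 1st
percentile of positive complete-record variances, flagged.

Sites are annotated with the 5-year means (the five annual windows
preceding the sample year) of LTDD, ETDD and modelled winter survival
at the nearest grid cell, and classified by the survival cutoffs above.
Records whose windows are not covered by the climate record are dropped
with a logged count, not fatally.

Group summaries: the **weighted mean resistance ratio** per
overwintering type is the weight-weighted mean of logRR back-transformed
by exp — a weighted geometric mean, the natural back-transform for
log-ratio effect sizes (invariant to record order and uniform weight
rescaling). Five resistance levels partition (0, ∞): susceptible
RR ≤ 1, low 1 < RR < 10, moderate 10 ≤ RR < 100, high 100 ≤ RR < 1000,
extremely high RR ≥ 1000.

The **overwintering-type test** fits a linear mixed model (statsmodels
MixedLM, REML): wlogRR ~ overwintering type + pesticide + ETDD +
pesticide:overwintering type + ETDD:pesticide, random intercept for
site×year. The three-way interaction is excluded (rank deficient in
designs of this shape). Each term is tested by a Wald chi-square on its
coefficient block using the fitted covariance — i.e. block tests on the
treatment-coded full model. ETDD is standardised internally for
optimiser stability (the chi-square is invariant to this). Empty or
collinear interaction columns are dropped (reported); a singular fit
falls back to OLS fixed effects with `converged=False` rather than
failing silently. Null-calibration simulations (no overwintering
effect, ~240 site-year groups) put the test's size near the nominal 5%.

High-resistance geography: quantile regression (statsmodels QuantReg)
of log₁₀ RR on 5-year LTDD at τ = 0.85 — the top-15% resistance level —
with the slope's two-sided t-test. The fitted quantile line is
projected onto the LTDD grid; cells below the host cutoff are zeroed
and excluded. Publication bias is screened by a funnel table of logRR
against field bioassay sample size with Kendall's rank correlation
(all-tied inputs are flagged rather than tested).

## Synthetic data: what it emulates, and what it does not

All inputs are generated with known ground truth:

- **Chamber regimes**: ~180-day (November–April) piecewise-linear
  decline/hold/rise profiles stepped every 10 days, spanning a cold
  gradient (site minima +12 °C down to −11 °C) so LTDD varies far more
  than 5-fold across the default 10 sites.
- **Survival experiment**: destructive sampling every 10 days, 11
  points, 55 larvae + 65 pupae per point per regime (220 observations),
  survivors Binomial(n, a·exp(b·LTDD)) with default truth a = 0.9,
  b = −0.005 °C⁻¹·day⁻¹ — magnitudes chosen to mimic a strongly
  chill-limited pest (survival ~0.9 at zero cold load, falling to <1%
  near LTDD ≈ 900), not claimed to be any fitted field values. A
  noiseless switch reproduces the curve exactly for oracle tests.
- **Field experiment**: 12 sites × 4 monthly samples × (3 stages on
  caged plants + 2 stages in buried jars) × 2 cages of 30, binomial
  around the same law with noisier site climates.
- **Climate grid**: T(cell, day) = equator temperature − 0.6·|lat| +
  static per-cell offset (sd 2 °C, emulating continentality/elevation —
  without it, entire latitude rows change class simultaneously and the
  marginal belt degenerates) + seasonal cosine (amplitude growing with
  |lat|, phase flipped across the equator) + linear warming trend
  (default 0.03 °C/yr) + daily noise (sd 1.5 °C). Host presence is a
  smooth low-frequency random field in [0, 1].
- **Resistance records**: ln RR = μ + overwintering effect + pesticide
  effect + ETDD slope + site×year random intercept + residual. Default
  overwintering effects put permanent sites 158-fold above transient
  and 5-fold above marginal on the ratio scale. LC50s, bioassay sizes
  and 95% CIs are constructed so the SE→V chain returns each record's
  generating measurement variance exactly; a configurable fraction of
  CIs is deleted to exercise imputation. Optional knobs add a direct
  LTDD trend and LTDD-proportional residual scale (heteroscedasticity)
  for quantile-recovery experiments.

What passing tests do **not** show about real data: the generators have
no spatial autocorrelation beyond the smooth fields, no snow/rainfall
or microhabitat buffering, no dispersal or biotic interactions, no
reporting bias, and the survival law is exactly exponential — so
recovery results certify the estimation machinery, not the biology.
Note also that in the default synthetic world ETDD is collinear with
overwintering type (warm sites have long growing seasons), exactly as
in real geography; recovery experiments that target the injected
overwintering fold therefore switch the confounding effects off.

## Problem sizes and reproducibility

Simulation experiments run at these scales (the package's own choices,
balancing Monte-Carlo error against cost): LTDD oracle, 1000 random
series; parameter recovery and model selection, 100 replicates of the
220-observation chamber design; mixed-model calibration, 200 null and
100 power replicates of a 720-record / ~240-group design (many small
groups preserve the asymptotic regime of the study-scale data at a
fraction of its cost); fold-change recovery, 6 replicates × 400
records; quantile recovery, 8 replicates × 400 records. Every stream
derives from one integer seed via `SeedSequence` spawning, so
replicates are independent and all results reproduce exactly.

## Known limitations

- Daily mean air temperature only: no sub-daily extremes, soil or
  canopy microclimate, or acute cold-tolerance limits.
- Raw-proportion least squares (by convention) rather than binomial
  likelihood; the robust covariance mitigates, but a GLM would weight
  observations more efficiently.
- The Wald term tests are treatment-coded block tests; with severely
  unbalanced real designs a marginality-respecting (Type II)
  construction or likelihood-ratio tests may be preferable.
- Areas use spherical cos-latitude weighting; no equal-area projection.
- The host mask is consumed as-is; the species-distribution model that
  produces it is out of scope.
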