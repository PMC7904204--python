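# Methods

This note documents the statistical machinery in `healthineq`, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not establish about real survey data.

## Anthropometric classification

Z-scores use the LMS method: for a measurement `x` and reference parameters
`(L, M, S)` (Box-Cox power, median, coefficient of variation) tabulated by
sex × age-in-months × indicator,

    z = ((x/M)^L − 1) / (L·S)   if L ≠ 0
    z = ln(x/M) / S             if L = 0.

The implementation is continuous in `L` at zero (verified to 1e−5 at
`L = 1e−8`) and strictly increasing in `x`. Classification applies the
conventional school-age cut-offs with deliberately asymmetric boundaries:
thinness requires BMI-for-age `z < −2` (strict), stunting height-for-age
`z ≤ −2` (inclusive), so a z-score of exactly −2 is stunted but not thin.
Co-existence is the conjunction.

Choices where the convention is not fixed:

- **Age mapping.** When only age in years is available, it is converted to
  completed months as `floor(age_years · 365.25 / 30.4375)`.
- **Interpolation.** Reference lookups between tabulated ages interpolate
  `L`, `M`, `S` linearly in age; queries outside the tabulated range raise
  an error naming the bounds rather than extrapolating.
- **Implausible values.** |z| > 5 is flagged (`implausible_z`) but kept by
  default; `classify_table(..., drop_implausible=True)` instead sets the
  flags missing. No restricted tail adjustment for extreme values is
  applied.
- **Missing data.** Missing z-scores propagate to missing outcome flags
  (nullable integers), and every downstream denominator counts only
  non-missing records (complete-case analysis per outcome).

The packaged reference table (`make_lms_fixture`) is synthetic: values are
in the physiological ballpark for adolescents and include `L = 0` rows to
exercise the logarithmic branch, but it is not a published growth standard.
Real analyses should supply their own reference CSV
(`sex, age_months, indicator, L, M, S`).

## Fractional ranks and the concentration index

Ranking uses the continuous wealth score, never the quintile recode.
Individual `i`'s fractional rank is the cumulative normalized weight of all
strictly poorer individuals plus half its own weight; tied scores share the
midpoint rank of the tied group's pooled weight span (the health-economics
convention — tie handling materially changes the index when the wealth
measure is coarse, which is why the generator can inject ties on demand).
With equal weights and distinct scores this is `(i − 0.5)/n`.

The index is `C = 2·cov_w(y, R)/μ` with the *population* weighted
covariance (divide by total weight, not total − 1). The population form is
not a stylistic choice: it is what makes the decomposition's adding-up
identity exact rather than approximate. Degenerate inputs raise typed
errors: `μ = 0` (index undefined), constant ranks (all scores tied),
non-positive weights.

Sign language: the package reports the neutral orientation "concentrated
among the poor / rich" alongside the signed index, since the pro-poor /
pro-rich labels are used inconsistently across the literature.

The concentration curve is emitted as explicit coordinates (cumulative
population share, cumulative outcome share), prepended with (0, 0); the
identity `C = 1 − 2·area` holds up to the `O(1/n)` discretization of the
trapezoid area, which the tests bound by `2/n`.

## Regression models

Association tables use maximum-likelihood logistic regression
(statsmodels GLM-Binomial; frequency weights when sampling weights are
supplied), reported as odds ratios with 95% Wald intervals
`exp(β ± 1.96·SE)`. All covariates enter one model simultaneously. Perfect
and quasi-separation (an empty cell in a dummy's 2×2 with the outcome) are
detected up front and reported as an error naming the column, since the ML
estimate diverges there.

The decomposition is fed by a weighted OLS linear probability model (LPM).
Predictions may leave [0, 1] — expected for an LPM and harmless here: what
the decomposition needs is the exact weighted orthogonality of residuals to
the design (checked to 1e−10), which only least squares provides. A
logistic alternative (`engine="logit_ape"`, average partial effects on the
probability scale) is available; its residual then additionally absorbs the
linearization error, and results carry the engine tag.

## Wagstaff decomposition

From `y = α + Σ β_k x_k + ε`:

    C = Σ_k η_k C_k + GC_ε/μ,    η_k = β_k x̄_k / μ,

with `C_k` the concentration index of dummy `x_k` over the same ranks and
`GC_ε = 2·cov_w(ε, R)`. Implementation notes:

- The residual is computed both as `actual − calculated` and directly as
  `GC_ε/μ`; the two agree to 1e−10 on every dataset (they are algebraically
  equal under OLS), and the test suite asserts this on random data.
- Percentage contributions are relative to the **calculated** (explained)
  CI, not the actual CI — the only convention under which per-factor group
  totals sum to 100.
- Empty categories (all-zero dummies) would make the design singular; they
  are excluded from the fit and emitted with a zero contribution and an
  undefined (NaN) `C_k`.
- Reference-category rows are emitted blank in the formatted table, for
  fidelity with the conventional table layout; formatted values round half
  away from zero (3 decimals for elasticities/indices/contributions, 1 for
  percentages).
- Contributions are invariant to the order in which factors are listed.

Analytic anchors used in tests: under equal weights and a uniform rank, a
top-quintile dummy has `C_k = 2(∫_{0.8}^{1} r dr − 0.2·0.5)/0.2 = 0.8`, a
bottom-quintile dummy −0.8, and a top-half indicator outcome has `C = 0.5`.

## Synthetic populations

`generate_population` emulates the structure of a two-state adolescent
survey with restricted microdata:

- **Scale and split.** Default 20,594 records with a boys' share of
  5,969/20,594, the scale of the emulated survey; all tests run at
  configurable `n`.
- **Wealth.** Continuous standard-normal score (so ranks are almost surely
  unique); `tie_fraction` duplicates scores to exercise tie handling;
  quintiles cut from the weighted fractional rank, hence balanced to ±1
  record under equal weights.
- **Covariates.** Eight categorical factors (age group, education, working
  status, media exposure, caste, religion, residence, state) drawn from
  softmax links `P(cat j | r) ∝ exp(a_j + b_j(r − 0.5))` on the wealth rank
  `r`. Baseline logits reproduce the emulated survey's descriptive
  marginals per sex; slopes encode plausible wealth dependence (education
  and media exposure rise with wealth; working status and rural residence
  fall). No generative model for these links is published anywhere — the
  logistic form is this package's choice.
- **Latent z-scores.** `z* = g·(r − 0.5) + Σ effects(x) + noise`, with
  `g = gradient_strength` defaulting to 0.65 SD per unit rank — chosen to
  match the emulated survey's poorest-to-richest gap in mean BMI-for-age
  z-scores (≈ 0.6 SD). Covariate latent effects default to modest shifts
  (±0.1 SD, `latent_effects`); the BMI and height noise terms share a
  common component (`latent_correlation = 0.55`) so thinness and stunting
  co-occur more often than independence would imply. Setting
  `gradient_strength = 0` removes the *direct* wealth effect; removing all
  socioeconomic dependence additionally requires empty `latent_effects`
  and zero covariate rank slopes (the no-gradient test constructs exactly
  that configuration and observes |C| ≤ 0.02).
- **Calibration.** The latent scores are shifted per sex so the achieved
  prevalence equals the target at the classification cut-off (a weighted
  quantile match, deterministic given the seed). Default targets: thinness
  25.8% (boys) / 13.1% (girls), stunting 25.6% / 39.3%. Co-existence is not
  targeted; it emerges from the joint latent model (≈ 13% / 10% at the
  defaults).
- **Weights.** Equal by default; `weight_scheme="variable"` draws
  lognormal(σ = 0.5) weights normalized to mean 1, since whether the
  emulated survey's estimates were weighted is not documented — both paths
  are supported everywhere.
- **Outcome flags** are classified from the generated z-scores with the
  same cut-offs as real data, so flag/z-score consistency is guaranteed by
  construction and asserted in tests.

`generate_lpm_population` is the second generator: covariates are simple
functions of the wealth rank (deterministic rank-window indicators or
Bernoulli-logistic draws) and the outcome is Bernoulli with mean
`α + Σ β_k x_k` clipped to [0, 1] (clip rate reported; > 10% warns;
an infeasible baseline errors). Because the conditional mean is exactly
linear, the decomposition's ground-truth contributions `η_k C_k` are
computable from the generator's own coefficients (`lpm_ground_truth`), and
parameter-recovery tests check the pipeline reproduces a dominant factor's
percentage contribution within ±5 points at n = 50,000.

### What the synthetic data does not emulate

Multi-stage cluster sampling and design effects, household structure,
item non-response patterns, measurement error in height/weight, asset-based
wealth-index construction (the generator starts from a score), and
age-varying reference parameters within the latent model. Passing tests
therefore demonstrate the correctness of the estimators and the exactness
of the decomposition algebra on data with a known generative process — not
that any particular field survey satisfies these assumptions.

## Problem sizes and numerics

The test suite and the acceptance script run analytic-limit checks at
n = 20,000, parameter recovery at n = 50,000, identity checks on
50–100 random datasets of n = 1,000, and oracle-equivalence comparisons on
hundreds of random samples — sizes at which Monte-Carlo error is comfortably
inside the asserted tolerances (±0.02 for analytic limits, ±5 points for
recovered percentage contributions, 1e−10/1e−12 for algebraic identities).
Sorting is stable (mergesort) so tie groups are deterministic; all
randomness flows through `numpy.random.default_rng` seeded from the config
or the acceptance script's `--seed`.

## Known limitations

- No standard errors or dominance tests for the concentration index, and no
  Erreygers/Wagstaff normalizations of the index for bounded outcomes; the
  generalized index appears only inside the decomposition residual.
- No survey-design-corrected (clustered) standard errors in the regression
  models.
- The LPM decomposition attributes inequality linearly; strongly nonlinear
  covariate effects will load onto the residual (or, under `logit_ape`,
  onto the approximation error).
- The quintile recode in the report tables is descriptive; the index always
  ranks on the continuous score.
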