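# Methods

This note documents the models implemented in `grbtrends`, the defaults of
the synthetic-data generator, the numerical choices behind the fits, and
what the test suite does and does not establish.

## Composite GRB score

Each of three ordinal survey items is mapped linearly onto 0–100
(`scale_min` → 0, `scale_max` → 100) and the respondent's score is the
arithmetic mean of the available items. Higher scores mean more egalitarian
beliefs. A respondent needs at least two of three non-missing items by
default (configurable; the all-items-required variant is `min_items=3`).
Reliability is Cronbach's α on listwise-complete rows,
α = k/(k−1)·(1 − Σ var(itemᵢ)/var(Σ items)), with sample variances. The
subpopulation split used by the fertility models assigns "low" to scores at
or below the split value (ties deliberately go to the less egalitarian
group) and defaults to the realized median of the analysis sample.

## Hierarchical trend model

**Model.** Respondent GRB scores y are Gaussian around a cell mean indexed
by country c (in cultural zone z), calendar year t, and age-sex group a:

    E[y] = β₀ + f_z(t) + g_c(t) + u_c + δ_a + v_{c,a}

* f_z: smooth zone trend — cubic B-splines (default 8 basis functions over
  1995–2022) with a second-order difference penalty on the wiggly part;
  each zone's constant and linear components are unpenalized fixed effects.
* g_c: smooth country deviation — same construction with 6 basis functions,
  where the wiggly parts of all countries share **one common smoothing
  parameter**, and the country-level linear and constant (random-intercept
  u_c) deviations carry separate ridge penalties. In the infinite-penalty
  limit every country collapses onto its zone trend; in the zero-penalty
  limit the fit reproduces unpenalized least squares (both are tested).
* δ_a: six age-sex fixed effects under an exact sum-to-zero constraint
  (orthonormal contrast parametrization), with penalized country-specific
  deviations v_{c,a} (random slopes).

Countries enter only if they have at least two survey waves spanning at
least a quarter of the observation period (configurable); others are dropped
with a logged warning.

**Estimation.** Every penalized block is eigen-reparametrized to an identity
penalty, so the model is one penalized weighted least-squares problem with
five smoothing parameters λ. Respondent data are collapsed to cell
sufficient statistics (mean, count, within-cell sum of squares), which keeps
the Gaussian likelihood, the residual variance estimate, and the REML
criterion exact while making each fit take a fraction of a second. λ are
selected by restricted marginal likelihood:

    −2·l_R(λ) = (N − M_f)·log(P/(N − M_f)) + log|XᵀWX + S(λ)| − log|S(λ)|₊

with P the penalized residual sum of squares, M_f the number of unpenalized
coefficients, and |·|₊ the product of positive eigenvalues. Optimization is
a coarse per-parameter grid on the log scale followed by Nelder-Mead
refinement.

**Uncertainty.** Draws come from the multivariate normal approximation of
the coefficient posterior, β | y, λ ~ N(β̂, σ̂²(XᵀWX+S)⁻¹). Conditioning on
the REML-selected λ alone understates uncertainty exactly where information
borrowing does the work (years without surveys), so by default the draws
also integrate over λ: log-smoothing parameters are sampled from a normal
approximation around the REML optimum (finite-difference Hessian;
flat directions are bounded), and the coefficient posterior is re-solved
per λ sample. In simulation this moves pooled 90%-interval coverage of
latent country-year means from ≈83% to ≈92%. Remaining approximations:
the λ posterior is treated as Gaussian, and the Gaussian likelihood ignores
the discreteness of the composite score.

## Poststratification

National means are population-weighted averages of the six age-sex cell
means; higher-level aggregates (zone, HDI class, global) weight national
means by adult (18+) population shares, computed **independently for every
posterior draw** so that uncertainty propagates through all aggregation
levels. Countries absent from the model are excluded rather than imputed,
and the represented adult population is reported alongside each series.
Equal-tailed 90% intervals use the 5th/95th percentiles with numpy's default
linear interpolation between order statistics, so results are
bit-reproducible. The "average country" series weights countries equally;
the "average citizen" series weights them by population.

## Compositional analyses

* **Counterfactual:** the global series is recomputed per draw with national
  shares frozen at the first year. "National composition" means country
  shares only; within-country age-sex weighting follows the observed year
  (the contrast of interest is between countries, not within them; the
  within-country variant would additionally freeze age-sex shares and is a
  one-line change to the weight construction). The headline statistic is the
  posterior median of 100·[(cf_end − obs_start)/(obs_end − obs_start) − 1],
  computed per draw **before** summarizing; it is flagged unstable when the
  observed change is near zero.
* **Size–GRB correlation:** Spearman rank correlation (average ranks for
  ties) between national adult population and national mean GRB, computed
  per draw with the same draw index across countries to preserve
  cross-country posterior correlation.
* **Growth regression:** log P_end = log P_start + α + β·GRB_true, where the
  trend model's posterior mean and SD of first-year national GRB enter as a
  noisy measurement: GRB_obs ~ N(GRB_true, se²), GRB_true ~ N(μ_g, τ²).
  Weakly informative zero-centered normal priors with scales set from the
  data's response range; inverse-gamma(2, ·) priors on variances. All full
  conditionals are conjugate, so the model is sampled by Gibbs (3,000
  iterations, 1,000 burn-in by default). Countries with se = 0 have their
  true score fixed, in which case the posterior slope matches weighted
  least squares (tested). exp(α + β·g) is reported as the predicted
  population growth factor.

## Hybrid within-between mixed model

Outcome: reported number of children of women aged 40–49 from each country's
most recent survey no older than 2010, treated as continuous. GRB and
religiosity (mean of four 0–100-rescaled items) are standardized to mean
0/SD 1 on the respondent level; every predictor is split into a
between-country component (country mean) and a within-country component
(deviation from it); age is pooled. Model 1: GRB only; Model 2 adds age,
education, income, town size (reference categories: primary or less, low
income, <5,000 inhabitants); Model 3 adds religiosity. Country random
intercepts and random within-GRB slopes; REML estimation via statsmodels'
MixedLM; p-values from a normal approximation on t-ratios; conditional R²
by the variance-partition (Nakagawa) formulation
(var_fixed + var_random)/(var_fixed + var_random + σ²). Boundary estimates
of the random-slope variance are reported as such, not treated as failures.

## Hierarchical ASFR model

The fertility schedule is f(a) = c·exp(−((a−μ)/s(a))²), s(a) = s₁ below the
peak and s₂ at or above it: c is the peak height (births per woman-year), μ
the age of peak fertility, s₁/s₂ the steepness before/after. A woman's
reported children at age a are Poisson with mean equal to the cumulative
schedule Σ f(x) over integer ages from the support minimum (15 by default —
children reported at 18 reflect earlier births) up to a. Two curves per
country (low/high GRB subpopulation by the realized sample median of the
women entering the model) give eight parameters per country, each drawn from
a global normal population distribution on (log c, μ, log s₁, log s₂) —
logs for positivity. Weakly informative priors: hyper-means
N(log 0.15, 1²), N(28, 5²), N(log 5, 1²), N(log 8, 1²); hierarchical
variances inverse-gamma(2, b) with prior-mean spreads of 0.2 on the log
scales and 2 years on μ.

**Sampling.** An adaptive Metropolis-within-Gibbs scheme: random-walk
updates of each country-group quadruple using an adaptively estimated full
proposal covariance (the four parameters trade off along strong likelihood
ridges), joint translation ("interweaving") moves that shift a hyper-mean
together with all its country parameters (breaking the hierarchy-block
coupling), and conjugate updates of the hyper-means and variances. The
likelihood uses per-(country, group, age) sufficient statistics, so cost is
independent of sample size. Defaults: 4 chains × (1,000 warmup + 1,000
kept). Diagnostics report rank-normalized R-hat and bulk ESS for all
hyper-means and for the derived average-country metrics; the convergence
gate applies to the derived metrics (TFR and age at cumulative fertility
0.5), because the raw curve parameters can show inflated R-hat along
likelihood ridges even when every reported functional is well mixed. With
`strict=True` a gate failure raises.

**Derived metrics,** per draw: TFR = cumulative fertility at the support
maximum (area under the schedule); age at which cumulative fertility reaches
0.5 children per woman, linearly interpolated between integer ages and
undefined (excluded, with a count) when the schedule never reaches 0.5; the
"average country" evaluates the curve at the hyper-means (geometric means
for the log-scale parameters); and the per-draw fraction of countries in
which the low-GRB group has higher TFR, and reaches 0.5 at a younger age.

## Synthetic-data generator

The generator is the package's test bed; it emulates the structure the
models assume, with one master seed and deterministic per-stage child seeds.

* **Trends:** 20 countries in four cultural zones with logistic zone trends
  (e.g. a high-base strongly-rising zone and a low-base declining zone,
  spanning roughly 36–74 points over 1995–2022), country intercept
  deviations (SD 4), and smooth low-order polynomial deviations (amplitude
  2.5) — smooth, monotone-ish national trajectories that remain parametric
  for recovery tests.
* **Age-sex structure:** six groups ({18–34, 35–59, 60+} × {female, male});
  offsets make women and younger adults more egalitarian (range ±~5 points,
  sum-to-zero), with country-level noise (SD 1.5). Group membership is
  derived from generated integer ages, so poststratification cells are
  consistent with the microdata.
* **Measurement:** person-level latent noise SD 20 and per-item noise SD 25
  on the 0–100 scale, discretized onto 2-, 3-, and 4-level ordinal items at
  evenly spaced thresholds (the items' original response formats are not
  publicly fixed; the mix exercises the rescaling code). These values yield
  a composite reliability of α ≈ 0.6, typical of short attitude scales.
  Because discretization is nonlinear, the generator stores the exact
  expected observed composite per cell (a closed-form normal-CDF sum);
  that expectation — not the latent mean — is the estimand of the trend
  model and the truth used in coverage tests.
* **Survey design:** 2–5 waves per country, first wave early (1995–2003)
  and last wave late (2013–2022) with uniformly drawn middle waves, giving
  heterogeneous gaps while guaranteeing that every country satisfies both
  the trend model's span rule and the fertility models' recency rule; 500
  respondents per wave, allocated to age-sex cells by the population shares
  of the survey year.
* **Population:** initial adult populations log-normal (median ≈ 8M); the
  27-year log growth is 0.90 − 0.010·GRB₁₉₉₅ plus country noise (SD 0.08),
  interpolated log-linearly; within-country age-sex shares are Dirichlet
  around a realistic adult structure and constant over time. Setting the
  slope and noise to zero makes the compositional null case exactly
  reachable (counterfactual ≡ observed).
* **Fertility:** children ~ Poisson(cumulative ASFR at the woman's age),
  with the high-GRB curve at (c=0.15, μ=29, s₁=5, s₂=9) — TFR ≈ 1.9 — and
  the low-GRB curve solved deterministically so the configured contrasts
  hold exactly (defaults: +0.17 children and 0.5-children age 1.52 years
  younger). A separate Gaussian hybrid-model generator (within −0.102,
  between −0.622, variance components 0.574/0.050/1.205) drives the
  mixed-model recovery tests.

**What the generator does not emulate:** questionnaire wording and real
country rosters; survey non-response and design weights beyond age-sex
composition; migration and mortality; social-desirability drift; item
missingness patterns. Passing tests therefore show that the estimators
recover the structure they assume at realistic sparsity and noise — not that
the assumptions hold in any particular real survey program.

## Problem sizes used in the checks

The acceptance-style tests run the trend-coverage study on 200 datasets at
the default scenario with 400 posterior draws each; mixed-model recovery on
100 replicates of 100 countries × 150 women; ASFR recovery on one
single-country fit at 5,000 women per subgroup plus 50 scaled-down
hierarchical replicates (6 countries × 150 women per group, 2 chains ×
800 iterations); and null-calibration studies of 25–50 replicates per
stage. These sizes keep the whole suite within minutes on one CPU while
leaving the Monte-Carlo error of each coverage estimate at a few percent.

## Known limitations

* The trend model's posterior is a Gaussian approximation; smoothing
  parameters are integrated over a normal approximation rather than sampled
  exactly, and non-Gaussian likelihoods are out of scope.
* The composite score is treated as continuous despite coarse items; the
  expected-composite estimand absorbs this for the generator, but on real
  data floor/ceiling compression near the scale ends is not modeled.
* Children-ever-born by age is a period proxy for fertility; no tempo
  adjustment or mortality correction of reported children is applied.
* The hybrid model fits counts with a Gaussian likelihood (by design, for
  comparability of coefficients); the Poisson treatment lives in the ASFR
  model.
* The measurement-error growth regression conditions on the trend model's
  posterior summaries (mean, SD) per country rather than its full joint
  posterior.
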