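# grbtrends

Tools for studying how population-level **gender-role beliefs (GRB)** — public
support for women's equal participation in work, education, and politics —
change over time, and how demographic processes (differential population
growth and differential fertility) constrain that change.

Cross-national value surveys are sparse: most countries contribute only a
handful of survey waves over three decades, with heterogeneous spacing and
imperfect age-sex representativeness. `grbtrends` addresses this with a
pipeline of five connected analyses, exercised end to end on synthetic survey
microdata with known ground truth:

1. **Composite scoring** (`grbtrends.measure`): three ordinal items are each
   linearly rescaled to 0–100 and averaged into a respondent's GRB score
   (higher = more egalitarian), with Cronbach's α for reliability and the
   median split used by the fertility models.
2. **Hierarchical smooth trends** (`grbtrends.trends`): one penalized
   Gaussian regression estimates a smooth time effect f_z(t) per cultural
   zone and a country deviation g_c(t) shrunk toward its zone (cubic
   B-splines, second-order difference penalties, one common wiggliness
   penalty for all countries), plus six age-sex effects with country-level
   deviations. Smoothing/variance parameters are selected by REML;
   uncertainty is propagated by sampling coefficient vectors from the
   Gaussian posterior approximation, including normal-approximation
   uncertainty in the log smoothing parameters.
3. **Poststratification** (`grbtrends.poststrat`): model-predicted cell means
   are reweighted by external adult population counts — age-sex shares within
   countries, national population shares across countries — per posterior
   draw, yielding national, zone, HDI-class, and global trajectories
   (multilevel regression and poststratification).
4. **Composition analyses** (`grbtrends.composition`): a counterfactual
   global series with national composition frozen at the first year; the
   relative trend excess 100·[(Δcf/Δobs) − 1] computed per draw; per-draw
   Spearman correlations between national population size and GRB; and a
   Bayesian measurement-error regression of 27-year log population growth on
   first-year national GRB (Gibbs sampler, conjugate throughout).
5. **Differential fertility** (`grbtrends.lmm`, `grbtrends.asfr`): a hybrid
   within-between mixed model for completed fertility of women 40–49
   (country random intercepts and GRB slopes), and a hierarchical Bayesian
   age-specific fertility rate model where a woman's reported children are
   Poisson with mean equal to her cumulative ASFR,
   f(a) = c·exp(−((a−μ)/s(a))²) with s(a)=s₁ before and s₂ after the peak,
   fit separately for the below-median ("low") and above-median ("high") GRB
   subpopulations of every country with shrinkage toward global means.

The synthetic-data generator (`grbtrends.synthetic`) is first-class, tested
code: it produces survey microdata and population tables with the exact
structure these models assume, and records every latent quantity for recovery
testing.

## Worked example

Run every stage end to end on a synthetic study (20 countries in 4 cultural
zones, 2–5 survey waves each, 500 respondents per wave, 1995–2022):

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

This prints, among other quantities (about a minute on one CPU):

```
"global_grb_start":              47.77   # population-weighted global GRB, 1995
"global_grb_end":                55.65   # same, 2022
"counterfactual_global_grb_end": 56.32   # 2022 global GRB under 1995 national shares
"relative_trend_excess_pct":      8.6    # counterfactual trend exceeds observed by ~9%
"growth_slope_per_grb_point":   -0.0088  # log adult-population growth per GRB point
"tfr_diff_low_minus_high":        0.097  # extra children for the low-GRB subpopulation
"age_at_half_diff_years":         2.08   # years earlier the low-GRB group reaches 0.5 children
"pct_countries_low_earlier":     91.5    # share of countries with that timing pattern
```

Reading the output: the gap between the observed and counterfactual 2022
global means isolates how much faster global egalitarianism would have grown
had national population shares stayed at their 1995 values — here the
counterfactual increase is about 9% larger, because the generator makes
low-GRB countries grow faster (slope −0.01 per GRB point on 27-year log
growth, recovered as −0.0088). The fertility contrasts recover the
generator's configuration (low-GRB women have more children and have them
earlier) from 2,850 women across 20 countries.

The same pipeline is available as a CLI with per-stage subcommands
(`grbtrends run --out run --seed 1 --draws 2000`, or `simulate | score |
trends | poststrat | composition | lmm | asfr | report` individually); each
stage communicates through schema-validated CSV files, and `report` writes a
one-page summary of all headline quantities.

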