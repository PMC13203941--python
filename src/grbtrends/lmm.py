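"""Hybrid (within-between) linear mixed models for completed fertility.

The outcome is a woman's reported number of children at age 40-49, treated
as continuous.  Each predictor is split into a between-country component
(the country mean) and a within-country component (the individual deviation
from it), so that the model estimates both how fertility varies with a
country's average GRB and how it varies with a woman's own GRB relative to
her compatriots.  Country random intercepts and random within-GRB slopes
absorb unobserved between-country variation.

Model 1 uses GRB only; Model 2 adds age (pooled), education, income and town
size; Model 3 adds religiosity.  GRB and religiosity are standardized to
mean 0 / SD 1 on the respondent level before centering.  Estimation is by
REML via statsmodels' MixedLM; p-values use a normal approximation on the
t-ratios; the conditional R-squared follows the variance-partition
(Nakagawa) formulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .measure import rescale_item

logger = logging.getLogger(__name__)

EDUCATION_LEVELS = ("primary", "lower_secondary", "upper_secondary", "tertiary")
INCOME_LEVELS = ("low", "medium", "high")
TOWN_LEVELS = ("lt5k", "5k-20k", "20k-100k", "100k-500k", "gt500k")

RELIGIOSITY_SCALES = ((1, 4), (1, 5), (1, 7), (1, 10))


def religiosity_index(
    items: pd.DataFrame, scales=RELIGIOSITY_SCALES, require_complete: bool = True
) -> np.ndarray:
    """Mean of four religiosity items after rescaling each to 0-100."""
    cols = [c for c in items.columns if c.startswith("rel")]
    if len(cols) != 4:
        raise ValueError("expected four religiosity item columns rel1..rel4")
    rescaled = np.column_stack(
        [
            rescale_item(items[c].to_numpy(dtype=float), lo, hi)
            for c, (lo, hi) in zip(sorted(cols), scales)
        ]
    )
    if require_complete:
        out = rescaled.mean(axis=1)
        out[np.isnan(rescaled).any(axis=1)] = np.nan
        return out
    return np.nanmean(rescaled, axis=1)


def within_between_split(x: pd.Series, groups: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Decompose x into country means (between) and deviations (within).

    within + between reconstructs x exactly.
    """
    between = x.groupby(groups).transform("mean")
    within = x - between
    return within, between


def build_lmm_sample(
    survey: pd.DataFrame,
    age_range: tuple[int, int] = (40, 49),
    recency_cutoff: int = 2010,
    min_country_n: int = 10,
) -> pd.DataFrame:
    """Women aged 40-49 from each country's most recent qualifying survey.

    Surveys older than the recency cutoff are discarded; a country whose
    latest survey predates the cutoff is dropped entirely.  Countries with
    very few eligible women are retained (hierarchical shrinkage handles
    them) but logged.
    """
    lo, hi = age_range
    out = []
    for country, sub in survey.groupby("country", sort=True):
        latest = int(sub["year"].max())
        if latest < recency_cutoff:
            logger.warning("dropping %s: latest survey %d predates %d",
                           country, latest, recency_cutoff)
            continue
        rows = sub[(sub["year"] == latest)
                   & (sub["sex"] == "female")
                   & (sub["age"] >= lo) & (sub["age"] <= hi)]
        if 0 < len(rows) < min_country_n:
            logger.warning("country %s has only %d eligible women", country, len(rows))
        if len(rows):
            out.append(rows)
    if not out:
        return survey.iloc[0:0].copy()
    return pd.concat(out, ignore_index=True)


@dataclass
class HybridLMMResult:
    model: int
    table: pd.DataFrame  # term, level, estimate, se, p
    country_intercept_sd: float
    country_slope_sd: float
    residual_sd: float
    n_obs: int
    n_countries: int
    conditional_r2: float
    loglik: float
    converged: bool

    def coef(self, term: str, level: str) -> float:
        row = self.table[(self.table["term"] == term) & (self.table["level"] == level)]
        return float(row["estimate"].iloc[0])

    def se(self, term: str, level: str) -> float:
        row = self.table[(self.table["term"] == term) & (self.table["level"] == level)]
        return float(row["se"].iloc[0])


def _zscore(x: pd.Series) -> pd.Series:
    return (x - x.mean()) / x.std(ddof=1)


def _dummy_block(values: pd.Series, levels) -> pd.DataFrame:
    """Indicator columns for all non-reference levels (first level = reference)."""
    out = {}
    for lev in levels[1:]:
        out[str(lev)] = (values == lev).astype(float)
    return pd.DataFrame(out, index=values.index)


def prepare_design(df: pd.DataFrame, model: int = 1) -> tuple[pd.DataFrame, list]:
    """Standardize, split predictors within/between, assemble the fixed part.

    Returns (frame with all model columns plus grb_within for the random
    slope, list of (column, term, level) fixed-effect descriptors).
    Listwise deletion of rows missing any model variable.
    """
    if model not in (1, 2, 3):
        raise ValueError("model must be 1, 2 or 3")
    need = ["country", "grb", "n_children"]
    if model >= 2:
        need += ["age", "education", "income", "town_size"]
    if model >= 3:
        need += ["religiosity"]
    work = df.dropna(subset=[c for c in need if c in df.columns]).copy()
    terms = []

    z = _zscore(work["grb"])
    w, b = within_between_split(z, work["country"])
    work["grb_within"], work["grb_between"] = w, b
    terms += [("grb_within", "GRB", "within"), ("grb_between", "GRB", "between")]

    if model >= 2:
        work["age_pooled"] = work["age"].astype(float)
        terms.append(("age_pooled", "Age", "pooled"))
        for var, levels, label in [
            ("education", EDUCATION_LEVELS, "Education"),
            ("income", INCOME_LEVELS, "Income"),
            ("town_size", TOWN_LEVELS, "Town size"),
        ]:
            dums = _dummy_block(work[var], levels)
            for col in dums.columns:
                wcol, bcol = within_between_split(dums[col], work["country"])
                work[f"{var}_{col}_w"] = wcol
                work[f"{var}_{col}_b"] = bcol
                terms.append((f"{var}_{col}_w", f"{label}: {col}", "within"))
                terms.append((f"{var}_{col}_b", f"{label}: {col}", "between"))
    if model >= 3:
        zr = _zscore(work["religiosity"])
        wr, br = within_between_split(zr, work["country"])
        work["relig_within"], work["relig_between"] = wr, br
        terms.append(("relig_within", "Religiosity", "within"))
        terms.append(("relig_between", "Religiosity", "between"))
    return work, terms


def fit_hybrid_lmm(
    df: pd.DataFrame, model: int = 1, reml: bool = True
) -> HybridLMMResult:
    """Fit the hybrid mixed model (country random intercept + GRB slope)."""
    import statsmodels.api as sm
    from scipy.stats import norm

    work, terms = prepare_design(df, model)
    cols = [c for c, _, _ in terms]
    exog = sm.add_constant(work[cols].to_numpy())
    endog = work["n_children"].to_numpy(dtype=float)
    groups = work["country"].to_numpy()
    exog_re = np.column_stack([np.ones(len(work)), work["grb_within"].to_numpy()])

    md = sm.MixedLM(endog, exog, groups=groups, exog_re=exog_re)
    import warnings

    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = md.fit(reml=reml, method="lbfgs", maxiter=200, disp=False)
        except Exception:
            res = md.fit(reml=reml, method="powell", maxiter=500, disp=False)
    converged = bool(res.converged)
    if not converged:
        logger.warning("mixed model %d did not fully converge", model)

    params = res.fe_params
    bse = res.bse_fe
    tvals = params / bse
    pvals = 2 * norm.sf(np.abs(tvals))
    rows = [{"term": "Intercept", "level": "", "estimate": params[0],
             "se": bse[0], "p": pvals[0]}]
    for j, (_, term, level) in enumerate(terms, start=1):
        rows.append({"term": term, "level": level, "estimate": params[j],
                     "se": bse[j], "p": pvals[j]})
    table = pd.DataFrame(rows)

    cov_re = np.asarray(res.cov_re)
    int_sd = float(np.sqrt(max(cov_re[0, 0], 0.0)))
    slope_sd = float(np.sqrt(max(cov_re[1, 1], 0.0)))
    resid_sd = float(np.sqrt(res.scale))

    # Nakagawa-style conditional R2: fixed + random variance over total
    var_f = float(np.var(exog @ params))
    var_r = float(np.mean(np.einsum("ij,jk,ik->i", exog_re, cov_re, exog_re)))
    r2c = (var_f + var_r) / (var_f + var_r + res.scale)

    return HybridLMMResult(
        model=model,
        table=table,
        country_intercept_sd=int_sd,
        country_slope_sd=slope_sd,
        residual_sd=resid_sd,
        n_obs=int(len(work)),
        n_countries=int(pd.Series(groups).nunique()),
        conditional_r2=float(r2c),
        loglik=float(res.llf),
        converged=converged,
    )
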