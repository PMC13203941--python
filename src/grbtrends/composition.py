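"""Compositional analyses: how differential population growth shapes the
global GRB trend.

Three pieces: (i) a counterfactual global series holding the national
composition of the world population fixed at its first-year shares, with the
relative trend excess computed per posterior draw; (ii) per-draw Spearman
rank correlations between national adult population size and national mean
GRB; (iii) a Bayesian measurement-error regression of 27-year log population
growth on first-year national GRB, where the predictor's posterior mean and
SD from the trend model enter as a noisy measurement of the true national
score.  The regression is sampled with a conjugate Gibbs sampler
(normal/inverse-gamma priors throughout).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .poststrat import CountryDraws


@dataclass
class CounterfactualResult:
    years: np.ndarray
    observed: np.ndarray  # (n_draws, n_years) global series
    counterfactual: np.ndarray  # same, with first-year national shares
    relative_excess: np.ndarray  # per-draw percent excess of cf over observed trend
    unstable: bool  # True when the observed change is too close to zero

    def summary(self) -> dict:
        q = lambda x, p: float(np.quantile(x, p))
        return {
            "observed_start": float(self.observed[:, 0].mean()),
            "observed_end": float(self.observed[:, -1].mean()),
            "counterfactual_end": float(self.counterfactual[:, -1].mean()),
            "relative_excess_median": float(np.median(self.relative_excess)),
            "relative_excess_lo90": q(self.relative_excess, 0.05),
            "relative_excess_hi90": q(self.relative_excess, 0.95),
        }


def relative_trend_excess(obs_start, obs_end, cf_end):
    """Percent by which the counterfactual trend exceeds the observed trend.

    100 * ((cf_end - obs_start) / (obs_end - obs_start) - 1); elementwise.
    """
    obs_start = np.asarray(obs_start, dtype=float)
    delta = np.asarray(obs_end, dtype=float) - obs_start
    return 100.0 * ((np.asarray(cf_end, dtype=float) - obs_start) / delta - 1.0)


def counterfactual_series(
    country_draws: CountryDraws, pop: pd.DataFrame, agesex=None
) -> CounterfactualResult:
    """Global series with national shares frozen at the first year.

    National composition is interpreted as country shares of the world adult
    population; within-country age-sex weighting follows the observed year
    (it is already folded into the national series).  Computed per draw; the
    headline excess statistic is the posterior median.
    """
    if agesex is None:
        agesex = sorted(pop["agesex"].unique())
    from .poststrat import build_weights

    countries, years = country_draws.countries, country_draws.years
    shares = build_weights(pop, countries, years, agesex, level="global")
    observed = np.einsum("dcy,cy->dy", country_draws.values, shares)
    frozen = np.repeat(shares[:, [0]], len(years), axis=1)
    counterfactual = np.einsum("dcy,cy->dy", country_draws.values, frozen)

    delta = observed[:, -1] - observed[:, 0]
    unstable = bool(np.median(np.abs(delta)) < 1e-6)
    with np.errstate(divide="ignore", invalid="ignore"):
        excess = relative_trend_excess(
            observed[:, 0], observed[:, -1], counterfactual[:, -1]
        )
    return CounterfactualResult(
        years=years,
        observed=observed,
        counterfactual=counterfactual,
        relative_excess=excess,
        unstable=unstable,
    )


def size_grb_correlation(
    country_draws: CountryDraws, pop: pd.DataFrame, year: int, agesex=None
) -> dict:
    """Per-draw Spearman correlation between adult population size and GRB.

    Ties get average ranks.  The same draw index is used across countries, so
    cross-country posterior correlation is preserved.
    """
    countries, years = country_draws.countries, country_draws.years
    if len(countries) < 5:
        raise ValueError("need at least 5 countries for a rank correlation")
    if agesex is None:
        agesex = sorted(pop["agesex"].unique())
    from .poststrat import _pop_cube

    cube = _pop_cube(pop, countries, years, agesex)
    yi = list(years).index(year)
    sizes = cube.sum(axis=2)[:, yi]
    size_ranks = rankdata(sizes)
    vals = country_draws.values[:, :, yi]  # (n_draws, n_countries)
    grb_ranks = rankdata(vals, axis=1)
    sr = size_ranks - size_ranks.mean()
    gr = grb_ranks - grb_ranks.mean(axis=1, keepdims=True)
    denom = np.sqrt((sr @ sr) * np.sum(gr * gr, axis=1))
    rho = (gr @ sr) / denom
    return {
        "year": year,
        "draws": rho,
        "mean": float(rho.mean()),
        "lo90": float(np.quantile(rho, 0.05)),
        "hi90": float(np.quantile(rho, 0.95)),
    }


# ---------------------------------------------------------------------------
# measurement-error growth regression
# ---------------------------------------------------------------------------


@dataclass
class GrowthRegressionResult:
    """Posterior draws for log-growth ~ alpha + beta * GRB_true."""

    alpha: np.ndarray
    beta: np.ndarray
    sigma: np.ndarray
    grb_sd: float  # SD of the observed national GRB (for per-SD slopes)

    @property
    def beta_per_sd(self) -> np.ndarray:
        return self.beta * self.grb_sd

    def summary(self) -> dict:
        def eti(x):
            return float(np.mean(x)), float(np.quantile(x, 0.05)), float(np.quantile(x, 0.95))

        bm, bl, bh = eti(self.beta)
        return {
            "beta_mean": bm,
            "beta_lo90": bl,
            "beta_hi90": bh,
            "beta_per_sd_mean": bm * self.grb_sd,
            "alpha_mean": float(self.alpha.mean()),
            "sigma_mean": float(self.sigma.mean()),
        }

    def predicted_growth_factor(self, grb_grid) -> pd.DataFrame:
        """Posterior mean and 90% interval of the 27-year population growth
        factor as a function of national GRB."""
        g = np.asarray(grb_grid, dtype=float)
        log_growth = self.alpha[:, None] + self.beta[:, None] * g[None, :]
        factor = np.exp(log_growth)
        return pd.DataFrame(
            {
                "grb": g,
                "mean": factor.mean(axis=0),
                "lo90": np.quantile(factor, 0.05, axis=0),
                "hi90": np.quantile(factor, 0.95, axis=0),
            }
        )


def growth_regression(
    grb_mean,
    grb_se,
    pop_start,
    pop_end,
    n_iter: int = 3000,
    n_burn: int = 1000,
    seed: int = 0,
) -> GrowthRegressionResult:
    """Gibbs sampler for the measurement-error growth regression.

    Outcome: d_i = log(pop_end_i) - log(pop_start_i); predictor: true national
    GRB, observed as grb_mean_i with known SD grb_se_i.  Model:

        d_i = alpha + beta * g_i + eps_i,  eps ~ N(0, sigma^2)
        grb_mean_i ~ N(g_i, grb_se_i^2),   g_i ~ N(mu_g, tau^2)

    Weakly informative zero-centered priors with scales set from the data's
    response range.  All conditionals are conjugate.  Countries with
    grb_se = 0 have their true score fixed at the observed value.
    """
    gm = np.asarray(grb_mean, dtype=float)
    se = np.asarray(grb_se, dtype=float)
    p0 = np.asarray(pop_start, dtype=float)
    p1 = np.asarray(pop_end, dtype=float)
    if np.any(p0 <= 0) or np.any(p1 <= 0):
        raise ValueError("populations must be positive")
    d = np.log(p1) - np.log(p0)
    n = len(d)

    sd_d = float(np.std(d)) or 1.0
    sd_g = float(np.std(gm)) or 1.0
    # prior scales from the response range
    s_alpha = 10.0 * sd_d + 10.0 * sd_d / sd_g * abs(gm.mean())
    s_beta = 10.0 * sd_d / sd_g
    a_sig, b_sig = 2.0, sd_d**2
    mu_g0, s_mu = gm.mean(), 10.0 * sd_g
    a_tau, b_tau = 2.0, sd_g**2

    rng = np.random.default_rng(seed)
    g = gm.copy()
    alpha, beta = d.mean(), 0.0
    sig2 = sd_d**2
    mu_g, tau2 = gm.mean(), sd_g**2
    fixed_g = se <= 0

    keep_a = np.empty(n_iter - n_burn)
    keep_b = np.empty(n_iter - n_burn)
    keep_s = np.empty(n_iter - n_burn)
    for it in range(n_iter):
        # (alpha, beta) | rest: bivariate normal
        Xg = np.column_stack([np.ones(n), g])
        prec = Xg.T @ Xg / sig2 + np.diag([1 / s_alpha**2, 1 / s_beta**2])
        cov = np.linalg.inv(prec)
        mean = cov @ (Xg.T @ d / sig2)
        ab = rng.multivariate_normal(mean, cov)
        alpha, beta = float(ab[0]), float(ab[1])
        # latent g_i
        pg = np.where(fixed_g, 0.0, 1 / np.maximum(se, 1e-12) ** 2) + beta**2 / sig2 + 1 / tau2
        mg = (
            np.where(fixed_g, 0.0, gm / np.maximum(se, 1e-12) ** 2)
            + beta * (d - alpha) / sig2
            + mu_g / tau2
        ) / pg
        g_new = mg + rng.standard_normal(n) / np.sqrt(pg)
        g = np.where(fixed_g, gm, g_new)
        # sigma^2
        resid = d - alpha - beta * g
        sig2 = (b_sig + 0.5 * resid @ resid) / rng.gamma(a_sig + 0.5 * n)
        # hyperparameters of the latent predictor
        pmu = n / tau2 + 1 / s_mu**2
        mu_g = rng.normal((g.sum() / tau2 + mu_g0 / s_mu**2) / pmu, np.sqrt(1 / pmu))
        tau2 = (b_tau + 0.5 * np.sum((g - mu_g) ** 2)) / rng.gamma(a_tau + 0.5 * n)
        if it >= n_burn:
            keep_a[it - n_burn] = alpha
            keep_b[it - n_burn] = beta
            keep_s[it - n_burn] = np.sqrt(sig2)

    return GrowthRegressionResult(
        alpha=keep_a, beta=keep_b, sigma=keep_s, grb_sd=sd_g
    )


def grb_mean_se_from_draws(country_draws: CountryDraws, year: int):
    """Per-country posterior mean and SD of national GRB in ``year``."""
    yi = list(country_draws.years).index(year)
    vals = country_draws.values[:, :, yi]
    return vals.mean(axis=0), vals.std(axis=0, ddof=1)
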