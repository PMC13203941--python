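"""Hierarchical Bayesian age-specific fertility rate (ASFR) model.

The fertility schedule of a subpopulation is described by a four-parameter
unimodal curve (Peristera-Kostaki form):

    f(a) = c * exp(-((a - mu) / s(a))^2),   s(a) = s1 if a < mu else s2

where ``c`` scales the height of the curve (births per woman-year), ``mu``
is the age of peak fertility, and ``s1``/``s2`` control steepness before and
after the peak.  A woman's reported number of children at age ``a`` is
modeled as Poisson with mean equal to her cumulative ASFR, i.e. the sum of
f over integer ages from the support minimum up to ``a``.

Two curves are fit per country — one for women at or below the global-median
gender-role-belief (GRB) score ("low", less egalitarian) and one above it
("high") — giving eight parameters per country.  All country-level
parameters are drawn hierarchically around global means, which shrinks
estimates for countries with small samples toward the cross-country average.
Positivity of c, s1, s2 is enforced by placing the hierarchy on their logs;
mu is modeled on the natural scale.

Posterior sampling uses an adaptive Metropolis-within-Gibbs scheme:
random-walk block updates of each country-by-group parameter quadruple on
the transformed scale, with conjugate normal / inverse-gamma updates for the
hierarchical means and variances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("low", "high")
PARAM_NAMES = ("c", "mu", "s1", "s2")

DEFAULT_SUPPORT = (15, 49)


@dataclass(frozen=True)
class ASFRParams:
    """Parameters of one fertility curve."""

    c: float
    mu: float
    s1: float
    s2: float

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError("c must be nonnegative")
        if self.s1 <= 0 or self.s2 <= 0:
            raise ValueError("s1 and s2 must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.c, self.mu, self.s1, self.s2])


def asfr_curve(age, p: ASFRParams):
    """Age-specific fertility rate (births per woman-year) at ``age``."""
    a = np.asarray(age, dtype=float)
    s = np.where(a < p.mu, p.s1, p.s2)
    out = p.c * np.exp(-(((a - p.mu) / s) ** 2))
    if np.isscalar(age):
        return float(out)
    return out


def cumulative_fertility(age, p: ASFRParams, support=DEFAULT_SUPPORT):
    """Expected children by ``age``: sum of ASFR over integer ages <= age.

    Ages below the support minimum accumulate nothing.
    """
    lo, hi = support
    grid = np.arange(lo, hi + 1)
    rates = asfr_curve(grid, p)
    csum = np.concatenate([[0.0], np.cumsum(rates)])
    a = np.asarray(age)
    idx = np.clip(np.floor(a).astype(int) - lo + 1, 0, len(grid))
    out = csum[idx]
    if np.isscalar(age):
        return float(out)
    return out


def total_fertility_rate(p: ASFRParams, support=DEFAULT_SUPPORT) -> float:
    """Area under the fertility schedule: expected completed family size."""
    return float(cumulative_fertility(support[1], p, support))


def age_at_half_fertility(p: ASFRParams, support=DEFAULT_SUPPORT) -> float:
    """Age at which cumulative fertility reaches 0.5 children per woman.

    Linear interpolation between integer ages; NaN if never reached.
    """
    lo, hi = support
    grid = np.arange(lo, hi + 1)
    csum = cumulative_fertility(grid, p, support)
    return _interp_crossing(grid, csum, 0.5)


def _interp_crossing(grid: np.ndarray, csum: np.ndarray, level: float) -> float:
    if csum[-1] < level:
        return float("nan")
    j = int(np.searchsorted(csum, level))
    if j == 0:
        return float(grid[0])
    prev = csum[j - 1]
    step = csum[j] - prev
    frac = 0.0 if step <= 0 else (level - prev) / step
    return float(grid[j - 1] + frac * (grid[j] - grid[j - 1]))


# ---------------------------------------------------------------------------
# hierarchical fit
# ---------------------------------------------------------------------------


@dataclass
class ASFRSamplerSettings:
    n_chains: int = 4
    n_warmup: int = 1000
    n_samples: int = 1000
    support: tuple[int, int] = DEFAULT_SUPPORT
    target_accept: float = 0.3
    rhat_threshold: float = 1.05
    strict: bool = False  # raise (rather than warn) on failed diagnostics
    # weakly informative priors, on the transformed scale
    # (log c, mu, log s1, log s2); location/scale of the hyper-mean priors
    hyper_mean_loc: tuple[float, ...] = (np.log(0.15), 28.0, np.log(5.0), np.log(8.0))
    hyper_mean_scale: tuple[float, ...] = (1.0, 5.0, 1.0, 1.0)
    # inverse-gamma(a, b) priors on the hierarchical variances
    hyper_var_a: float = 2.0
    hyper_var_b: tuple[float, ...] = (0.04, 4.0, 0.04, 0.04)


@dataclass
class ASFRFit:
    """Posterior draws for the hierarchical two-subpopulation ASFR model."""

    countries: list
    groups: tuple = GROUPS
    # draws on the natural scale (c, mu, s1, s2)
    theta: np.ndarray = field(default=None)  # (n_draws, n_countries, 2, 4)
    hyper_mean: np.ndarray = field(default=None)  # (n_draws, 2, 4) transformed scale
    hyper_sd: np.ndarray = field(default=None)  # (n_draws, 2, 4) transformed scale
    support: tuple = DEFAULT_SUPPORT
    diagnostics: pd.DataFrame = field(default=None)
    accept_rates: np.ndarray = field(default=None)
    n_chains: int = 1

    @property
    def n_draws(self) -> int:
        return self.theta.shape[0]

    def average_country_params(self) -> np.ndarray:
        """Per-draw curve parameters of the 'average country' (natural scale).

        All country-varying parameters set to their hierarchical mean; for
        log-scale parameters this is the geometric mean across countries.
        """
        out = self.hyper_mean.copy()
        out[..., [0, 2, 3]] = np.exp(out[..., [0, 2, 3]])
        return out

    def to_frame(self) -> pd.DataFrame:
        n_draws, n_c, n_g, _ = self.theta.shape
        idx = pd.MultiIndex.from_product(
            [range(n_draws), self.countries, self.groups],
            names=["draw", "country", "group"],
        )
        flat = self.theta.reshape(n_draws * n_c * n_g, 4)
        return pd.DataFrame(flat, columns=list(PARAM_NAMES), index=idx).reset_index()


def poisson_loglik(children, mean):
    """Poisson log-pmf (per observation), guarding the zero-mean boundary."""
    k = np.asarray(children, dtype=float)
    mu = np.asarray(mean, dtype=float)
    from scipy.special import gammaln

    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(
            mu > 0,
            k * np.log(np.maximum(mu, 1e-300)) - mu - gammaln(k + 1),
            np.where(k == 0, 0.0, -np.inf),
        )
    return ll


def _suffstats(df: pd.DataFrame, countries, support):
    """Per (country, group): (ages, n per age, total children per age)."""
    lo, hi = support
    stats = {}
    for ci, country in enumerate(countries):
        for gi, group in enumerate(GROUPS):
            sub = df[(df["country"] == country) & (df["grb_group"] == group)]
            if len(sub) == 0:
                stats[(ci, gi)] = None
                continue
            agg = sub.groupby("age")["n_children"].agg(["count", "sum"])
            ages = agg.index.to_numpy(dtype=int)
            stats[(ci, gi)] = (
                ages,
                agg["count"].to_numpy(dtype=float),
                agg["sum"].to_numpy(dtype=float),
            )
    return stats


def _block_loglik(theta_t, stat, grid, lo):
    """Poisson log-likelihood of one country-group block.

    ``theta_t`` is on the transformed scale (log c, mu, log s1, log s2).
    Uses sufficient statistics: sum_a [K_a log M(a) - n_a M(a)] with M the
    cumulative schedule.
    """
    if stat is None:
        return 0.0
    c = np.exp(theta_t[0])
    mu = theta_t[1]
    s1 = np.exp(theta_t[2])
    s2 = np.exp(theta_t[3])
    s = np.where(grid < mu, s1, s2)
    rates = c * np.exp(-(((grid - mu) / s) ** 2))
    csum = np.cumsum(rates)
    ages, n_a, k_a = stat
    m = csum[ages - lo]
    m = np.maximum(m, 1e-300)
    return float(np.sum(k_a * np.log(m) - n_a * m))


def fit_asfr(
    df: pd.DataFrame,
    settings: ASFRSamplerSettings | None = None,
    seed: int = 0,
) -> ASFRFit:
    """Fit the hierarchical two-subpopulation ASFR model by MCMC.

    ``df`` must contain columns country, age, n_children, grb_group
    ("low"/"high"), restricted to women in the fertile age range.
    """
    settings = settings or ASFRSamplerSettings()
    df = df.dropna(subset=["n_children", "age"]).copy()
    df["age"] = df["age"].astype(int)
    lo, hi = settings.support
    df = df[(df["age"] >= lo) & (df["age"] <= hi)]
    if len(df) == 0:
        raise ValueError("no usable observations for the ASFR model")
    countries = sorted(df["country"].unique())
    n_c = len(countries)
    stats = _suffstats(df, countries, settings.support)
    grid = np.arange(lo, hi + 1, dtype=float)

    m0 = np.array(settings.hyper_mean_loc)
    s0 = np.array(settings.hyper_mean_scale)
    var_a = settings.hyper_var_a
    var_b = np.array(settings.hyper_var_b)

    ss = np.random.SeedSequence(seed)
    chains = []
    hyper_m_chains = []
    hyper_sd_chains = []
    acc_all = []
    for chain_seed in ss.spawn(settings.n_chains):
        rng = np.random.default_rng(chain_seed)
        th, hm, hsd, acc = _run_chain(
            rng, stats, grid, lo, n_c, m0, s0, var_a, var_b, settings
        )
        chains.append(th)
        hyper_m_chains.append(hm)
        hyper_sd_chains.append(hsd)
        acc_all.append(acc)

    theta_t = np.concatenate(chains, axis=0)
    theta = theta_t.copy()
    theta[..., [0, 2, 3]] = np.exp(theta[..., [0, 2, 3]])
    fit = ASFRFit(
        countries=countries,
        theta=theta,
        hyper_mean=np.concatenate(hyper_m_chains, axis=0),
        hyper_sd=np.concatenate(hyper_sd_chains, axis=0),
        support=settings.support,
        accept_rates=np.mean(acc_all, axis=0),
        n_chains=settings.n_chains,
    )
    fit.diagnostics = _diagnostics(chains, hyper_m_chains, settings)
    return fit


def _run_chain(rng, stats, grid, lo, n_c, m0, s0, var_a, var_b, settings):
    n_g, n_p = 2, 4
    theta = np.tile(m0, (n_c, n_g, 1)) + rng.normal(0, 0.05, (n_c, n_g, n_p))
    hyper_m = np.tile(m0, (n_g, 1)).astype(float)
    hyper_v = np.tile(var_b / (var_a - 1.0), (n_g, 1))
    # adaptive block proposals: global log-scale (Robbins-Monro toward the
    # target acceptance rate) times a running empirical covariance that
    # captures the strong within-block parameter correlations
    log_scale = np.full((n_c, n_g), np.log(0.1))
    shift_log_scale = np.log(np.tile(np.maximum(s0 / 10.0, 0.02), (n_g, 1)))
    run_n = np.zeros((n_c, n_g))
    run_mean = np.zeros((n_c, n_g, n_p))
    run_m2 = np.zeros((n_c, n_g, n_p, n_p))
    chol_prop = np.tile(np.eye(n_p), (n_c, n_g, 1, 1))
    n_iter = settings.n_warmup + settings.n_samples
    keep_theta = np.empty((settings.n_samples, n_c, n_g, n_p))
    keep_m = np.empty((settings.n_samples, n_g, n_p))
    keep_sd = np.empty((settings.n_samples, n_g, n_p))
    acc_count = np.zeros((n_c, n_g))
    prop_count = np.zeros((n_c, n_g))

    curr_ll = np.empty((n_c, n_g))
    for ci in range(n_c):
        for gi in range(n_g):
            curr_ll[ci, gi] = _block_loglik(theta[ci, gi], stats[(ci, gi)], grid, lo)

    cov_start = min(200, settings.n_warmup // 3)
    for it in range(n_iter):
        # --- block Metropolis updates of country-group parameters
        for ci in range(n_c):
            for gi in range(n_g):
                scale = np.exp(log_scale[ci, gi])
                prop = theta[ci, gi] + scale * (
                    chol_prop[ci, gi] @ rng.standard_normal(n_p)
                )
                ll_prop = _block_loglik(prop, stats[(ci, gi)], grid, lo)
                lp_curr = -0.5 * np.sum(
                    (theta[ci, gi] - hyper_m[gi]) ** 2 / hyper_v[gi]
                )
                lp_prop = -0.5 * np.sum((prop - hyper_m[gi]) ** 2 / hyper_v[gi])
                log_r = ll_prop + lp_prop - curr_ll[ci, gi] - lp_curr
                accept = np.log(rng.random()) < log_r
                if accept:
                    theta[ci, gi] = prop
                    curr_ll[ci, gi] = ll_prop
                prop_count[ci, gi] += 1
                if accept:
                    acc_count[ci, gi] += 1
                if it < settings.n_warmup:
                    step = min(0.1, 5.0 / (it + 10))
                    delta = step * ((1.0 if accept else 0.0) - settings.target_accept)
                    log_scale[ci, gi] += delta
                    # Welford update of the block's empirical covariance
                    run_n[ci, gi] += 1
                    d = theta[ci, gi] - run_mean[ci, gi]
                    run_mean[ci, gi] += d / run_n[ci, gi]
                    run_m2[ci, gi] += np.outer(d, theta[ci, gi] - run_mean[ci, gi])
                    if run_n[ci, gi] > cov_start and it % 50 == 0:
                        cov = run_m2[ci, gi] / (run_n[ci, gi] - 1)
                        cov = (2.38**2 / n_p) * cov + 1e-8 * np.eye(n_p)
                        try:
                            chol_prop[ci, gi] = np.linalg.cholesky(cov)
                        except np.linalg.LinAlgError:
                            pass

        # --- joint translation moves (interweaving): shift one hyper mean
        # and all its country parameters together; breaks the strong
        # coupling between the hierarchy and the country blocks
        for gi in range(n_g):
            for k in range(n_p):
                delta = np.exp(shift_log_scale[gi, k]) * rng.standard_normal()
                prop = theta[:, gi, k] + delta
                ll_prop = np.empty(n_c)
                for ci in range(n_c):
                    th = theta[ci, gi].copy()
                    th[k] = prop[ci]
                    ll_prop[ci] = _block_loglik(th, stats[(ci, gi)], grid, lo)
                m_prop = hyper_m[gi, k] + delta
                log_r = (
                    ll_prop.sum()
                    - curr_ll[:, gi].sum()
                    - 0.5 * ((m_prop - m0[k]) ** 2 - (hyper_m[gi, k] - m0[k]) ** 2)
                    / s0[k] ** 2
                )
                accept = np.log(rng.random()) < log_r
                if accept:
                    theta[:, gi, k] = prop
                    hyper_m[gi, k] = m_prop
                    curr_ll[:, gi] = ll_prop
                if it < settings.n_warmup:
                    step = min(0.1, 5.0 / (it + 10))
                    shift_log_scale[gi, k] += step * (
                        (1.0 if accept else 0.0) - settings.target_accept
                    )

        # --- conjugate updates of hierarchy
        for gi in range(n_g):
            for k in range(n_p):
                vals = theta[:, gi, k]
                prec = n_c / hyper_v[gi, k] + 1.0 / s0[k] ** 2
                mean = (vals.sum() / hyper_v[gi, k] + m0[k] / s0[k] ** 2) / prec
                hyper_m[gi, k] = rng.normal(mean, np.sqrt(1.0 / prec))
                a_post = var_a + 0.5 * n_c
                b_post = var_b[k] + 0.5 * np.sum((vals - hyper_m[gi, k]) ** 2)
                hyper_v[gi, k] = b_post / rng.gamma(a_post)

        if it >= settings.n_warmup:
            j = it - settings.n_warmup
            keep_theta[j] = theta
            keep_m[j] = hyper_m
            keep_sd[j] = np.sqrt(hyper_v)

    acc_rate = np.divide(acc_count, np.maximum(prop_count, 1))
    return keep_theta, keep_m, keep_sd, acc_rate


def _diagnostics(theta_chains, hyper_m_chains, settings) -> pd.DataFrame:
    """Rank-normalized R-hat and bulk ESS.

    Reported for every hierarchical mean and for the derived average-country
    fertility metrics (TFR, age at cumulative fertility 0.5, per group).  The
    convergence gate applies to the derived metrics: the raw curve parameters
    trade off along likelihood ridges (e.g. peak location vs pre-peak
    steepness) and can show inflated R-hat even when every quantity the
    analysis reports is well mixed.
    """
    import arviz as az

    def _stat(x):  # x: (chains, draws)
        ds = az.convert_to_dataset(np.asarray(x))
        return float(az.rhat(ds)["x"].values), float(az.ess(ds)["x"].values)

    arr = np.stack(hyper_m_chains)  # (chains, draws, 2, 4)
    rows = []
    for gi, group in enumerate(GROUPS):
        for k, name in enumerate(PARAM_NAMES):
            rhat, ess = _stat(arr[:, :, gi, k])
            rows.append(
                {"param": f"hyper_mean[{group},{name}]", "rhat": rhat,
                 "ess_bulk": ess, "gated": False}
            )
    natural = arr.copy()
    natural[..., [0, 2, 3]] = np.exp(natural[..., [0, 2, 3]])
    tfr, age_half = _metrics_from_params(natural, settings.support)
    for gi, group in enumerate(GROUPS):
        for name, x in [("avg_tfr", tfr[:, :, gi]), ("avg_age_at_half", age_half[:, :, gi])]:
            rhat, ess = _stat(x)
            rows.append(
                {"param": f"{name}[{group}]", "rhat": rhat, "ess_bulk": ess,
                 "gated": True}
            )
    diag = pd.DataFrame(rows)
    bad = diag[diag["gated"] & (diag["rhat"] > settings.rhat_threshold)]
    if len(bad):
        msg = f"ASFR sampler convergence failure: {bad.to_dict('records')}"
        if settings.strict:
            raise RuntimeError(msg)
        logger.warning(msg)
    return diag


# ---------------------------------------------------------------------------
# derived metrics
# ---------------------------------------------------------------------------


@dataclass
class FertilityMetrics:
    """Per-draw fertility level/timing metrics derived from an ASFRFit."""

    tfr: np.ndarray  # (n_draws, n_countries, 2)
    age_at_half: np.ndarray  # same shape; NaN where never reached
    avg_tfr: np.ndarray  # (n_draws, 2) average-country metrics
    avg_age_at_half: np.ndarray
    prop_low_higher_tfr: np.ndarray  # (n_draws,)
    prop_low_earlier: np.ndarray  # (n_draws,)
    n_undefined_age_at_half: int = 0

    def summary(self) -> pd.DataFrame:
        def eti(x):
            x = x[np.isfinite(x)]
            return float(np.mean(x)), float(np.quantile(x, 0.05)), float(np.quantile(x, 0.95))

        rows = []
        for name, x in [
            ("tfr_diff_low_minus_high", self.avg_tfr[:, 0] - self.avg_tfr[:, 1]),
            (
                "age_at_half_diff_high_minus_low",
                self.avg_age_at_half[:, 1] - self.avg_age_at_half[:, 0],
            ),
            ("prop_low_higher_tfr", self.prop_low_higher_tfr),
            ("prop_low_earlier", self.prop_low_earlier),
        ]:
            m, lo, hi = eti(x)
            rows.append({"metric": name, "mean": m, "lo90": lo, "hi90": hi})
        return pd.DataFrame(rows)


def _metrics_from_params(theta: np.ndarray, support) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized TFR and age-at-half for an array of parameter quadruples.

    ``theta`` has shape (..., 4) on the natural scale.
    """
    lo, hi = support
    grid = np.arange(lo, hi + 1, dtype=float)
    c = theta[..., 0:1]
    mu = theta[..., 1:2]
    s1 = theta[..., 2:3]
    s2 = theta[..., 3:4]
    s = np.where(grid < mu, s1, s2)
    rates = c * np.exp(-(((grid - mu) / s) ** 2))
    csum = np.cumsum(rates, axis=-1)
    tfr = csum[..., -1]
    # interpolated crossing of 0.5
    reached = csum >= 0.5
    never = ~reached[..., -1]
    j = np.argmax(reached, axis=-1)
    j = np.maximum(j, 1)
    prev = np.take_along_axis(csum, j[..., None] - 1, axis=-1)[..., 0]
    curr = np.take_along_axis(csum, j[..., None], axis=-1)[..., 0]
    first_ge = csum[..., 0] >= 0.5
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(curr > prev, (0.5 - prev) / (curr - prev), 0.0)
    age_half = grid[j - 1] + frac
    age_half = np.where(first_ge, grid[0], age_half)
    age_half = np.where(never, np.nan, age_half)
    return tfr, age_half


def derive_metrics(fit: ASFRFit) -> FertilityMetrics:
    """TFR, age at cumulative fertility 0.5, and cross-country proportions."""
    tfr, age_half = _metrics_from_params(fit.theta, fit.support)
    avg_params = fit.average_country_params()
    avg_tfr, avg_age = _metrics_from_params(avg_params, fit.support)
    # per draw: share of countries where the low-GRB group has higher TFR /
    # reaches half a child per woman at a younger age
    low_tfr, high_tfr = tfr[:, :, 0], tfr[:, :, 1]
    prop_higher = np.mean(low_tfr > high_tfr, axis=1)
    low_age, high_age = age_half[:, :, 0], age_half[:, :, 1]
    both = np.isfinite(low_age) & np.isfinite(high_age)
    with np.errstate(invalid="ignore"):
        earlier = (low_age < high_age) & both
    denom = np.maximum(both.sum(axis=1), 1)
    prop_earlier = earlier.sum(axis=1) / denom
    return FertilityMetrics(
        tfr=tfr,
        age_at_half=age_half,
        avg_tfr=avg_tfr,
        avg_age_at_half=avg_age,
        prop_low_higher_tfr=prop_higher,
        prop_low_earlier=prop_earlier,
        n_undefined_age_at_half=int(np.isnan(age_half).sum()),
    )
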