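"""Synthetic survey microdata and population tables with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: three ordinal gender-role-belief (GRB) items loading on a latent
0-100 score, country-specific smooth time trends nested in cultural zones,
six age-sex strata with group effects, differential country population
growth negatively tied to GRB, and fertility schedules whose level and
timing depend on GRB.  Every latent quantity is recorded in a
:class:`GroundTruth` object so that estimators can be tested for recovery.

Latent country trends are scaled logistic curves (one shape per cultural
zone) plus a low-order smooth polynomial deviation per country.  Survey
items are generated by adding person- and item-level Gaussian noise to the
latent cell mean and discretizing onto each item's ordinal scale with fixed,
evenly spaced thresholds.  Because discretization is nonlinear, the
generator also stores the exact expected value of the observed composite
score for every country-year-age-sex cell (a closed-form normal-CDF sum);
that expectation is the estimand of the trend model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .asfr import (
    ASFRParams,
    age_at_half_fertility,
    cumulative_fertility,
    total_fertility_rate,
    DEFAULT_SUPPORT,
)
from .measure import DEFAULT_ITEM_SCALES, composite_grb, rescale_item

AGESEX_GROUPS = (
    "male_18-34",
    "female_18-34",
    "male_35-59",
    "female_35-59",
    "male_60+",
    "female_60+",
)

AGE_BANDS = {"18-34": (18, 34), "35-59": (35, 59), "60+": (60, 80)}

#: baseline adult age-sex composition (slightly younger-male-heavy, summing to 1)
BASE_AGESEX_SHARES = np.array([0.19, 0.18, 0.18, 0.18, 0.13, 0.14])


def agesex_label(age: int, sex: str) -> str:
    if 18 <= age <= 34:
        band = "18-34"
    elif 35 <= age <= 59:
        band = "35-59"
    else:
        band = "60+"
    return f"{sex}_{band}"


@dataclass(frozen=True)
class ZoneSpec:
    """Logistic mean-trend parameters for one cultural zone.

    trend(year) = base + gain / (1 + exp(-(year - midpoint) / rate))
    """

    name: str
    base: float
    gain: float
    midpoint: float
    rate: float

    def curve(self, years) -> np.ndarray:
        y = np.asarray(years, dtype=float)
        return self.base + self.gain / (1.0 + np.exp(-(y - self.midpoint) / self.rate))


DEFAULT_ZONES = (
    ZoneSpec("western", base=58.0, gain=16.0, midpoint=2006.0, rate=7.0),
    ZoneSpec("orthodox", base=46.0, gain=9.0, midpoint=2010.0, rate=8.0),
    ZoneSpec("confucian", base=44.0, gain=5.0, midpoint=2008.0, rate=8.0),
    ZoneSpec("islamic_south", base=40.0, gain=-4.0, midpoint=2009.0, rate=8.0),
)


@dataclass(frozen=True)
class FertilityLink:
    """ASFR curve parameters of the two GRB subgroups.

    By default the low-GRB (less egalitarian) group's curve is calibrated so
    that its total fertility exceeds the high group's by ``tfr_gap`` children
    and it reaches half a child per woman ``timing_gap`` years earlier.
    """

    high: ASFRParams
    low: ASFRParams
    split_value: float | None = None  # None: realized median at generation time
    support: tuple[int, int] = DEFAULT_SUPPORT


def calibrate_low_group(
    high: ASFRParams,
    tfr_gap: float = 0.17,
    timing_gap: float = 1.52,
    support=DEFAULT_SUPPORT,
) -> ASFRParams:
    """Solve for the low-GRB curve hitting exact TFR and timing contrasts.

    Keeps s1/s2 at the high group's values and adjusts (c, mu) so that
    TFR_low = TFR_high + tfr_gap and age_at_half_low = age_at_half_high -
    timing_gap, with metrics computed on the same integer-age grid the
    analysis uses.
    """
    from scipy.optimize import fsolve

    t_high = total_fertility_rate(high, support)
    a_high = age_at_half_fertility(high, support)

    def resid(x):
        c, mu = x
        p = ASFRParams(c=max(c, 1e-6), mu=mu, s1=high.s1, s2=high.s2)
        return [
            total_fertility_rate(p, support) - (t_high + tfr_gap),
            age_at_half_fertility(p, support) - (a_high - timing_gap),
        ]

    sol = fsolve(resid, x0=[high.c * 1.1, high.mu - timing_gap], full_output=False)
    low = ASFRParams(c=float(sol[0]), mu=float(sol[1]), s1=high.s1, s2=high.s2)
    return low


def default_fertility_link() -> FertilityLink:
    high = ASFRParams(c=0.15, mu=29.0, s1=5.0, s2=9.0)
    return FertilityLink(high=high, low=calibrate_low_group(high))


@dataclass(frozen=True)
class ScenarioConfig:
    """All knobs of the synthetic scenario.

    Scale parameters are in 0-100 GRB points unless noted.  One master seed
    drives everything; per-stage child seeds are derived deterministically.
    """

    n_countries: int = 20
    zones: tuple[ZoneSpec, ...] = DEFAULT_ZONES
    years: tuple[int, int] = (1995, 2022)
    agesex_groups: tuple[str, ...] = AGESEX_GROUPS
    # latent trend structure
    country_level_sd: float = 4.0  # country intercept deviation from zone
    trend_dev_scale: float = 2.5  # smooth polynomial deviation amplitude
    agesex_dev_sd: float = 1.5  # country deviation of age-sex effects
    # measurement
    person_sd: float = 20.0  # person-level latent GRB spread within a cell
    item_noise_sd: float = 25.0  # latent-to-item noise per item
    item_scales: tuple[tuple[int, int], ...] = DEFAULT_ITEM_SCALES
    # survey design
    waves_min: int = 2
    waves_max: int = 5
    n_per_wave: int = 500
    # population growth: log P(2022) = log P(1995) + intercept + slope * GRB_1995
    growth_slope: float = -0.010
    growth_intercept: float = 0.90
    growth_resid_sd: float = 0.08
    init_pop_log_mean: float = np.log(8e6)
    init_pop_log_sd: float = 1.0
    # fertility
    fertility_link: FertilityLink = field(default_factory=default_fertility_link)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.agesex_groups) != 6:
            raise ValueError("exactly six age-sex groups are required")
        y0, y1 = self.years
        if y1 <= y0:
            raise ValueError("years must be an increasing (start, end) range")
        for name in ("person_sd", "item_noise_sd", "country_level_sd",
                     "trend_dev_scale", "agesex_dev_sd", "growth_resid_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not (1 <= self.waves_min <= self.waves_max):
            raise ValueError("invalid wave range")
        if self.n_per_wave < 1:
            raise ValueError("requested respondents per wave must be >= 1")

    @property
    def year_grid(self) -> np.ndarray:
        return np.arange(self.years[0], self.years[1] + 1)


@dataclass
class GroundTruth:
    """Everything the generator knows, for recovery testing."""

    countries: list
    zone_lookup: pd.DataFrame  # country, zone, hdi_class
    years: np.ndarray
    agesex_groups: tuple
    latent_trends: np.ndarray  # (n_countries, n_years) latent mean GRB
    agesex_effects: np.ndarray  # (n_countries, 6), sum-to-zero per country
    cell_latent: np.ndarray  # (n_countries, n_years, 6)
    cell_expected: np.ndarray  # expected observed composite per cell
    population: pd.DataFrame | None = None
    growth_log_change: np.ndarray | None = None  # per-country realized 27y log growth
    asfr_params: dict | None = None
    fertility_split_value: float | None = None


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

_STAGE = {"trends": 0, "population": 1, "survey": 2, "fertility": 3, "lmm": 4}


def _stage_rng(config: ScenarioConfig, stage: str) -> np.random.Generator:
    ss = np.random.SeedSequence(config.seed)
    return np.random.default_rng(ss.spawn(len(_STAGE))[_STAGE[stage]])


def _legendre_dev(u: np.ndarray, coefs: np.ndarray) -> np.ndarray:
    """Low-order smooth deviation on u in [0, 1] (shifted Legendre P1..P3)."""
    t = 2.0 * u - 1.0
    p1 = t
    p2 = 0.5 * (3 * t**2 - 1)
    p3 = 0.5 * (5 * t**3 - 3 * t)
    return coefs[0] * p1 + coefs[1] * p2 + coefs[2] * p3


def expected_composite(
    latent_mean,
    person_sd: float,
    item_noise_sd: float,
    item_scales=DEFAULT_ITEM_SCALES,
):
    """Exact expected value of the observed composite score given cell mean.

    A cell member's item response is the latent mean plus N(0, person_sd^2 +
    item_noise_sd^2) noise, discretized at thresholds 100*j/L.  The expected
    rescaled item value is a finite sum of normal CDFs.
    """
    m = np.asarray(latent_mean, dtype=float)
    s = float(np.hypot(person_sd, item_noise_sd))
    per_item = []
    for lo, hi in item_scales:
        n_levels = hi - lo + 1
        cuts = 100.0 * np.arange(1, n_levels) / n_levels
        values = 100.0 * np.arange(n_levels) / (n_levels - 1)
        if s == 0:
            idx = np.searchsorted(cuts, m, side="right")
            per_item.append(values[idx])
            continue
        cdf = norm.cdf((cuts.reshape((-1,) + (1,) * m.ndim) - m) / s)
        probs = np.diff(
            np.concatenate(
                [np.zeros((1, *m.shape)), cdf, np.ones((1, *m.shape))], axis=0
            ),
            axis=0,
        )
        per_item.append(np.tensordot(values, probs, axes=(0, 0)))
    return np.mean(per_item, axis=0)


def _discretize_items(latent, rng, item_noise_sd, item_scales):
    """Ordinal item responses (1..L) from person-level latent scores."""
    out = {}
    for j, (lo, hi) in enumerate(item_scales, start=1):
        n_levels = hi - lo + 1
        cuts = 100.0 * np.arange(1, n_levels) / n_levels
        x = latent + rng.normal(0.0, item_noise_sd, size=latent.shape)
        out[f"item{j}"] = np.searchsorted(cuts, x, side="right") + lo
    return out


def make_ground_truth(config: ScenarioConfig) -> GroundTruth:
    """Latent trends, age-sex effects and measurement-scale cell means.

    Deterministic given the config seed; shared by the population and survey
    generators so their latent worlds agree.
    """
    rng = _stage_rng(config, "trends")
    years = config.year_grid
    u = (years - years[0]) / (years[-1] - years[0])
    n_c = config.n_countries
    countries = [f"C{i + 1:02d}" for i in range(n_c)]
    zone_of = [config.zones[i % len(config.zones)] for i in range(n_c)]

    level_dev = rng.normal(0.0, config.country_level_sd, n_c)
    poly = rng.normal(0.0, 1.0, (n_c, 3))
    trends = np.empty((n_c, len(years)))
    for i in range(n_c):
        trends[i] = (
            zone_of[i].curve(years)
            + level_dev[i]
            + config.trend_dev_scale * _legendre_dev(u, poly[i])
        )
    trends = np.clip(trends, 2.0, 98.0)

    base_effects = _base_agesex_effects()
    effects = base_effects[None, :] + rng.normal(
        0.0, config.agesex_dev_sd, (n_c, 6)
    )
    effects -= effects.mean(axis=1, keepdims=True)

    cell_latent = trends[:, :, None] + effects[:, None, :]
    cell_expected = expected_composite(
        cell_latent, config.person_sd, config.item_noise_sd, config.item_scales
    )

    # HDI class from mid-period latent level quartiles (synthetic assignment)
    mid = trends[:, len(years) // 2]
    q = np.quantile(mid, [0.25, 0.5, 0.75])
    hdi = np.array(["low", "medium", "high", "very_high"])[
        np.searchsorted(q, mid, side="right")
    ]
    lookup = pd.DataFrame(
        {
            "country": countries,
            "zone": [z.name for z in zone_of],
            "hdi_class": hdi,
        }
    )
    return GroundTruth(
        countries=countries,
        zone_lookup=lookup,
        years=years,
        agesex_groups=config.agesex_groups,
        latent_trends=trends,
        agesex_effects=effects,
        cell_latent=cell_latent,
        cell_expected=cell_expected,
    )


def _base_agesex_effects() -> np.ndarray:
    """Global age-sex offsets: women and younger adults more egalitarian."""
    sex = {"male": -2.5, "female": 2.5}
    age = {"18-34": 2.0, "35-59": 0.5, "60+": -2.5}
    eff = np.array(
        [sex[g.split("_")[0]] + age[g.split("_")[1]] for g in AGESEX_GROUPS]
    )
    return eff - eff.mean()


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------


def generate_population(
    config: ScenarioConfig, ground_truth: GroundTruth | None = None
) -> pd.DataFrame:
    """Country-year-age-sex adult population counts.

    Total adult population grows log-linearly; the 27-year log growth is
    ``growth_intercept + growth_slope * latent GRB in the first year`` plus
    optional country-level noise.  Within-country age-sex shares are drawn
    once per country and held constant over time.
    """
    gt = ground_truth or make_ground_truth(config)
    rng = _stage_rng(config, "population")
    years = gt.years
    span = years[-1] - years[0]
    n_c = len(gt.countries)

    log_init = rng.normal(config.init_pop_log_mean, config.init_pop_log_sd, n_c)
    if np.any(np.exp(log_init) <= 0):  # pragma: no cover - defensive
        raise ValueError("non-positive initial population generated")
    grb0 = gt.latent_trends[:, 0]
    log_change = (
        config.growth_intercept
        + config.growth_slope * grb0
        + (rng.normal(0.0, config.growth_resid_sd, n_c)
           if config.growth_resid_sd > 0 else 0.0)
    )
    shares = rng.dirichlet(BASE_AGESEX_SHARES * 120.0, size=n_c)

    rows = []
    for i, country in enumerate(gt.countries):
        rate = log_change[i] / span
        totals = np.exp(log_init[i] + rate * (years - years[0]))
        for yi, year in enumerate(years):
            for gi, group in enumerate(config.agesex_groups):
                rows.append((country, int(year), group, totals[yi] * shares[i, gi]))
    pop = pd.DataFrame(rows, columns=["country", "year", "agesex", "count"])
    gt.population = pop
    gt.growth_log_change = log_change
    return pop


def generate_survey(
    config: ScenarioConfig,
    pop: pd.DataFrame,
    ground_truth: GroundTruth | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Respondent-level survey microdata plus the generating ground truth.

    Each country gets 2-5 survey waves; the first wave falls early and the
    last falls in 2013 or later, so every country satisfies both the trend
    model's span rule and the fertility models' recency rule while keeping
    wave-year gaps heterogeneous.
    """
    gt = ground_truth or make_ground_truth(config)
    if gt.population is None:
        gt.population = pop
    rng = _stage_rng(config, "survey")
    years = gt.years
    y0, y1 = int(years[0]), int(years[-1])
    pop_shares = (
        pop.set_index(["country", "year", "agesex"])["count"]
        .unstack("agesex")
        .reindex(columns=list(config.agesex_groups))
    )

    records = []
    group_bands = [g.split("_") for g in config.agesex_groups]
    for i, country in enumerate(gt.countries):
        n_waves = int(rng.integers(config.waves_min, config.waves_max + 1))
        first = int(rng.integers(y0, y0 + 9))
        last = int(rng.integers(max(y1 - 9, first + 7), y1 + 1))
        middle = sorted(
            rng.choice(
                np.arange(first + 1, last), size=max(n_waves - 2, 0), replace=False
            ).tolist()
        ) if n_waves > 2 else []
        wave_years = [first] + middle + [last]
        for year in wave_years:
            shares = pop_shares.loc[(country, year)].to_numpy()
            shares = shares / shares.sum()
            grp_idx = rng.choice(6, size=config.n_per_wave, p=shares)
            yi = year - y0
            for gi in range(6):
                n_g = int(np.sum(grp_idx == gi))
                if n_g == 0:
                    continue
                sex, band = group_bands[gi]
                lo, hi = AGE_BANDS[band]
                ages = rng.integers(lo, hi + 1, n_g)
                latent = gt.cell_latent[i, yi, gi] + rng.normal(
                    0.0, config.person_sd, n_g
                )
                items = _discretize_items(
                    latent, rng, config.item_noise_sd, config.item_scales
                )
                covs = _covariates(latent, rng, n_g)
                rec = {
                    "country": np.repeat(country, n_g),
                    "year": np.repeat(year, n_g),
                    "age": ages,
                    "sex": np.repeat(sex, n_g),
                    "agesex": np.repeat(config.agesex_groups[gi], n_g),
                    **items,
                    **covs,
                }
                records.append(pd.DataFrame(rec))
    survey = pd.concat(records, ignore_index=True)
    survey["n_children"] = np.nan
    return survey, gt


def _covariates(latent: np.ndarray, rng, n: int) -> dict:
    """Education/income/town-size/religiosity covariates, loosely tied to GRB."""
    z = (latent - 50.0) / 30.0
    edu_lat = z + rng.normal(0.0, 1.0, n)
    education = np.array(["primary", "lower_secondary", "upper_secondary", "tertiary"])[
        np.searchsorted([-0.8, 0.2, 1.0], edu_lat, side="right")
    ]
    inc_lat = 0.4 * edu_lat + rng.normal(0.0, 1.0, n)
    income = np.array(["low", "medium", "high"])[
        np.searchsorted([-0.4, 0.8], inc_lat, side="right")
    ]
    town = rng.choice(
        ["lt5k", "5k-20k", "20k-100k", "100k-500k", "gt500k"],
        size=n,
        p=[0.30, 0.20, 0.20, 0.15, 0.15],
    )
    relig_lat = 50.0 - 12.0 * z + rng.normal(0.0, 18.0, n)
    rel = {}
    for j, (lo, hi) in enumerate(((1, 4), (1, 5), (1, 7), (1, 10)), start=1):
        n_levels = hi - lo + 1
        cuts = 100.0 * np.arange(1, n_levels) / n_levels
        x = relig_lat + rng.normal(0.0, 20.0, n)
        rel[f"rel{j}"] = np.searchsorted(cuts, x, side="right") + lo
    return {"education": education, "income": income, "town_size": town, **rel}


def generate_fertility(
    config: ScenarioConfig,
    survey: pd.DataFrame,
    ground_truth: GroundTruth | None = None,
) -> pd.DataFrame:
    """Draw children counts for women in the fertile age range.

    Each woman's count is Poisson with mean equal to her GRB subgroup's
    cumulative ASFR at her age.  The subgroup is determined by her composite
    score relative to the configured split (default: the realized median
    among the women receiving counts).
    """
    rng = _stage_rng(config, "fertility")
    link = config.fertility_link
    out = survey.copy()
    if "sex" not in out.columns or "age" not in out.columns:
        raise ValueError("survey must carry sex and age columns")
    lo, hi = link.support
    women = (out["sex"] == "female") & (out["age"] >= 18) & (out["age"] <= hi)
    idx = out.index[women]
    rescaled = np.column_stack(
        [
            rescale_item(out.loc[idx, f"item{j + 1}"].to_numpy(float), a, b)
            for j, (a, b) in enumerate(config.item_scales)
        ]
    )
    grb = composite_grb(rescaled)
    split = link.split_value
    if split is None:
        split = float(np.nanmedian(grb))
    is_low = grb <= split
    means = np.where(
        is_low,
        cumulative_fertility(out.loc[idx, "age"].to_numpy(int), link.low, link.support),
        cumulative_fertility(out.loc[idx, "age"].to_numpy(int), link.high, link.support),
    )
    out.loc[idx, "n_children"] = rng.poisson(means).astype(float)
    out.attrs["fertility_split_value"] = split
    if ground_truth is not None:
        ground_truth.asfr_params = {"low": link.low, "high": link.high}
        ground_truth.fertility_split_value = split
    return out


def generate_scenario(
    config: ScenarioConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Convenience wrapper: population + survey + fertility in one call."""
    gt = make_ground_truth(config)
    pop = generate_population(config, gt)
    survey, gt = generate_survey(config, pop, gt)
    survey = generate_fertility(config, survey, gt)
    return survey, pop, gt


# ---------------------------------------------------------------------------
# generator for the hybrid (within-between) mixed-model recovery tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HybridCoefs:
    """Generating coefficients of the Gaussian hybrid fertility model."""

    intercept: float = 2.2
    within: float = -0.102
    between: float = -0.622
    intercept_sd: float = 0.574
    slope_sd: float = 0.050
    resid_sd: float = 1.205


def generate_hybrid_sample(
    n_countries: int = 100,
    n_per_country: int = 150,
    coefs: HybridCoefs = HybridCoefs(),
    seed: int = 0,
) -> pd.DataFrame:
    """Country-clustered sample from the within/between fertility model.

    Standardized GRB decomposes into a country mean (SD ~0.8 across
    countries) and an individual deviation; children counts follow the
    Gaussian hybrid model with country random intercepts and random
    within-slopes.  Used to test estimator recovery.
    """
    rng = np.random.default_rng(seed)
    between_sd = 0.8
    within_sd = np.sqrt(1.0 - between_sd**2)
    rows = []
    for i in range(n_countries):
        m = rng.normal(0.0, between_sd)
        w = rng.normal(0.0, within_sd, n_per_country)
        x = m + w
        xbar = x.mean()
        u0 = rng.normal(0.0, coefs.intercept_sd)
        u1 = rng.normal(0.0, coefs.slope_sd)
        children = (
            coefs.intercept
            + (coefs.within + u1) * (x - xbar)
            + coefs.between * xbar
            + u0
            + rng.normal(0.0, coefs.resid_sd, n_per_country)
        )
        rows.append(
            pd.DataFrame(
                {"country": f"C{i + 1:03d}", "grb_z": x, "n_children": children}
            )
        )
    return pd.concat(rows, ignore_index=True)
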