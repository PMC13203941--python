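"""Poststratification of cell-level trend draws to population means.

Model-predicted mean GRB for each country-year-age-sex cell is reweighted by
external population counts: within-country age-sex shares give national
means; national adult-population shares aggregate countries to cultural
zones, HDI classes, or the world.  Every weighted average is computed
independently for each posterior draw, so uncertainty propagates through all
aggregation levels.  Equal-tailed intervals use linear interpolation between
order statistics (numpy's default quantile rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trends import TrendPosterior

LEVELS = ("country", "zone", "hdi", "global")


@dataclass
class CountryDraws:
    """Per-draw poststratified national mean GRB."""

    values: np.ndarray  # (n_draws, n_countries, n_years)
    countries: list
    years: np.ndarray


@dataclass
class AggregateSeries:
    """Posterior summary of one aggregation unit's trajectory."""

    unit: str
    years: np.ndarray
    mean: np.ndarray
    lo90: np.ndarray
    hi90: np.ndarray
    represented_population: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "unit": self.unit,
                "year": self.years,
                "mean": self.mean,
                "lo90": self.lo90,
                "hi90": self.hi90,
                "represented_population": self.represented_population,
            }
        )


def _pop_cube(pop: pd.DataFrame, countries, years, agesex) -> np.ndarray:
    """Population counts as a dense (country, year, agesex) array."""
    pivot = pop.set_index(["country", "year", "agesex"])["count"]
    idx = pd.MultiIndex.from_product([countries, years, agesex])
    missing = idx.difference(pivot.index)
    if len(missing):
        raise ValueError(
            f"population table is missing {len(missing)} cells, e.g. {list(missing[:3])}"
        )
    return pivot.reindex(idx).to_numpy().reshape(len(countries), len(years), len(agesex))


def build_weights(
    pop: pd.DataFrame, countries, years, agesex, level: str = "country"
) -> np.ndarray:
    """Poststratification weights.

    ``level='country'``: within-country age-sex shares, shape (country, year,
    agesex), summing to 1 over cells within each country-year.  Other levels:
    national adult-population shares, shape (country, year), summing to 1
    over the listed countries each year.
    """
    cube = _pop_cube(pop, countries, years, agesex)
    if np.any(cube < 0):
        raise ValueError("negative population counts")
    if level == "country":
        return cube / cube.sum(axis=2, keepdims=True)
    totals = cube.sum(axis=2)
    return totals / totals.sum(axis=0, keepdims=True)


def poststratify(draws: TrendPosterior, pop: pd.DataFrame) -> CountryDraws:
    """National mean GRB per draw: age-sex cells weighted by population shares."""
    w = build_weights(pop, draws.countries, draws.years, draws.agesex, "country")
    values = np.einsum("dcyg,cyg->dcy", draws.values, w)
    return CountryDraws(values=values, countries=draws.countries, years=draws.years)


def aggregate(
    country_draws: CountryDraws,
    pop: pd.DataFrame,
    level: str = "global",
    lookup: pd.DataFrame | None = None,
    agesex=None,
) -> dict:
    """Aggregate national series to zone / HDI-class / global series.

    Returns {unit: (per-draw values (n_draws, n_years), represented adult
    population per year)}.  Countries absent from the draws are excluded from
    the aggregate; the represented population is reported alongside.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}")
    countries = country_draws.countries
    years = country_draws.years
    if agesex is None:
        agesex = sorted(pop["agesex"].unique())
    cube = _pop_cube(pop, countries, years, agesex)
    totals = cube.sum(axis=2)  # (country, year)

    if level == "country":
        return {
            c: (country_draws.values[:, i, :], totals[i])
            for i, c in enumerate(countries)
        }
    if level == "global":
        groups = {"global": list(range(len(countries)))}
    else:
        col = "zone" if level == "zone" else "hdi_class"
        if lookup is None:
            raise ValueError(f"{level} aggregation needs a country lookup table")
        lut = dict(zip(lookup["country"], lookup[col]))
        groups: dict = {}
        for i, c in enumerate(countries):
            groups.setdefault(lut[c], []).append(i)

    out = {}
    for unit, idx in sorted(groups.items()):
        sub_tot = totals[idx]  # (k, years)
        w = sub_tot / sub_tot.sum(axis=0, keepdims=True)
        vals = np.einsum("dky,ky->dy", country_draws.values[:, idx, :], w)
        out[unit] = (vals, sub_tot.sum(axis=0))
    return out


def summarize(
    unit: str,
    values: np.ndarray,
    years: np.ndarray,
    represented_population=None,
) -> AggregateSeries:
    """Posterior mean and 90% equal-tailed interval per year."""
    if values.shape[0] < 100:
        raise ValueError("need at least 100 draws to summarize")
    rep = (
        np.asarray(represented_population, dtype=float)
        if represented_population is not None
        else np.full(len(years), np.nan)
    )
    return AggregateSeries(
        unit=unit,
        years=np.asarray(years),
        mean=values.mean(axis=0),
        lo90=np.quantile(values, 0.05, axis=0),
        hi90=np.quantile(values, 0.95, axis=0),
        represented_population=rep,
    )


def change_summary(values: np.ndarray, years, y_from: int, y_to: int) -> dict:
    """Posterior summary of the y_from -> y_to change, computed per draw."""
    years = list(np.asarray(years))
    delta = values[:, years.index(y_to)] - values[:, years.index(y_from)]
    return {
        "mean": float(delta.mean()),
        "median": float(np.median(delta)),
        "lo90": float(np.quantile(delta, 0.05)),
        "hi90": float(np.quantile(delta, 0.95)),
    }


def equal_vs_weighted(
    country_draws: CountryDraws, pop: pd.DataFrame, agesex=None
) -> tuple[np.ndarray, np.ndarray]:
    """Average-country vs average-citizen global series (per draw).

    Returns (equal-weight series, population-weight series), each of shape
    (n_draws, n_years).
    """
    equal = country_draws.values.mean(axis=1)
    weighted = aggregate(country_draws, pop, "global", agesex=agesex)["global"][0]
    return equal, weighted
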