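import numpy as np
import pandas as pd
import pytest

from grbtrends.measure import score_survey
from grbtrends.synthetic import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def small_scenario():
    """A compact scenario shared by tests that only need realistic structure."""
    cfg = ScenarioConfig(n_countries=8, n_per_wave=300, seed=42)
    survey, pop, gt = generate_scenario(cfg)
    return cfg, survey, pop, gt


@pytest.fixture(scope="session")
def scored_scenario(small_scenario):
    cfg, survey, pop, gt = small_scenario
    return cfg, score_survey(survey, add_group=True), pop, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_country_draws():
    """Hand-sized national draws for poststratification arithmetic tests."""
    from grbtrends.poststrat import CountryDraws

    years = np.array([1995, 2000, 2022])
    values = np.array(
        [
            [[40.0, 41.0, 42.0], [60.0, 61.0, 62.0]],
            [[40.0, 41.0, 42.0], [60.0, 61.0, 62.0]],
        ]
    )  # 2 draws, 2 countries, 3 years
    return CountryDraws(values=values, countries=["A", "B"], years=years)


def toy_population(countries, years, agesex, counts_by_country):
    rows = []
    for c in countries:
        for y in years:
            for g in agesex:
                rows.append((c, y, g, counts_by_country[c] / len(agesex)))
    return pd.DataFrame(rows, columns=["country", "year", "agesex", "count"])
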