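import numpy as np
import pandas as pd
import pytest

from grbtrends.asfr import ASFRParams, cumulative_fertility, total_fertility_rate
from grbtrends.measure import score_survey
from grbtrends.synthetic import (
    FertilityLink,
    ScenarioConfig,
    calibrate_low_group,
    expected_composite,
    generate_fertility,
    generate_population,
    generate_scenario,
    generate_survey,
    make_ground_truth,
)


def test_config_validation():
    with pytest.raises(ValueError):
        ScenarioConfig(years=(2022, 1995))
    with pytest.raises(ValueError):
        ScenarioConfig(person_sd=-1.0)
    with pytest.raises(ValueError):
        ScenarioConfig(n_per_wave=0)
    with pytest.raises(ValueError):
        ScenarioConfig(agesex_groups=("a", "b"))


def test_same_seed_reproduces_tables_exactly(small_scenario):
    cfg, survey, pop, _ = small_scenario
    survey2, pop2, _ = generate_scenario(cfg)
    pd.testing.assert_frame_equal(survey, survey2)
    pd.testing.assert_frame_equal(pop, pop2)


def test_different_seed_changes_tables(small_scenario):
    cfg, survey, _, _ = small_scenario
    from dataclasses import replace

    survey2, _, _ = generate_scenario(replace(cfg, seed=cfg.seed + 1))
    assert not survey.equals(survey2)


class TestPopulation:
    def test_zero_slope_equal_growth_factors(self):
        cfg = ScenarioConfig(n_countries=5, growth_slope=0.0, growth_resid_sd=0.0, seed=1)
        pop = generate_population(cfg)
        totals = pop.groupby(["country", "year"])["count"].sum().unstack("year")
        ratios = totals[2022] / totals[1995]
        assert np.allclose(ratios, ratios.iloc[0])

    def test_negative_slope_low_grb_grows_faster(self):
        cfg = ScenarioConfig(n_countries=12, growth_slope=-0.01, growth_resid_sd=0.0, seed=2)
        gt = make_ground_truth(cfg)
        pop = generate_population(cfg, gt)
        totals = pop.groupby(["country", "year"])["count"].sum().unstack("year")
        ratios = (totals[2022] / totals[1995]).loc[gt.countries].to_numpy()
        grb0 = gt.latent_trends[:, 0]
        # closed form: log ratio = intercept + slope * grb0 -> strictly decreasing
        order = np.argsort(grb0)
        assert np.all(np.diff(np.log(ratios[order])) < 0)
        # exact slope check between the most extreme pair
        i, j = order[0], order[-1]
        slope = (np.log(ratios[j]) - np.log(ratios[i])) / (grb0[j] - grb0[i])
        assert slope == pytest.approx(-0.01, rel=1e-9)

    def test_counts_strictly_positive(self, small_scenario):
        _, _, pop, _ = small_scenario
        assert (pop["count"] > 0).all()


class TestSurvey:
    def test_wave_count_in_range(self, small_scenario):
        cfg, survey, _, _ = small_scenario
        waves = survey.groupby("country")["year"].nunique()
        assert waves.between(cfg.waves_min, cfg.waves_max).all()

    def test_agesex_membership_consistent_with_age(self, small_scenario):
        _, survey, _, _ = small_scenario
        from grbtrends.synthetic import agesex_label

        expect = [agesex_label(a, s) for a, s in zip(survey["age"], survey["sex"])]
        assert (survey["agesex"] == expect).all()

    def test_agesex_shares_match_population_within_binomial_error(self, small_scenario):
        cfg, survey, pop, _ = small_scenario
        merged = survey.groupby(["country", "year", "agesex"]).size().rename("n")
        pshare = pop.set_index(["country", "year", "agesex"])["count"]
        for (c, y), sub in merged.groupby(level=[0, 1]):
            n = sub.sum()
            p = pshare.loc[c, y] / pshare.loc[c, y].sum()
            obs = sub.droplevel([0, 1]).reindex(p.index).fillna(0) / n
            se = np.sqrt(p * (1 - p) / n)
            assert (np.abs(obs - p) < 5 * se + 1e-9).all()

    def test_large_wave_sample_mean_near_expected_composite(self):
        cfg = ScenarioConfig(n_countries=2, n_per_wave=6000, waves_min=2, waves_max=2, seed=9)
        gt = make_ground_truth(cfg)
        pop = generate_population(cfg, gt)
        survey, gt = generate_survey(cfg, pop, gt)
        scored = score_survey(survey)
        ymap = {y: i for i, y in enumerate(gt.years)}
        gmap = {g: i for i, g in enumerate(cfg.agesex_groups)}
        cell = scored.groupby(["country", "year", "agesex"])["grb"].agg(["mean", "count"])
        big = cell[cell["count"] >= 500]
        for (c, y, g), row in big.iterrows():
            truth = gt.cell_expected[gt.countries.index(c), ymap[y], gmap[g]]
            assert abs(row["mean"] - truth) < 1.0 + 4 * 30 / np.sqrt(row["count"])


class TestExpectedComposite:
    def test_matches_monte_carlo(self, rng):
        m = 55.0
        person_sd, item_sd = 20.0, 25.0
        n = 200_000
        latent = m + rng.normal(0, person_sd, n)
        vals = []
        for lo, hi in ((1, 2), (1, 3), (1, 4)):
            L = hi - lo + 1
            cuts = 100.0 * np.arange(1, L) / L
            x = latent + rng.normal(0, item_sd, n)
            lev = np.searchsorted(cuts, x, side="right")
            vals.append(100.0 * lev / (L - 1))
        mc = np.mean(vals)
        exact = expected_composite(np.array(m), person_sd, item_sd)
        assert mc == pytest.approx(float(exact), abs=0.2)


class TestFertility:
    def test_zero_height_curve_gives_zero_children(self, small_scenario):
        cfg, survey, _, _ = small_scenario
        from dataclasses import replace

        zero = ASFRParams(c=0.0, mu=28.0, s1=5.0, s2=9.0)
        cfg0 = replace(cfg, fertility_link=FertilityLink(high=zero, low=zero))
        out = generate_fertility(cfg0, survey.drop(columns="n_children"))
        kids = out.loc[out["n_children"].notna(), "n_children"]
        assert (kids == 0).all()

    def test_children_only_for_women_in_support(self, small_scenario):
        _, survey, _, _ = small_scenario
        has = survey["n_children"].notna()
        assert (survey.loc[has, "sex"] == "female").all()
        assert survey.loc[has, "age"].between(18, 49).all()

    def test_missing_sex_rejected(self, small_scenario):
        cfg, survey, _, _ = small_scenario
        with pytest.raises(ValueError):
            generate_fertility(cfg, survey.drop(columns=["sex"]))

    def test_mean_children_at_49_matches_configured_tfr(self):
        # Monte-Carlo check against the closed-form cumulative schedule
        rng = np.random.default_rng(5)
        p = ASFRParams(c=0.16, mu=28.0, s1=5.0, s2=9.0)
        kids = rng.poisson(cumulative_fertility(49, p), size=10_000)
        tfr = total_fertility_rate(p)
        se = np.sqrt(tfr / 10_000)
        assert abs(kids.mean() - tfr) < 2 * se + 0.01


def test_calibrated_low_group_hits_exact_contrasts():
    from grbtrends.asfr import age_at_half_fertility

    high = ASFRParams(c=0.15, mu=29.0, s1=5.0, s2=9.0)
    low = calibrate_low_group(high, tfr_gap=0.17, timing_gap=1.52)
    assert total_fertility_rate(low) - total_fertility_rate(high) == pytest.approx(0.17, abs=1e-8)
    assert age_at_half_fertility(high) - age_at_half_fertility(low) == pytest.approx(1.52, abs=1e-8)
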