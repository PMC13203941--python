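import numpy as np
import pandas as pd
import pytest

from grbtrends.measure import score_survey
from grbtrends.splines import bspline_basis, difference_penalty
from grbtrends.synthetic import ScenarioConfig, generate_scenario, make_ground_truth
from grbtrends.trends import (
    TrendModelSpec,
    build_design,
    draw_posterior,
    fit_trend_model,
)


def deboor(x, t, k, i):
    """Textbook de Boor recursion for a single B-spline basis function."""
    if k == 0:
        return 1.0 if t[i] <= x < t[i + 1] else 0.0
    d1 = t[i + k] - t[i]
    d2 = t[i + k + 1] - t[i + 1]
    a = 0.0 if d1 == 0 else (x - t[i]) / d1 * deboor(x, t, k - 1, i)
    b = 0.0 if d2 == 0 else (t[i + k + 1] - x) / d2 * deboor(x, t, k - 1, i + 1)
    return a + b


def _single_country_survey(years, n_per_year=40, seed=0, mean_fn=None):
    rng = np.random.default_rng(seed)
    rows = []
    for y in years:
        m = mean_fn(y) if mean_fn else 50.0
        rows.append(
            pd.DataFrame(
                {
                    "country": "A",
                    "year": y,
                    "agesex": "all",
                    "grb": m + rng.normal(0, 5, n_per_year),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


ZONES_A = pd.DataFrame({"country": ["A"], "zone": ["z1"]})


class TestDesign:
    def test_degenerate_single_country_reduces_to_intercept_plus_smooth(self):
        survey = _single_country_survey(range(1995, 2023, 3))
        spec = TrendModelSpec(basis_dim_zone=6, n_draws=100)
        design = build_design(survey, ZONES_A, spec)
        # intercept + zone linear + zone wiggly (dim-2); no country/agesex blocks
        assert design.p == 1 + 1 + (6 - 2)
        assert [b.name for b in design.pen_blocks] == ["zone_smooth"]

    def test_penalty_matrix_symmetric_psd(self):
        S = difference_penalty(8, 2)
        assert np.allclose(S, S.T)
        assert np.linalg.eigvalsh(S).min() > -1e-10

    def test_basis_matches_de_boor_recursion(self):
        n_basis, degree = 7, 3
        interior = np.linspace(0, 1, n_basis - degree + 1)[1:-1]
        t = np.concatenate([[0] * 4, interior, [1] * 4])
        probes = np.array([0.05, 0.23, 0.5, 0.77, 0.99])
        B = bspline_basis(probes, n_basis, 0.0, 1.0, degree)
        oracle = np.array(
            [[deboor(x, t, degree, i) for i in range(n_basis)] for x in probes]
        )
        assert np.allclose(B, oracle, atol=1e-12)

    def test_single_wave_country_excluded_with_warning(self, caplog):
        survey = _single_country_survey(range(1995, 2023, 3))
        extra = pd.DataFrame(
            {"country": "B", "year": 2010, "agesex": "all", "grb": np.full(30, 55.0)}
        )
        zones = pd.DataFrame({"country": ["A", "B"], "zone": ["z1", "z1"]})
        import logging

        with caplog.at_level(logging.WARNING, logger="grbtrends.trends"):
            design = build_design(pd.concat([survey, extra]), zones, TrendModelSpec())
        assert design.countries == ["A"]
        assert "B" in design.dropped_countries
        assert any("inclusion" in r.message for r in caplog.records)

    def test_short_span_country_excluded(self):
        survey = _single_country_survey(range(1995, 2023, 3))
        extra = _single_country_survey([2010, 2012], seed=1).assign(country="B")
        zones = pd.DataFrame({"country": ["A", "B"], "zone": ["z1", "z1"]})
        design = build_design(pd.concat([survey, extra]), zones, TrendModelSpec())
        assert "B" in design.dropped_countries


class TestFit:
    def test_zero_penalty_single_country_equals_ols(self):
        years = list(range(1995, 2023, 2))
        survey = _single_country_survey(years, mean_fn=lambda y: 40 + 0.5 * (y - 1995))
        spec = TrendModelSpec(basis_dim_zone=6, n_draws=100)
        design = build_design(survey, ZONES_A, spec)
        tiny = {k: 1e-8 for k in design.lam_keys()}
        model = fit_trend_model(design, lambdas=tiny)
        W = design.cells["n"].to_numpy(float)
        X, y = design.X, design.cells["ybar"].to_numpy()
        beta_ols, *_ = np.linalg.lstsq(X * np.sqrt(W)[:, None], y * np.sqrt(W), rcond=None)
        assert np.abs(model.beta - beta_ols).max() / np.abs(beta_ols).max() < 1e-6

    def test_flat_trend_recovery(self):
        rng = np.random.default_rng(3)
        rows = []
        zones = []
        for i, c in enumerate("ABCDE"):
            zones.append({"country": c, "zone": "z1"})
            for y in (1996, 2005, 2013, 2021):
                rows.append(
                    pd.DataFrame(
                        {
                            "country": c,
                            "year": y,
                            "agesex": "all",
                            "grb": 50.0 + rng.normal(0, 10, 400),
                        }
                    )
                )
        design = build_design(pd.concat(rows), pd.DataFrame(zones), TrendModelSpec(n_draws=100))
        model = fit_trend_model(design)
        pred = model.predict_cells()
        assert np.abs(pred["fit"] - 50.0).max() < 1.5

    def test_infinite_penalty_collapses_countries_to_zone(self):
        rng = np.random.default_rng(4)
        rows, zones = [], []
        for c, off in zip("AB", (+5.0, -5.0)):
            zones.append({"country": c, "zone": "z1"})
            for y in (1995, 2004, 2013, 2022):
                rows.append(
                    pd.DataFrame(
                        {"country": c, "year": y, "agesex": "all",
                         "grb": 50.0 + off + rng.normal(0, 3, 200)}
                    )
                )
        design = build_design(pd.concat(rows), pd.DataFrame(zones), TrendModelSpec(n_draws=100))
        lam = {k: 1.0 for k in design.lam_keys()}
        for k in ("country_smooth", "country_linear", "country_intercept"):
            lam[k] = 1e12
        model = fit_trend_model(design, lambdas=lam)
        pred = model.predict_cells().pivot_table(index="year", columns="country", values="fit")
        assert np.abs(pred["A"] - pred["B"]).max() < 1e-3

    def test_translation_equivariance(self):
        survey = _single_country_survey(range(1995, 2023, 4), seed=7)
        design = build_design(survey, ZONES_A, TrendModelSpec(n_draws=100))
        lam = {k: 1.0 for k in design.lam_keys()}
        m0 = fit_trend_model(design, lambdas=lam)
        shifted = survey.assign(grb=survey["grb"] + 7.5)
        d2 = build_design(shifted, ZONES_A, TrendModelSpec(n_draws=100))
        m2 = fit_trend_model(d2, lambdas=lam)
        assert np.allclose(
            m2.predict_cells()["fit"], m0.predict_cells()["fit"] + 7.5, atol=1e-8
        )

    def test_country_relabeling_equivariance(self, scored_scenario):
        cfg, scored, pop, gt = scored_scenario
        spec = TrendModelSpec(n_draws=100)
        design = build_design(scored, gt.zone_lookup, spec)
        model = fit_trend_model(design)
        pred = model.predict_cells()
        # relabel countries (reverse names), keeping zones attached
        mapping = dict(zip(gt.countries, reversed(gt.countries)))
        scored2 = scored.assign(country=scored["country"].map(mapping))
        zones2 = gt.zone_lookup.assign(country=gt.zone_lookup["country"].map(mapping))
        model2 = fit_trend_model(build_design(scored2, zones2, spec))
        pred2 = model2.predict_cells()
        pred2["country"] = pred2["country"].map({v: k for k, v in mapping.items()})
        merged = pred.merge(pred2, on=["country", "year", "agesex"], suffixes=("", "_r"))
        assert np.allclose(merged["fit"], merged["fit_r"], atol=1e-6)


class TestPosterior:
    def test_zero_residual_variance_draws_identical(self):
        survey = _single_country_survey(range(1995, 2023, 4))
        design = build_design(survey, ZONES_A, TrendModelSpec(n_draws=100))
        model = fit_trend_model(design, lambdas={k: 1.0 for k in design.lam_keys()})
        model.sigma2 = 0.0
        post = draw_posterior(model, n_draws=100, seed=0)
        assert np.allclose(post.values.std(axis=0), 0.0)

    def test_draw_mean_converges_to_point_fit(self, scored_scenario):
        cfg, scored, pop, gt = scored_scenario
        design = build_design(scored, gt.zone_lookup, TrendModelSpec(n_draws=2000))
        model = fit_trend_model(design)
        post = draw_posterior(model, n_draws=2000, seed=1, lambda_uncertainty=False)
        point = model.predict_cells()["fit"].to_numpy().reshape(post.values.shape[1:])
        sd = post.values.std(axis=0)
        mc_err = 4 * sd / np.sqrt(post.n_draws) + 1e-6
        assert (np.abs(post.values.mean(axis=0) - point) < mc_err).mean() > 0.99

    def test_gap_years_no_less_uncertain_than_surveyed(self, scored_scenario):
        # information borrowing: on average over countries, the draw SD of a
        # cell is weakly larger in survey-free years than in surveyed years
        cfg, scored, pop, gt = scored_scenario
        design = build_design(scored, gt.zone_lookup, TrendModelSpec(n_draws=800))
        model = fit_trend_model(design)
        post = draw_posterior(model, n_draws=800, seed=2)
        sd = post.values.std(axis=0).mean(axis=2)  # (country, year)
        surveyed = np.zeros_like(sd, dtype=bool)
        obs = design.cells[["country", "year"]].drop_duplicates()
        for c, y in obs.itertuples(index=False):
            surveyed[post.countries.index(c), list(post.years).index(y)] = True
        assert sd[surveyed].mean() <= sd[~surveyed].mean()

    def test_finite_everywhere_including_survey_free_years(self, scored_scenario):
        cfg, scored, pop, gt = scored_scenario
        design = build_design(scored, gt.zone_lookup, TrendModelSpec(n_draws=200))
        model = fit_trend_model(design)
        post = draw_posterior(model, n_draws=200, seed=3)
        assert np.isfinite(post.values).all()

    def test_agesex_effects_sum_to_zero(self, scored_scenario):
        cfg, scored, pop, gt = scored_scenario
        design = build_design(scored, gt.zone_lookup, TrendModelSpec(n_draws=100))
        model = fit_trend_model(design)
        assert model.agesex_effects().sum() == pytest.approx(0.0, abs=1e-9)
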