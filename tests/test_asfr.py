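import numpy as np
import pandas as pd
import pytest
from scipy import stats

from grbtrends.asfr import (
    ASFRParams,
    ASFRSamplerSettings,
    age_at_half_fertility,
    asfr_curve,
    cumulative_fertility,
    derive_metrics,
    fit_asfr,
    poisson_loglik,
    total_fertility_rate,
    _metrics_from_params,
)


class TestCurve:
    def test_peak_value_is_c(self):
        p = ASFRParams(c=0.2, mu=28.0, s1=5.0, s2=9.0)
        assert asfr_curve(28.0, p) == pytest.approx(0.2)

    def test_symmetric_when_scales_equal(self):
        p = ASFRParams(c=0.15, mu=30.0, s1=6.0, s2=6.0)
        for d in (1.0, 3.0, 7.5):
            assert asfr_curve(30 - d, p) == pytest.approx(asfr_curve(30 + d, p))

    def test_direct_evaluation(self):
        p = ASFRParams(c=0.2, mu=28.0, s1=5.0, s2=9.0)
        assert asfr_curve(23.0, p) == pytest.approx(0.2 * np.exp(-1.0), abs=1e-10)

    def test_unimodal_nonnegative(self):
        p = ASFRParams(c=0.18, mu=27.0, s1=4.0, s2=8.0)
        ages = np.linspace(10, 60, 500)
        f = asfr_curve(ages, p)
        assert (f >= 0).all()
        peak = np.argmax(f)
        assert (np.diff(f[: peak + 1]) >= -1e-12).all()
        assert (np.diff(f[peak:]) <= 1e-12).all()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ASFRParams(c=-0.1, mu=28, s1=5, s2=9)
        with pytest.raises(ValueError):
            ASFRParams(c=0.1, mu=28, s1=0.0, s2=9)


class TestCumulative:
    def test_at_support_minimum_single_term(self):
        p = ASFRParams(c=0.2, mu=28.0, s1=5.0, s2=9.0)
        assert cumulative_fertility(15, p) == pytest.approx(asfr_curve(15.0, p))

    def test_zero_height_gives_zero(self):
        p = ASFRParams(c=0.0, mu=28.0, s1=5.0, s2=9.0)
        assert cumulative_fertility(np.arange(15, 50), p).max() == 0.0

    def test_below_support_is_zero(self):
        p = ASFRParams(c=0.2, mu=28.0, s1=5.0, s2=9.0)
        assert cumulative_fertility(14, p) == 0.0

    @pytest.mark.parametrize("age", [20, 30, 45])
    def test_matches_brute_force_sum(self, age):
        p = ASFRParams(c=0.17, mu=26.5, s1=4.5, s2=8.5)
        brute = sum(asfr_curve(float(a), p) for a in range(15, age + 1))
        assert cumulative_fertility(age, p) == pytest.approx(brute, abs=1e-12)

    def test_nondecreasing_in_age(self):
        p = ASFRParams(c=0.17, mu=26.5, s1=4.5, s2=8.5)
        cs = cumulative_fertility(np.arange(15, 50), p)
        assert (np.diff(cs) >= 0).all()


class TestMonotonicity:
    def test_raising_c_raises_tfr_and_not_age_at_half(self):
        base = ASFRParams(c=0.12, mu=28.0, s1=5.0, s2=9.0)
        higher = ASFRParams(c=0.20, mu=28.0, s1=5.0, s2=9.0)
        assert total_fertility_rate(higher) > total_fertility_rate(base)
        assert age_at_half_fertility(higher) <= age_at_half_fertility(base)

    def test_age_at_half_matches_fine_grid_inversion(self):
        p = ASFRParams(c=0.16, mu=27.0, s1=5.0, s2=9.0)
        a = age_at_half_fertility(p)
        # oracle: invert the piecewise-linear cumulative curve on a fine grid
        grid = np.arange(15, 50)
        cs = cumulative_fertility(grid, p)
        fine = np.linspace(15, 49, 34 * 1000 + 1)
        interp = np.interp(fine, grid, cs)
        oracle = fine[np.argmax(interp >= 0.5)]
        assert a == pytest.approx(oracle, abs=0.01)

    def test_undefined_when_tfr_below_half(self):
        p = ASFRParams(c=0.005, mu=28.0, s1=5.0, s2=9.0)
        assert np.isnan(age_at_half_fertility(p))


class TestPoissonLoglik:
    def test_matches_scipy_on_random_triples(self, rng):
        ks = rng.integers(0, 8, 20)
        mus = rng.uniform(0.05, 4.0, 20)
        ours = poisson_loglik(ks, mus)
        oracle = stats.poisson.logpmf(ks, mus)
        assert np.abs(ours - oracle).max() < 1e-10

    def test_zero_mean_boundary(self):
        assert poisson_loglik(0, 0.0) == 0.0
        assert poisson_loglik(2, 0.0) == -np.inf


def _simulate(countries, n_per_group, params_low, params_high, seed,
              jitter=None):
    rng = np.random.default_rng(seed)
    rows = []
    for c in countries:
        for grp, p in (("low", params_low), ("high", params_high)):
            if jitter is not None:
                t = np.array([np.log(p.c), p.mu, np.log(p.s1), np.log(p.s2)])
                t = t + rng.normal(0, jitter)
                p = ASFRParams(np.exp(t[0]), t[1], np.exp(t[2]), np.exp(t[3]))
            ages = rng.integers(18, 50, n_per_group)
            kids = rng.poisson(cumulative_fertility(ages, p))
            rows.append(pd.DataFrame(
                {"country": c, "age": ages, "n_children": kids, "grb_group": grp}
            ))
    return pd.concat(rows, ignore_index=True)


FAST = ASFRSamplerSettings(n_chains=2, n_warmup=500, n_samples=500)


class TestFit:
    def test_identical_groups_tfr_difference_covers_zero(self):
        p = ASFRParams(c=0.15, mu=29.0, s1=5.0, s2=9.0)
        df = _simulate(list("ABCDE"), 250, p, p, seed=4)
        fit = fit_asfr(df, FAST, seed=4)
        m = derive_metrics(fit)
        diff = m.avg_tfr[:, 0] - m.avg_tfr[:, 1]
        lo, hi = np.quantile(diff, [0.05, 0.95])
        assert lo <= 0.0 <= hi

    def test_hierarchical_shrinkage_with_homogeneous_countries(self):
        # no between-country variation in the generator: the posterior
        # between-country SD concentrates near its floor
        p = ASFRParams(c=0.15, mu=29.0, s1=5.0, s2=9.0)
        df = _simulate(list("ABCDEFGH"), 200, p, p, seed=5)
        fit = fit_asfr(df, FAST, seed=5)
        # posterior spreads concentrate well below the prior means
        # (prior mean tau: 2.0 years for mu, 0.2 for log c)
        assert fit.hyper_sd[:, :, 1].mean() < 1.5  # mu spread (years)
        assert fit.hyper_sd[:, :, 0].mean() < 0.15  # log-c spread

    def test_empty_data_rejected(self):
        df = pd.DataFrame(columns=["country", "age", "n_children", "grb_group"])
        with pytest.raises(ValueError):
            fit_asfr(df, FAST)


class TestMetrics:
    def test_dominating_curve_gives_proportion_one(self):
        # group "low" strictly dominates: higher TFR in every country and draw
        theta = np.zeros((10, 3, 2, 4))
        theta[..., 0, :] = [0.2, 28.0, 5.0, 9.0]
        theta[..., 1, :] = [0.1, 29.5, 5.0, 9.0]
        tfr, age_half = _metrics_from_params(theta, (15, 49))
        assert (tfr[:, :, 0] > tfr[:, :, 1]).all()
        assert (age_half[:, :, 0] < age_half[:, :, 1]).all()

    def test_metrics_match_scalar_oracles(self):
        p = ASFRParams(c=0.18, mu=27.0, s1=4.0, s2=8.0)
        theta = p.as_array().reshape(1, 1, 1, 4)
        tfr, age_half = _metrics_from_params(theta, (15, 49))
        assert tfr[0, 0, 0] == pytest.approx(total_fertility_rate(p), abs=1e-12)
        assert age_half[0, 0, 0] == pytest.approx(age_at_half_fertility(p), abs=1e-12)
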