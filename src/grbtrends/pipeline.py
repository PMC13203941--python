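"""End-to-end orchestration: stages, file formats, manifest, report.

Stages communicate only through serialized, schema-validated CSV files in
the run directory, so each stage can also be run on its own from the CLI.
All randomness flows from the explicit per-stage seeds in :class:`RunConfig`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import composition as comp
from . import poststrat as ps
from .asfr import ASFRSamplerSettings, derive_metrics, fit_asfr
from .lmm import build_lmm_sample, fit_hybrid_lmm, religiosity_index
from .measure import cronbach_alpha, rescale_item, score_survey, DEFAULT_ITEM_SCALES
from .schemas import validate_table
from .synthetic import ScenarioConfig, generate_scenario
from .trends import TrendModelSpec, build_design, draw_posterior, fit_trend_model

logger = logging.getLogger(__name__)

STAGES = ("simulate", "score", "trends", "poststrat", "composition", "lmm", "asfr", "report")


@dataclass
class RunConfig:
    out_dir: str = "run"
    stages: tuple = STAGES
    seed: int = 0
    n_draws: int = 2000
    scenario: ScenarioConfig = None
    trend_spec: TrendModelSpec = None
    lmm_models: tuple = (1, 2, 3)
    split_value: float | None = None  # None: realized median
    asfr_settings: ASFRSamplerSettings = None

    def __post_init__(self) -> None:
        if self.scenario is None:
            self.scenario = ScenarioConfig(seed=self.seed)
        if self.trend_spec is None:
            self.trend_spec = TrendModelSpec(n_draws=self.n_draws)
        if self.asfr_settings is None:
            self.asfr_settings = ASFRSamplerSettings()

    def stage_seed(self, stage: str) -> int:
        child = np.random.SeedSequence(self.seed).spawn(len(STAGES))
        return int(child[STAGES.index(stage)].generate_state(1)[0] % (2**31))

    def to_yaml(self, path) -> None:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            return obj

        payload = enc(self)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def _checksum(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages in dependency order; returns the run dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    from . import __version__

    manifest = {"grbtrends_version": __version__, "stages": {}, "seed": config.seed}
    t_all = time.time()

    def record(stage, files):
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t_stage, 3),
            "files": {f.name: _checksum(f) for f in files},
        }

    if "simulate" in config.stages:
        t_stage = time.time()
        scenario = dataclasses.replace(config.scenario, seed=config.stage_seed("simulate"))
        survey, pop, gt = generate_scenario(scenario)
        survey.to_csv(out / "survey.csv", index=False)
        pop.to_csv(out / "population.csv", index=False)
        gt.zone_lookup.to_csv(out / "zones.csv", index=False)
        _write_ground_truth(gt, out / "ground_truth.json")
        for name, schema in [("survey.csv", "survey"), ("population.csv", "population")]:
            v = validate_table(str(out / name), schema)
            if not v:
                raise RuntimeError(f"{name} failed validation: {v.messages}")
        record("simulate", [out / "survey.csv", out / "population.csv", out / "zones.csv"])

    if "score" in config.stages:
        t_stage = time.time()
        survey = pd.read_csv(out / "survey.csv")
        scored = score_survey(survey, add_group=True, split_value=config.split_value)
        scored["religiosity"] = religiosity_index(
            scored[["rel1", "rel2", "rel3", "rel4"]]
        )
        scored.to_csv(out / "survey_scored.csv", index=False)
        items = np.column_stack(
            [
                rescale_item(scored[f"item{j + 1}"].to_numpy(float), lo, hi)
                for j, (lo, hi) in enumerate(DEFAULT_ITEM_SCALES)
            ]
        )
        rel = cronbach_alpha(items)
        (out / "reliability.json").write_text(
            json.dumps(
                {
                    "alpha": rel.alpha,
                    "n_respondents": rel.n_respondents,
                    "item_variances": list(rel.item_variances),
                },
                indent=2,
            )
        )
        record("score", [out / "survey_scored.csv", out / "reliability.json"])

    if "trends" in config.stages:
        t_stage = time.time()
        scored = pd.read_csv(out / "survey_scored.csv")
        zones = pd.read_csv(out / "zones.csv")
        design = build_design(scored, zones, config.trend_spec)
        model = fit_trend_model(design)
        post = draw_posterior(model, seed=config.stage_seed("trends"))
        post.to_frame().to_csv(out / "trend_draws.csv", index=False)
        summary = {
            "lambdas": model.lambdas,
            "sigma2": model.sigma2,
            "converged": model.converged,
            "n_countries": len(design.countries),
            "dropped_countries": design.dropped_countries,
        }
        (out / "trend_model.json").write_text(json.dumps(summary, indent=2))
        record("trends", [out / "trend_draws.csv", out / "trend_model.json"])

    if "poststrat" in config.stages:
        t_stage = time.time()
        from .trends import TrendPosterior

        post = TrendPosterior.from_frame(pd.read_csv(out / "trend_draws.csv"))
        pop = pd.read_csv(out / "population.csv")
        lookup = pd.read_csv(out / "zones.csv")
        country_draws = ps.poststratify(post, pop)
        np.save(out / "country_draws.npy", country_draws.values)
        frames = []
        for level in ("global", "zone", "hdi", "country"):
            for unit, (vals, rep) in ps.aggregate(
                country_draws, pop, level, lookup
            ).items():
                frames.append(ps.summarize(unit, vals, country_draws.years, rep).to_frame())
        series = pd.concat(frames, ignore_index=True)
        series.to_csv(out / "poststrat_series.csv", index=False)
        eq, wt = ps.equal_vs_weighted(country_draws, pop)
        pd.DataFrame(
            {
                "year": country_draws.years,
                "equal_weight_mean": eq.mean(axis=0),
                "population_weight_mean": wt.mean(axis=0),
            }
        ).to_csv(out / "global_equal_vs_weighted.csv", index=False)
        record("poststrat", [out / "poststrat_series.csv"])

    if "composition" in config.stages:
        t_stage = time.time()
        country_draws = _load_country_draws(out)
        pop = pd.read_csv(out / "population.csv")
        cf = comp.counterfactual_series(country_draws, pop)
        pd.DataFrame(
            {
                "year": cf.years,
                "observed_mean": cf.observed.mean(axis=0),
                "counterfactual_mean": cf.counterfactual.mean(axis=0),
            }
        ).to_csv(out / "counterfactual_series.csv", index=False)
        y0, y1 = int(country_draws.years[0]), int(country_draws.years[-1])
        corr0 = comp.size_grb_correlation(country_draws, pop, y0)
        corr1 = comp.size_grb_correlation(country_draws, pop, y1)
        gm, gse = comp.grb_mean_se_from_draws(country_draws, y0)
        pop_tot = (
            pop.groupby(["country", "year"])["count"].sum().unstack("year")
            .loc[country_draws.countries]
        )
        reg = comp.growth_regression(
            gm, gse, pop_tot[y0].to_numpy(), pop_tot[y1].to_numpy(),
            seed=config.stage_seed("composition"),
        )
        results = {
            "counterfactual": cf.summary(),
            "spearman_start": {k: v for k, v in corr0.items() if k != "draws"},
            "spearman_end": {k: v for k, v in corr1.items() if k != "draws"},
            "growth_regression": reg.summary(),
        }
        (out / "composition.json").write_text(json.dumps(results, indent=2))
        reg.predicted_growth_factor(np.linspace(gm.min(), gm.max(), 25)).to_csv(
            out / "growth_prediction.csv", index=False
        )
        record("composition", [out / "composition.json"])

    if "lmm" in config.stages:
        t_stage = time.time()
        scored = pd.read_csv(out / "survey_scored.csv")
        sample = build_lmm_sample(scored)
        tables = []
        info = []
        for m in config.lmm_models:
            res = fit_hybrid_lmm(sample, model=m)
            t = res.table.copy()
            t["model"] = m
            tables.append(t)
            info.append(
                {
                    "model": m,
                    "country_intercept_sd": res.country_intercept_sd,
                    "country_slope_sd": res.country_slope_sd,
                    "residual_sd": res.residual_sd,
                    "n_obs": res.n_obs,
                    "n_countries": res.n_countries,
                    "conditional_r2": res.conditional_r2,
                    "converged": res.converged,
                }
            )
        pd.concat(tables, ignore_index=True).to_csv(out / "lmm_table.csv", index=False)
        (out / "lmm_info.json").write_text(json.dumps(info, indent=2))
        record("lmm", [out / "lmm_table.csv", out / "lmm_info.json"])

    if "asfr" in config.stages:
        t_stage = time.time()
        scored = pd.read_csv(out / "survey_scored.csv")
        sample = build_lmm_sample(scored, age_range=(18, 49))
        sample = sample.dropna(subset=["grb", "n_children"])
        # subpopulation split at the realized median of the modeling sample
        from .measure import median_split

        sample["grb_group"] = median_split(
            sample["grb"].to_numpy(), config.split_value
        )
        fit = fit_asfr(
            sample, config.asfr_settings, seed=config.stage_seed("asfr")
        )
        fit.to_frame().to_csv(out / "asfr_draws.csv", index=False)
        metrics = derive_metrics(fit)
        metrics.summary().to_csv(out / "asfr_metrics.csv", index=False)
        fit.diagnostics.to_csv(out / "asfr_diagnostics.csv", index=False)
        record("asfr", [out / "asfr_draws.csv", out / "asfr_metrics.csv"])

    if "report" in config.stages:
        t_stage = time.time()
        make_report(out)
        record("report", [out / "report.md"])

    manifest["total_seconds"] = round(time.time() - t_all, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _write_ground_truth(gt, path: Path) -> None:
    payload = {
        "countries": gt.countries,
        "years": gt.years.tolist(),
        "agesex_groups": list(gt.agesex_groups),
        "latent_trends": gt.latent_trends.tolist(),
        "agesex_effects": gt.agesex_effects.tolist(),
        "cell_expected": gt.cell_expected.tolist(),
        "growth_log_change": (
            gt.growth_log_change.tolist() if gt.growth_log_change is not None else None
        ),
        "asfr_params": (
            {k: vars(v) for k, v in gt.asfr_params.items()} if gt.asfr_params else None
        ),
        "fertility_split_value": gt.fertility_split_value,
    }
    path.write_text(json.dumps(payload))


def _load_country_draws(out: Path) -> ps.CountryDraws:
    values = np.load(out / "country_draws.npy")
    draws = pd.read_csv(out / "trend_draws.csv", usecols=["country", "year"])
    countries = sorted(draws["country"].unique())
    years = np.array(sorted(draws["year"].unique()))
    return ps.CountryDraws(values=values, countries=countries, years=years)


def make_report(run_dir) -> Path:
    """Juxtapose the headline quantities of every completed stage."""
    out = Path(run_dir)
    lines = ["# Pipeline report", ""]

    f = out / "reliability.json"
    if f.exists():
        rel = json.loads(f.read_text())
        lines += [
            f"- Composite reliability: Cronbach's alpha = {rel['alpha']:.3f} "
            f"(n = {rel['n_respondents']})"
        ]
    f = out / "poststrat_series.csv"
    if f.exists():
        s = pd.read_csv(f)
        g = s[s["unit"] == "global"].sort_values("year")
        first, last = g.iloc[0], g.iloc[-1]
        lines += [
            f"- Global population-weighted GRB: {first['mean']:.1f} "
            f"[{first['lo90']:.1f}, {first['hi90']:.1f}] in {int(first['year'])} "
            f"to {last['mean']:.1f} [{last['lo90']:.1f}, {last['hi90']:.1f}] "
            f"in {int(last['year'])}"
        ]
    f = out / "composition.json"
    if f.exists():
        c = json.loads(f.read_text())
        cf = c["counterfactual"]
        lines += [
            f"- Counterfactual {int(pd.read_csv(out / 'counterfactual_series.csv')['year'].max())} "
            f"global GRB (fixed national composition): {cf['counterfactual_end']:.1f} "
            f"vs observed {cf['observed_end']:.1f}",
            f"- Relative trend excess (posterior median): "
            f"{cf['relative_excess_median']:.0f}%",
            f"- Spearman(size, GRB): {c['spearman_start']['mean']:.2f} "
            f"[{c['spearman_start']['lo90']:.2f}, {c['spearman_start']['hi90']:.2f}] at start; "
            f"{c['spearman_end']['mean']:.2f} "
            f"[{c['spearman_end']['lo90']:.2f}, {c['spearman_end']['hi90']:.2f}] at end",
            f"- Growth regression slope: {c['growth_regression']['beta_mean']:.4f} "
            f"per GRB point "
            f"[{c['growth_regression']['beta_lo90']:.4f}, "
            f"{c['growth_regression']['beta_hi90']:.4f}]",
        ]
    f = out / "lmm_table.csv"
    if f.exists():
        t = pd.read_csv(f).fillna({"level": ""})
        m1 = t[t["model"] == 1]
        wi = m1[(m1["term"] == "GRB") & (m1["level"] == "within")].iloc[0]
        be = m1[(m1["term"] == "GRB") & (m1["level"] == "between")].iloc[0]
        lines += [
            f"- Hybrid LMM (Model 1) GRB effects: within {wi['estimate']:.3f} "
            f"(SE {wi['se']:.3f}), between {be['estimate']:.3f} (SE {be['se']:.3f})"
        ]
    f = out / "asfr_metrics.csv"
    if f.exists():
        m = pd.read_csv(f).set_index("metric")
        tfr = m.loc["tfr_diff_low_minus_high"]
        age = m.loc["age_at_half_diff_high_minus_low"]
        p1 = m.loc["prop_low_higher_tfr"]
        p2 = m.loc["prop_low_earlier"]
        lines += [
            f"- TFR difference (low - high GRB): {tfr['mean']:.2f} "
            f"[{tfr['lo90']:.2f}, {tfr['hi90']:.2f}] children",
            f"- Age at cumulative fertility 0.5, high minus low GRB: "
            f"{age['mean']:.2f} [{age['lo90']:.2f}, {age['hi90']:.2f}] years",
            f"- Countries where the low-GRB group has higher TFR: "
            f"{100 * p1['mean']:.1f}% [{100 * p1['lo90']:.1f}, {100 * p1['hi90']:.1f}]",
            f"- Countries where the low-GRB group reaches 0.5 children earlier: "
            f"{100 * p2['mean']:.1f}% [{100 * p2['lo90']:.1f}, {100 * p2['hi90']:.1f}]",
        ]
    text = "\n".join(lines) + "\n"
    (out / "report.md").write_text(text)
    return out / "report.md"
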