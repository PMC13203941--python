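"""Hierarchical smooth-trend model for mean GRB.

One Gaussian penalized-regression model estimates a smooth calendar-time
trend in mean GRB for every country, nested within cultural zones:

* a smooth trend per cultural zone (cubic B-splines, second-order
  difference penalty);
* a smooth country-level deviation from the zone trend, with one common
  smoothing parameter penalizing the wiggliness of all country curves and
  ridge penalties shrinking country-level linear and constant deviations
  toward zero (so in the infinite-penalty limit each country collapses onto
  its zone trend);
* fixed effects for the six age-sex groups (sum-to-zero), plus penalized
  country-specific deviations from them (random slopes) and country random
  intercepts.

All penalized blocks are reparametrized to identity penalties, making the
whole fit a single penalized least-squares problem.  Smoothing and variance
parameters are selected by restricted marginal likelihood (coarse log-scale
grid followed by Nelder-Mead refinement).  Uncertainty is propagated by
sampling coefficient vectors from the Gaussian approximation of the
posterior conditional on the selected smoothing parameters
(empirical Bayes), then pushing the draws through the prediction design for
every country, year and age-sex cell.

Respondent-level data are collapsed to cell sufficient statistics (mean,
count, within-cell sum of squares), which leaves the Gaussian likelihood,
the REML criterion, and the residual-variance estimate exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .splines import (
    bspline_basis,
    difference_penalty,
    reparametrize_penalty,
    sum_to_zero_contrasts,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrendModelSpec:
    basis_dim_zone: int = 8
    basis_dim_country: int = 6
    penalty_order: int = 2
    n_draws: int = 2000
    year_range: tuple[int, int] = (1995, 2022)
    min_waves: int = 2
    min_span_frac: float = 0.25

    def __post_init__(self) -> None:
        if self.basis_dim_zone < 4 or self.basis_dim_country < 4:
            raise ValueError("basis dimensions must be >= 4")
        if self.n_draws < 100:
            raise ValueError("n_draws must be >= 100")


@dataclass
class PenBlock:
    name: str
    sl: slice
    lam_key: str


@dataclass
class TrendDesign:
    """Design and penalty structure plus everything needed for prediction."""

    spec: TrendModelSpec
    cells: pd.DataFrame  # country, year, agesex, ybar, n
    X: np.ndarray
    pen_blocks: list
    n_fixed: int
    countries: list
    zones: list
    zone_of: dict
    agesex_levels: list
    sse_within: float
    n_total: int
    _zone_rep: object = None
    _ctry_rep: object = None
    _Q_zone: np.ndarray | None = None
    _Q_agesex: np.ndarray | None = None
    dropped_countries: list = field(default_factory=list)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def lam_keys(self) -> list:
        seen = []
        for b in self.pen_blocks:
            if b.lam_key not in seen:
                seen.append(b.lam_key)
        return seen

    # -- row construction ---------------------------------------------------

    def _u(self, years) -> np.ndarray:
        y0, y1 = self.spec.year_range
        return (np.asarray(years, dtype=float) - y0) / (y1 - y0)

    def build_rows(self, frame: pd.DataFrame) -> np.ndarray:
        """Design rows for any (country, year, agesex) frame."""
        y0, y1 = self.spec.year_range
        u = self._u(frame["year"].to_numpy())
        uc = u - 0.5
        n = len(frame)
        zone_idx = np.array(
            [self.zones.index(self.zone_of[c]) for c in frame["country"]]
        )
        ctry_idx = np.array([self.countries.index(c) for c in frame["country"]])
        cols = []
        # fixed: intercept
        cols.append(np.ones((n, 1)))
        # fixed: zone linear
        zl = np.zeros((n, len(self.zones)))
        zl[np.arange(n), zone_idx] = uc
        cols.append(zl)
        # fixed: zone constant contrasts
        if len(self.zones) > 1:
            zi = np.zeros((n, len(self.zones)))
            zi[np.arange(n), zone_idx] = 1.0
            cols.append(zi @ self._Q_zone)
        # fixed: age-sex contrasts
        if len(self.agesex_levels) > 1:
            ai = np.zeros((n, len(self.agesex_levels)))
            a_idx = np.array(
                [self.agesex_levels.index(a) for a in frame["agesex"]]
            )
            ai[np.arange(n), a_idx] = 1.0
            cols.append(ai @ self._Q_agesex)
        # penalized: zone wiggly smooths
        Bz = bspline_basis(u, self.spec.basis_dim_zone, 0.0, 1.0)
        Zz = Bz @ self._zone_rep.range_transform
        rz = Zz.shape[1]
        zw = np.zeros((n, len(self.zones) * rz))
        for j in range(len(self.zones)):
            mask = zone_idx == j
            zw[np.ix_(mask, np.arange(j * rz, (j + 1) * rz))] = Zz[mask]
        cols.append(zw)
        n_c = len(self.countries)
        if n_c > 1:
            # penalized: country wiggly deviations
            Bc = bspline_basis(u, self.spec.basis_dim_country, 0.0, 1.0)
            Zc = Bc @ self._ctry_rep.range_transform
            rc = Zc.shape[1]
            cw = np.zeros((n, n_c * rc))
            for j in range(n_c):
                mask = ctry_idx == j
                cw[np.ix_(mask, np.arange(j * rc, (j + 1) * rc))] = Zc[mask]
            cols.append(cw)
            # penalized: country linear deviations
            cl = np.zeros((n, n_c))
            cl[np.arange(n), ctry_idx] = uc
            cols.append(cl)
            # penalized: country random intercepts
            ci = np.zeros((n, n_c))
            ci[np.arange(n), ctry_idx] = 1.0
            cols.append(ci)
            # penalized: country age-sex deviations
            if len(self.agesex_levels) > 1:
                ca = np.zeros((n, n_c * (len(self.agesex_levels) - 1)))
                Qa = self._Q_agesex
                for j in range(n_c):
                    mask = ctry_idx == j
                    if not mask.any():
                        continue
                    a_idx = np.array(
                        [
                            self.agesex_levels.index(a)
                            for a in frame.loc[mask, "agesex"]
                        ]
                    )
                    ca[
                        np.ix_(
                            mask,
                            np.arange(
                                j * Qa.shape[1], (j + 1) * Qa.shape[1]
                            ),
                        )
                    ] = Qa[a_idx]
                cols.append(ca)
        return np.hstack(cols)

    def prediction_frame(self) -> pd.DataFrame:
        y0, y1 = self.spec.year_range
        years = np.arange(y0, y1 + 1)
        idx = pd.MultiIndex.from_product(
            [self.countries, years, self.agesex_levels],
            names=["country", "year", "agesex"],
        )
        return idx.to_frame(index=False)


def filter_survey(survey: pd.DataFrame, spec: TrendModelSpec) -> tuple[pd.DataFrame, list]:
    """Apply the inclusion rule: >= min_waves waves spanning >= min_span_frac
    of the observation period.  Returns (filtered survey, dropped countries)."""
    y0, y1 = spec.year_range
    span_req = spec.min_span_frac * (y1 - y0)
    dropped = []
    keep = []
    for country, sub in survey.groupby("country", sort=True):
        yrs = sorted(sub["year"].unique())
        if len(yrs) < spec.min_waves or (yrs[-1] - yrs[0]) < span_req:
            dropped.append(country)
        else:
            keep.append(country)
    if dropped:
        logger.warning(
            "excluding %d countries failing the inclusion rule: %s",
            len(dropped),
            dropped,
        )
    return survey[survey["country"].isin(keep)].copy(), dropped


def build_design(
    survey: pd.DataFrame,
    zones: pd.DataFrame,
    spec: TrendModelSpec | None = None,
) -> TrendDesign:
    """Aggregate the survey to cells and assemble design + penalty blocks.

    ``survey`` needs columns country, year, agesex, grb; ``zones`` maps
    country -> zone.
    """
    spec = spec or TrendModelSpec()
    survey = survey.dropna(subset=["grb"])
    survey, dropped = filter_survey(survey, spec)
    if len(survey) == 0:
        raise ValueError("no countries satisfy the inclusion rule")

    g = survey.groupby(["country", "year", "agesex"], sort=True)["grb"]
    cells = g.agg(ybar="mean", n="count").reset_index()
    sse_within = float(((survey["grb"] - g.transform("mean")) ** 2).sum())

    countries = sorted(cells["country"].unique())
    zmap = dict(zip(zones["country"], zones["zone"]))
    missing = [c for c in countries if c not in zmap]
    if missing:
        raise ValueError(f"countries missing from zone lookup: {missing}")
    zone_of = {c: zmap[c] for c in countries}
    zone_list = sorted(set(zone_of.values()))
    agesex_levels = sorted(cells["agesex"].unique())

    design = TrendDesign(
        spec=spec,
        cells=cells,
        X=None,
        pen_blocks=[],
        n_fixed=0,
        countries=countries,
        zones=zone_list,
        zone_of=zone_of,
        agesex_levels=agesex_levels,
        sse_within=sse_within,
        n_total=int(len(survey)),
        dropped_countries=dropped,
    )
    design._zone_rep = reparametrize_penalty(
        difference_penalty(spec.basis_dim_zone, spec.penalty_order),
        spec.penalty_order,
    )
    design._ctry_rep = reparametrize_penalty(
        difference_penalty(spec.basis_dim_country, spec.penalty_order),
        spec.penalty_order,
    )
    if len(zone_list) > 1:
        design._Q_zone = sum_to_zero_contrasts(len(zone_list))
    if len(agesex_levels) > 1:
        design._Q_agesex = sum_to_zero_contrasts(len(agesex_levels))

    # column layout bookkeeping
    n_fixed = 1 + len(zone_list)
    if len(zone_list) > 1:
        n_fixed += len(zone_list) - 1
    if len(agesex_levels) > 1:
        n_fixed += len(agesex_levels) - 1
    pen = []
    pos = n_fixed
    rz = spec.basis_dim_zone - spec.penalty_order
    pen.append(PenBlock("zone_smooth", slice(pos, pos + len(zone_list) * rz), "zone_smooth"))
    pos += len(zone_list) * rz
    n_c = len(countries)
    if n_c > 1:
        rc = spec.basis_dim_country - spec.penalty_order
        pen.append(PenBlock("country_smooth", slice(pos, pos + n_c * rc), "country_smooth"))
        pos += n_c * rc
        pen.append(PenBlock("country_linear", slice(pos, pos + n_c), "country_linear"))
        pos += n_c
        pen.append(PenBlock("country_intercept", slice(pos, pos + n_c), "country_intercept"))
        pos += n_c
        if len(agesex_levels) > 1:
            k = n_c * (len(agesex_levels) - 1)
            pen.append(PenBlock("country_agesex", slice(pos, pos + k), "country_agesex"))
            pos += k
    design.pen_blocks = pen
    design.n_fixed = n_fixed
    design.X = design.build_rows(cells)
    assert design.X.shape[1] == pos
    return design


def penalty_diag(design: TrendDesign, lambdas: dict) -> np.ndarray:
    d = np.zeros(design.p)
    for b in design.pen_blocks:
        d[b.sl] = lambdas[b.lam_key]
    return d


@dataclass
class FittedTrendModel:
    design: TrendDesign
    beta: np.ndarray
    chol: tuple  # cho_factor of X'WX + S
    sigma2: float
    lambdas: dict
    reml: float
    converged: bool

    def agesex_effects(self) -> pd.Series:
        """The six sum-to-zero age-sex fixed effects."""
        d = self.design
        if d._Q_agesex is None:
            raise ValueError("no age-sex variation in the design")
        start = 1 + len(d.zones) + (len(d.zones) - 1 if len(d.zones) > 1 else 0)
        k = len(d.agesex_levels) - 1
        eff = d._Q_agesex @ self.beta[start : start + k]
        return pd.Series(eff, index=d.agesex_levels)

    def predict_cells(self) -> pd.DataFrame:
        frame = self.design.prediction_frame()
        frame["fit"] = self.design.build_rows(frame) @ self.beta
        return frame


def _reml_parts(design: TrendDesign):
    W = design.cells["n"].to_numpy(dtype=float)
    y = design.cells["ybar"].to_numpy(dtype=float)
    X = design.X
    XtWX = (X * W[:, None]).T @ X
    XtWy = X.T @ (W * y)
    yty = float(np.sum(W * y * y)) + design.sse_within
    return XtWX, XtWy, yty


def reml_criterion(design: TrendDesign, loglam: np.ndarray, parts=None) -> float:
    """-2 * restricted log-likelihood (up to a constant) at log-lambdas."""
    XtWX, XtWy, yty = parts or _reml_parts(design)
    keys = design.lam_keys()
    lambdas = {k: float(np.exp(v)) for k, v in zip(keys, loglam)}
    d = penalty_diag(design, lambdas)
    A = XtWX + np.diag(d)
    try:
        c, low = cho_factor(A, lower=True)
    except np.linalg.LinAlgError:
        return np.inf
    beta = cho_solve((c, low), XtWy)
    P = yty - float(beta @ XtWy)
    P = max(P, 1e-12)
    nf = design.n_total - design.n_fixed
    logdet_A = 2.0 * float(np.sum(np.log(np.diag(c))))
    logdet_S = sum(
        (b.sl.stop - b.sl.start) * np.log(lambdas[b.lam_key])
        for b in design.pen_blocks
    )
    return nf * np.log(P / nf) + logdet_A - logdet_S


def fit_trend_model(
    design: TrendDesign,
    lambdas: dict | None = None,
) -> FittedTrendModel:
    """Penalized Gaussian fit with REML-selected smoothing parameters.

    Passing ``lambdas`` explicitly skips smoothing-parameter selection
    (used for limit checks and fast refits).
    """
    parts = _reml_parts(design)
    XtWX, XtWy, yty = parts
    keys = design.lam_keys()
    converged = True
    if lambdas is None:
        x0 = np.zeros(len(keys))
        # coordinate-wise coarse grid, two sweeps
        grid = np.array([-6.0, -3.0, 0.0, 3.0, 6.0, 9.0])
        best = reml_criterion(design, x0, parts)
        for _ in range(2):
            for j in range(len(keys)):
                vals = []
                for g in grid:
                    x = x0.copy()
                    x[j] = g
                    vals.append(reml_criterion(design, x, parts))
                jbest = int(np.argmin(vals))
                if vals[jbest] < best:
                    best = vals[jbest]
                    x0[j] = grid[jbest]
        res = minimize(
            lambda x: reml_criterion(design, x, parts),
            x0,
            method="Nelder-Mead",
            options={"xatol": 0.05, "fatol": 1e-4, "maxfev": 120 * len(keys)},
        )
        if not res.success and res.fun > best + 1e-6:
            logger.warning("REML refinement did not converge: %s", res.message)
            converged = False
            res_x = x0
            res_fun = best
        else:
            res_x, res_fun = res.x, res.fun
        lambdas = {k: float(np.exp(v)) for k, v in zip(keys, res_x)}
        reml_val = float(res_fun)
    else:
        loglam = np.array([np.log(lambdas[k]) for k in keys])
        reml_val = float(reml_criterion(design, loglam, parts))

    d = penalty_diag(design, lambdas)
    A = XtWX + np.diag(d)
    c, low = cho_factor(A, lower=True)
    beta = cho_solve((c, low), XtWy)
    P = yty - float(beta @ XtWy)
    sigma2 = max(P, 0.0) / (design.n_total - design.n_fixed)
    return FittedTrendModel(
        design=design,
        beta=beta,
        chol=(c, low),
        sigma2=float(sigma2),
        lambdas=lambdas,
        reml=reml_val,
        converged=converged,
    )


@dataclass
class TrendPosterior:
    """Draws of predicted cell means for every country, year, age-sex cell."""

    values: np.ndarray  # (n_draws, n_countries, n_years, n_groups)
    countries: list
    years: np.ndarray
    agesex: list

    @property
    def n_draws(self) -> int:
        return self.values.shape[0]

    def mean(self) -> np.ndarray:
        return self.values.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        n_d, n_c, n_y, n_g = self.values.shape
        idx = pd.MultiIndex.from_product(
            [range(n_d), self.countries, self.years, self.agesex],
            names=["draw", "country", "year", "agesex"],
        )
        return pd.DataFrame(
            {"value": self.values.reshape(-1)}, index=idx
        ).reset_index()

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrendPosterior":
        countries = sorted(df["country"].unique())
        years = np.array(sorted(df["year"].unique()))
        agesex = sorted(df["agesex"].unique())
        n_d = df["draw"].nunique()
        pivot = df.sort_values(["draw", "country", "year", "agesex"])
        values = pivot["value"].to_numpy().reshape(
            n_d, len(countries), len(years), len(agesex)
        )
        return cls(values=values, countries=countries, years=years, agesex=agesex)


def _loglambda_covariance(design: TrendDesign, model: FittedTrendModel, parts) -> np.ndarray:
    """Normal approximation to the uncertainty of the log smoothing
    parameters: inverse Hessian of the restricted negative log-likelihood at
    the REML optimum (central finite differences)."""
    keys = design.lam_keys()
    rho = np.log([model.lambdas[k] for k in keys])
    d = len(keys)
    h = 0.3
    f0 = reml_criterion(design, rho, parts)
    fp = np.empty(d)
    fm = np.empty(d)
    H = np.zeros((d, d))
    for i in range(d):
        e = np.zeros(d)
        e[i] = h
        fp[i] = reml_criterion(design, rho + e, parts)
        fm[i] = reml_criterion(design, rho - e, parts)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h**2
    for i in range(d):
        for j in range(i + 1, d):
            e = np.zeros(d)
            e[i] = h
            e[j] = h
            fpp = reml_criterion(design, rho + e, parts)
            fmm = reml_criterion(design, rho - e, parts)
            H[i, j] = H[j, i] = (
                fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm
            ) / (2 * h**2)
    H *= 0.5  # criterion is -2 * restricted log-likelihood
    w, V = np.linalg.eigh(H)
    # flat directions (lambda effectively at a boundary) get a wide but
    # bounded spread rather than an unbounded one
    w = np.maximum(w, 0.05)
    return (V / w) @ V.T


def draw_posterior(
    model: FittedTrendModel,
    n_draws: int | None = None,
    seed: int | np.random.Generator = 0,
    lambda_uncertainty: bool = True,
    n_lambda: int = 25,
) -> TrendPosterior:
    """Sample coefficients from the Gaussian posterior approximation and push
    them through the prediction design for all countries x years x cells.

    With ``lambda_uncertainty`` (default) the draws also propagate the
    uncertainty of the REML-selected log smoothing parameters: draws are
    generated under ``n_lambda`` smoothing-parameter vectors sampled from the
    normal approximation around the optimum, refitting the penalized
    coefficients for each.  Without it, draws condition on the selected
    smoothing parameters (pure empirical Bayes).
    """
    from scipy.linalg import solve_triangular

    design = model.design
    n_draws = n_draws or design.spec.n_draws
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    frame = design.prediction_frame()
    Xp = design.build_rows(frame)
    p = design.p

    if not lambda_uncertainty or model.sigma2 == 0.0:
        c, low = model.chol
        z = rng.standard_normal((p, n_draws))
        # A = L L'; cov = sigma2 * A^-1 => draws = beta + sigma * L^-T z
        L = np.tril(c) if low else np.triu(c).T
        delta = solve_triangular(L.T, z, lower=False) * np.sqrt(model.sigma2)
        vals = Xp @ (model.beta[:, None] + delta)
    else:
        parts = _reml_parts(design)
        XtWX, XtWy, yty = parts
        keys = design.lam_keys()
        rho_hat = np.log([model.lambdas[k] for k in keys])
        cov_rho = _loglambda_covariance(design, model, parts)
        Lr = np.linalg.cholesky(cov_rho)
        nf = design.n_total - design.n_fixed
        counts = np.full(n_lambda, n_draws // n_lambda)
        counts[: n_draws % n_lambda] += 1
        chunks = []
        for k in range(n_lambda):
            step = np.clip(Lr @ rng.standard_normal(len(keys)), -6.0, 6.0)
            lams = {key: float(np.exp(v)) for key, v in zip(keys, rho_hat + step)}
            A = XtWX + np.diag(penalty_diag(design, lams))
            c, low = cho_factor(A, lower=True)
            beta = cho_solve((c, low), XtWy)
            sig2 = max(yty - float(beta @ XtWy), 1e-12) / nf
            L = np.tril(c)
            z = rng.standard_normal((p, counts[k]))
            betas = beta[:, None] + solve_triangular(L.T, z, lower=False) * np.sqrt(sig2)
            chunks.append(Xp @ betas)
        vals = np.hstack(chunks)

    n_c = len(design.countries)
    n_y = design.spec.year_range[1] - design.spec.year_range[0] + 1
    n_g = len(design.agesex_levels)
    values = vals.T.reshape(n_draws, n_c, n_y, n_g)
    years = np.arange(design.spec.year_range[0], design.spec.year_range[1] + 1)
    return TrendPosterior(
        values=values,
        countries=design.countries,
        years=years,
        agesex=design.agesex_levels,
    )


def surveyed_year_mask(design: TrendDesign) -> pd.DataFrame:
    """(country, year) pairs with survey data, for uncertainty comparisons."""
    return design.cells[["country", "year"]].drop_duplicates()
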