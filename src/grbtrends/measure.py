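"""Composite gender-role-belief (GRB) scoring.

A respondent's GRB score is the arithmetic mean of up to three ordinal survey
items on women's equal role in work, university education, and political
leadership, after each item is linearly rescaled to 0-100.  Higher scores
indicate more egalitarian beliefs.  The module also provides Cronbach's alpha
for the three-item composite and the median split used by the fertility
models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

#: default ordinal response scales (min, max) for the three items
DEFAULT_ITEM_SCALES: tuple[tuple[int, int], ...] = ((1, 2), (1, 3), (1, 4))

ITEM_COLUMNS = ("item1", "item2", "item3")


@dataclass(frozen=True)
class ReliabilityReport:
    """Cronbach's alpha and the ingredients that went into it."""

    alpha: float
    n_respondents: int
    item_variances: tuple[float, ...]
    total_variance: float

    def __post_init__(self) -> None:
        if np.isfinite(self.alpha) and self.alpha > 1.0 + 1e-12:
            raise ValueError("alpha cannot exceed 1")


def rescale_item(raw, scale_min: float, scale_max: float):
    """Linearly map an ordinal response onto 0-100.

    ``scale_min`` maps to 0 and ``scale_max`` to 100.  Missing values (NaN)
    propagate; out-of-range values raise.
    """
    if scale_max <= scale_min:
        raise ValueError("scale_max must exceed scale_min")
    arr = np.asarray(raw, dtype=float)
    valid = ~np.isnan(arr)
    if np.any((arr[valid] < scale_min) | (arr[valid] > scale_max)):
        raise ValueError(
            f"response outside [{scale_min}, {scale_max}] encountered"
        )
    out = (arr - scale_min) / (scale_max - scale_min) * 100.0
    if np.isscalar(raw):
        return float(out)
    return out


def composite_grb(items, min_items: int = 2):
    """Arithmetic mean of the available rescaled items (0-100 each).

    Rows with fewer than ``min_items`` non-missing items get NaN.  Input is a
    2-D array-like of already rescaled values, one row per respondent.
    """
    arr = np.atleast_2d(np.asarray(items, dtype=float))
    if arr.shape[1] < 1:
        raise ValueError("at least one item column required")
    n_ok = np.sum(~np.isnan(arr), axis=1)
    with np.errstate(invalid="ignore"):
        means = np.nanmean(np.where(np.isnan(arr), np.nan, arr), axis=1)
    means = np.where(n_ok >= max(min_items, 1), means, np.nan)
    return means


def cronbach_alpha(item_matrix) -> ReliabilityReport:
    """Cronbach's alpha on listwise-complete rows.

    alpha = k/(k-1) * (1 - sum of item variances / variance of row sums),
    with sample (ddof=1) variances.
    """
    arr = np.asarray(item_matrix, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >=2 items")
    complete = ~np.isnan(arr).any(axis=1)
    arr = arr[complete]
    n, k = arr.shape
    if n < 3:
        raise ValueError("need at least 3 complete rows")
    item_var = arr.var(axis=0, ddof=1)
    total_var = arr.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("zero variance of the total score; alpha undefined")
    alpha = k / (k - 1) * (1.0 - item_var.sum() / total_var)
    return ReliabilityReport(
        alpha=float(alpha),
        n_respondents=int(n),
        item_variances=tuple(float(v) for v in item_var),
        total_variance=float(total_var),
    )


def median_split(scores, split_value: float | None = None) -> np.ndarray:
    """Label each score "low" (score <= split) or "high" (score > split).

    Ties go to "low": respondents at or below the split form the less
    egalitarian group.  The default split is the realized sample median of
    the non-missing scores.
    """
    arr = np.asarray(scores, dtype=float)
    if split_value is None:
        split_value = float(np.nanmedian(arr))
    if not 0.0 <= split_value <= 100.0:
        raise ValueError("split_value must lie in [0, 100]")
    labels = np.where(arr <= split_value, "low", "high").astype(object)
    labels[np.isnan(arr)] = None
    return labels


def score_survey(
    survey: pd.DataFrame,
    item_scales: Sequence[tuple[int, int]] = DEFAULT_ITEM_SCALES,
    min_items: int = 2,
    add_group: bool = False,
    split_value: float | None = None,
) -> pd.DataFrame:
    """Attach a ``grb`` column (and optionally ``grb_group``) to a survey table."""
    rescaled = np.column_stack(
        [
            rescale_item(survey[col].to_numpy(dtype=float), lo, hi)
            for col, (lo, hi) in zip(ITEM_COLUMNS, item_scales)
        ]
    )
    out = survey.copy()
    out["grb"] = composite_grb(rescaled, min_items=min_items)
    if add_group:
        out["grb_group"] = median_split(out["grb"].to_numpy(), split_value)
    return out
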