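"""Lightweight schema validation for the pipeline's tabular interchange files."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ValidationResult:
    ok: bool
    messages: list = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.ok


def _check_range(df, col, lo, hi, messages):
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[(vals < lo) | (vals > hi)]
    for i in list(bad[:5]):
        messages.append(f"row {i}: {col}={df.loc[i, col]!r} outside [{lo}, {hi}]")
    return len(bad) == 0


SCHEMAS = {
    "survey": {
        "required": ["country", "year", "age", "sex", "item1", "item2", "item3"],
        "ranges": {"age": (18, 120), "year": (1900, 2100)},
        "key": None,
    },
    "population": {
        "required": ["country", "year", "agesex", "count"],
        "ranges": {"count": (0, np.inf)},
        "key": ["country", "year", "agesex"],
    },
    "draws": {
        "required": ["draw", "country", "year", "agesex", "value"],
        "ranges": {},
        "key": ["draw", "country", "year", "agesex"],
    },
    "series": {
        "required": ["unit", "year", "mean", "lo90", "hi90"],
        "ranges": {},
        "key": ["unit", "year"],
    },
    "lmm_table": {
        "required": ["term", "level", "estimate", "se", "p", "model"],
        "ranges": {"p": (0, 1), "se": (0, np.inf)},
        "key": None,
    },
    "asfr_draws": {
        "required": ["draw", "country", "group", "c", "mu", "s1", "s2"],
        "ranges": {"c": (0, np.inf), "s1": (0, np.inf), "s2": (0, np.inf)},
        "key": ["draw", "country", "group"],
    },
}


def validate_table(table, schema_name: str) -> ValidationResult:
    """Column, range and key-uniqueness checks against a registered schema."""
    if schema_name not in SCHEMAS:
        raise ValueError(f"unknown schema {schema_name!r}")
    schema = SCHEMAS[schema_name]
    df = pd.read_csv(table) if isinstance(table, str) else table
    messages: list = []
    ok = True
    for col in schema["required"]:
        if col not in df.columns:
            messages.append(f"missing required column {col!r}")
            ok = False
    if not ok:
        return ValidationResult(False, messages)
    for col, (lo, hi) in schema["ranges"].items():
        if not _check_range(df, col, lo, hi, messages):
            ok = False
    if schema_name == "survey" and "grb" in df.columns:
        if not _check_range(df, "grb", 0, 100, messages):
            ok = False
    key = schema["key"]
    if key:
        dup = df.duplicated(subset=key)
        if dup.any():
            first = df[dup].iloc[0]
            messages.append(
                f"duplicated key {tuple(first[k] for k in key)} in columns {key}"
            )
            ok = False
    return ValidationResult(ok, messages)
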