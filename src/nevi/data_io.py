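"""Reading tract feature tables, applying exclusion filters, writing scores.

A *feature table* is a :class:`pandas.DataFrame` indexed by census-tract
GEOID (an opaque string; leading zeros preserved) with a ``borough`` stratum
column, an integer ``population`` column, and one float column per registry
feature. Missing values are real NaN, never sentinel numbers.

Tract exclusion mirrors the study design: tracts with population below a
threshold (default 20) are dropped first, then tracts with at least one
missing feature value, so a tiny tract that also has gaps is logged under
the population reason.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import IntegrityError, SchemaError
from .registry import Registry

__all__ = [
    "ExclusionLog",
    "read_feature_table",
    "apply_tract_filters",
    "write_scores",
    "read_scores",
]

REASON_LOW_POPULATION = "low_population"
REASON_MISSING_FEATURE = "missing_feature"


@dataclass
class ExclusionLog:
    """Record of which tracts a filtering pass removed and why."""

    n_input: int
    n_retained: int
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (geoid, reason)

    @property
    def counts(self) -> dict[str, int]:
        out = {REASON_LOW_POPULATION: 0, REASON_MISSING_FEATURE: 0}
        for _, reason in self.excluded:
            out[reason] += 1
        return out

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_excluded": self.n_excluded,
            "counts": self.counts,
            "excluded": [{"geoid": g, "reason": r} for g, r in self.excluded],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")


def read_feature_table(path: str | Path, registry: Registry) -> pd.DataFrame:
    """Read a tract-by-feature CSV and validate it against the registry.

    The file must have ``geoid``, ``borough`` and ``population`` columns plus
    one column per registry feature; extra columns are dropped. Empty cells
    become NaN.

    Raises
    ------
    SchemaError
        If a required column is absent (the message names it).
    IntegrityError
        If a GEOID appears more than once.
    """
    df = pd.read_csv(path, dtype={"geoid": str, "borough": str})
    for col in ("geoid", "borough", "population"):
        if col not in df.columns:
            raise SchemaError(f"input table is missing required column {col!r}")
    missing = [f for f in registry.feature_ids if f not in df.columns]
    if missing:
        raise SchemaError(f"input table is missing feature column(s) {missing}")
    if df["geoid"].duplicated().any():
        dups = df.loc[df["geoid"].duplicated(), "geoid"].tolist()
        raise IntegrityError(f"duplicate geoid(s): {dups}")

    df = df.set_index("geoid")
    table = df[["borough", "population"]].copy()
    table["population"] = pd.to_numeric(df["population"], errors="coerce").astype("Int64")
    for f in registry.feature_ids:
        table[f] = pd.to_numeric(df[f], errors="coerce")
    return table


def apply_tract_filters(
    table: pd.DataFrame, min_population: int = 20
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the study's exclusion filters; return (retained table, log).

    Removes tracts with ``population < min_population`` first, then tracts
    with any missing feature value among the remainder. The retained table
    has no missing values. Idempotent.
    """
    feature_cols = [c for c in table.columns if c not in ("borough", "population")]
    log = ExclusionLog(n_input=len(table), n_retained=0)

    pop = table["population"].fillna(-1)
    low = pop < min_population
    for geoid in table.index[low]:
        log.excluded.append((geoid, REASON_LOW_POPULATION))
    remaining = table.loc[~low]

    has_missing = remaining[feature_cols].isna().any(axis=1)
    for geoid in remaining.index[has_missing]:
        log.excluded.append((geoid, REASON_MISSING_FEATURE))

    retained = remaining.loc[~has_missing].copy()
    log.n_retained = len(retained)
    return retained, log


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    """Write a score table to CSV, geoid first, for external joining to shapefiles."""
    out = scores.copy()
    out.index.name = "geoid"
    out.to_csv(path, float_format="%.17g")


def read_scores(path: str | Path) -> pd.DataFrame:
    """Read back a CSV written by :func:`write_scores` (round-trips values)."""
    return pd.read_csv(path, dtype={"geoid": str}).set_index("geoid")
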