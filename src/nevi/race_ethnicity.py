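"""Sensitivity analyses around racial and ethnic composition.

The primary index deliberately excludes racial/ethnic identity composition,
treating socioeconomic, residential and health features as downstream
proxies of structural racism instead. Two descriptive checks are provided:

* scoring with the augmented registry (see
  :func:`nevi.registry.build_sensitivity_registry`), which is just the
  ordinary pipeline on the 58-feature variant; and
* summaries of vulnerability by "high composition" neighborhoods — tracts
  whose proportion of a group strictly exceeds the citywide median
  proportion for that group. A tract can be high-composition for several
  groups at once. These are descriptive medians only; no causal machinery.
"""

from __future__ import annotations

import pandas as pd

from .errors import InsufficientDataError

__all__ = ["high_composition_flags", "summarize_scores_by_group"]


def high_composition_flags(comp: pd.DataFrame) -> pd.DataFrame:
    """Boolean tract-by-group flags: proportion strictly above the citywide median.

    The median is computed over the tracts present in ``comp`` (i.e. the
    retained tracts). Strict inequality means a tract exactly at the median
    is not flagged; flags depend only on ranks, so any strictly increasing
    transform of a group's proportions leaves them unchanged.
    """
    if len(comp) < 1:
        raise InsufficientDataError("composition table is empty")
    return comp.gt(comp.median(axis=0), axis=1)


def summarize_scores_by_group(
    flags: pd.DataFrame, scores: pd.DataFrame, domain_ids: list[str] | None = None
) -> pd.DataFrame:
    """Median overall and domain scores over each group's high-composition tracts.

    Returns a DataFrame indexed by group with columns ``n_high``,
    ``median_overall`` and ``median_<domain>``. A group with no flagged
    tracts gets NaN medians (summary unavailable) rather than an error.
    """
    common = flags.index.intersection(scores.index)
    flags = flags.loc[common]
    scores = scores.loc[common]
    if domain_ids is None:
        domain_ids = [c for c in scores.columns if c != "overall" and not c.startswith("_")
                      and c in ("demographics", "economic", "residential", "health_status")]

    rows = {}
    for group in flags.columns:
        sel = scores.loc[flags[group]]
        row = {"n_high": int(flags[group].sum())}
        if len(sel):
            row["median_overall"] = float(sel["overall"].median())
            for d in domain_ids:
                row[f"median_{d}"] = float(sel[d].median())
        else:
            row["median_overall"] = float("nan")
            for d in domain_ids:
                row[f"median_{d}"] = float("nan")
        rows[group] = row
    out = pd.DataFrame(rows).T
    out.index.name = "group"
    out["n_high"] = out["n_high"].astype(int)
    return out
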