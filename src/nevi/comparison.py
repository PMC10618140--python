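"""Index comparison: adapted Neighborhood Deprivation Index, rank correlations, quartiles.

The Neighborhood Deprivation Index (NDI) here follows the Messer-style
construction: z-score a set of socioeconomic deprivation variables, take
the first principal component of their correlation matrix, and use the
standardized component scores as the deprivation index (higher = more
deprived). An optional grouping performs the extraction separately within
spatial strata (e.g. boroughs), which lets the component reflect
within-stratum heterogeneity. The variable list is configurable;
:func:`default_ndi_variables` supplies a deprivation set drawn from the
registry's economic features plus female-led households and household
crowding. Because the exact adaptation used alongside any particular study
may differ (variable list, stratification), treat this construction as an
approximation to be configured, not a fixed reference implementation.

The first component's sign is arbitrary, so it is anchored: the loading on
a designated deprivation variable (default ``pct_below_poverty``) is forced
positive, making larger NDI mean more deprivation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InsufficientDataError
from .registry import Registry

__all__ = [
    "NDIResult",
    "IndexComparison",
    "default_ndi_variables",
    "compute_ndi",
    "spearman_compare",
    "quartile_classify",
    "read_external_index",
]

_OVERALL = "overall"


def default_ndi_variables(registry: Registry) -> list[str]:
    """Deprivation variable list: all economic features + female-led households + crowding."""
    econ = [f.feature_id for f in registry.features if f.domain_id == "economic"]
    return econ + ["pct_female_led", "pct_crowded_households"]


@dataclass
class NDIResult:
    """Per-tract NDI scores with per-stratum loadings and variance explained."""

    scores: pd.Series  # indexed by geoid; mean 0, sd 1 within each stratum
    loadings: pd.DataFrame  # variables x strata
    variance_explained: dict[str, float]  # stratum -> fraction in (0, 1]
    strata: pd.Series | None = None  # geoid -> stratum label (None = single stratum)


def _first_component(z: np.ndarray) -> tuple[np.ndarray, float]:
    """First PC of the correlation matrix of already-z-scored columns."""
    corr = np.corrcoef(z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    # eigh returns ascending order; take the largest
    v = eigvecs[:, -1]
    return v, float(eigvals[-1] / eigvals.sum())


def compute_ndi(
    table: pd.DataFrame,
    variable_ids: list[str] | None = None,
    strata: pd.Series | None = None,
    anchor: str = "pct_below_poverty",
    registry: Registry | None = None,
) -> NDIResult:
    """First-principal-component deprivation index, optionally within strata.

    Parameters
    ----------
    table
        Filtered feature table (no missing values) indexed by geoid.
    variable_ids
        Deprivation variables to use; defaults to
        :func:`default_ndi_variables` (requires ``registry``).
    strata
        Optional geoid-aligned labels; the PCA and standardization are done
        separately per stratum. Each stratum needs more tracts than variables.
    anchor
        Variable whose loading is forced positive so larger NDI = more deprived.
    """
    if variable_ids is None:
        if registry is None:
            raise ValueError("pass variable_ids or a registry for the default list")
        variable_ids = default_ndi_variables(registry)
    if anchor not in variable_ids:
        raise ValueError(f"anchor {anchor!r} is not among the NDI variables")

    x = table[variable_ids].astype(float)
    if strata is None:
        groups = pd.Series("all", index=x.index)
    else:
        groups = strata.reindex(x.index)

    scores = pd.Series(np.nan, index=x.index, name="ndi")
    loadings = {}
    varexp = {}
    for label, idx in x.groupby(groups).groups.items():
        xg = x.loc[idx]
        if len(xg) < len(variable_ids) + 1:
            raise InsufficientDataError(
                f"stratum {label!r} has {len(xg)} tracts for {len(variable_ids)} variables"
            )
        sd = xg.std(axis=0, ddof=1)
        constant = sd[sd == 0].index.tolist()
        if constant:
            raise DegenerateInputError(
                f"variable(s) {constant} are constant within stratum {label!r}"
            )
        z = ((xg - xg.mean(axis=0)) / sd).to_numpy()
        v, ve = _first_component(z)
        if v[variable_ids.index(anchor)] < 0:
            v = -v
        raw = z @ v
        raw = (raw - raw.mean()) / raw.std(ddof=1)
        scores.loc[idx] = raw
        loadings[label] = v
        varexp[str(label)] = ve

    return NDIResult(
        scores=scores,
        loadings=pd.DataFrame(loadings, index=variable_ids),
        variance_explained=varexp,
        strata=None if strata is None else groups,
    )


@dataclass
class IndexComparison:
    """Spearman correlations between two indices, overall and per group."""

    name_a: str
    name_b: str
    rho: pd.DataFrame = field(default_factory=pd.DataFrame)  # columns: group, rho, n

    def overall_rho(self) -> float:
        return float(self.rho.loc[self.rho["group"] == _OVERALL, "rho"].iloc[0])


def spearman_compare(
    a: pd.Series,
    b: pd.Series,
    groups: pd.Series | None = None,
    name_a: str = "a",
    name_b: str = "b",
) -> IndexComparison:
    """Spearman rank correlation (average ranks for ties), overall and per group.

    ``a`` and ``b`` are aligned on their index (geoid); groups with fewer
    than 3 aligned tracts raise :class:`InsufficientDataError`.
    """
    common = a.index.intersection(b.index)
    if len(common) < 3:
        raise InsufficientDataError(f"only {len(common)} aligned tracts; need at least 3")
    av, bv = a.loc[common].astype(float), b.loc[common].astype(float)

    rows = [{"group": _OVERALL, "rho": float(stats.spearmanr(av, bv).statistic), "n": len(common)}]
    if groups is not None:
        g = groups.reindex(common)
        for label, idx in av.groupby(g).groups.items():
            if len(idx) < 3:
                raise InsufficientDataError(f"group {label!r} has {len(idx)} tracts; need >= 3")
            rows.append(
                {
                    "group": str(label),
                    "rho": float(stats.spearmanr(av.loc[idx], bv.loc[idx]).statistic),
                    "n": len(idx),
                }
            )
    return IndexComparison(name_a=name_a, name_b=name_b, rho=pd.DataFrame(rows))


def quartile_classify(scores: pd.Series) -> pd.Series:
    """Empirical quartile label 1-4 per tract; tied values share a quartile.

    Uses minimum ranks so a tie group is classified as a block; a totally
    tied input yields label 1 everywhere. Labels depend only on ranks, so
    any strictly increasing transform of the scores leaves them unchanged.
    """
    if len(scores) < 4:
        raise InsufficientDataError(f"quartiles need at least 4 tracts, got {len(scores)}")
    n = len(scores)
    ranks = stats.rankdata(scores.to_numpy(), method="min").astype(int)
    labels = (ranks - 1) * 4 // n + 1
    return pd.Series(labels, index=scores.index, name="quartile")


def read_external_index(path: str | Path, score_col: str, geoid_col: str = "geoid") -> pd.Series:
    """Read a precomputed external index (e.g. SVI/EJI/DAC) as a geoid-keyed series."""
    df = pd.read_csv(path, dtype={geoid_col: str})
    return df.set_index(geoid_col)[score_col].astype(float)
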