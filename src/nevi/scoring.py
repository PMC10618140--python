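"""The ToxPi-style NEVI computation.

Pipeline, per the index construction:

1. z-score each feature across tracts (sample sd, denominator n-1);
2. negate inverse-coded features so larger always means more vulnerable;
3. re-center each feature so its minimum is zero (ToxPi treats negative
   values as invalid, and shifting preserves the distribution's shape);
4. sum features within each subdomain, then min-max transform the sums to
   [0, 1] across tracts (subtract the minimum, divide by the range);
5. overall score = weight-sum of subdomain scores (weights from the
   registry, summing to 1); domain scores = unweighted means of each
   domain's subdomain scores.

Because domains are equally weighted, the overall score equals the mean of
the domain scores — an algebraic identity the test suite asserts.

Degenerate columns are defined to zero: a zero-variance feature has z = 0
everywhere, and a zero-range subdomain sum scores 0 for every tract, which
keeps all scores inside [0, 1].
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, RegistryError
from .registry import Registry

__all__ = [
    "standardize_features",
    "score_subdomains",
    "score_domains",
    "score_overall",
    "run_nevi_pipeline",
]


def standardize_features(table: pd.DataFrame, registry: Registry) -> pd.DataFrame:
    """Direction-aligned, re-centered z-scores (tracts x features, min 0 per column).

    ``table`` must already have passed the exclusion filters (no missing
    feature values) and contain at least two tracts.
    """
    if len(table) < 2:
        raise InsufficientDataError(
            f"standardization needs at least 2 tracts, got {len(table)}"
        )
    x = table[registry.feature_ids].astype(float)
    if x.isna().any().any():
        raise InsufficientDataError("feature table still contains missing values; filter first")

    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    z = (x - mean).divide(sd.where(sd > 0, np.inf), axis=1)  # zero-variance -> 0

    directions = registry.directions()
    signs = pd.Series({f: -1.0 if directions[f] == "inverse" else 1.0 for f in x.columns})
    z = z.multiply(signs, axis=1)
    return z - z.min(axis=0)


def score_subdomains(std: pd.DataFrame, registry: Registry) -> pd.DataFrame:
    """Min-max transformed within-subdomain feature sums (tracts x subdomains, in [0,1])."""
    out = {}
    for sub in registry.subdomains:
        total = std[list(sub.feature_ids)].sum(axis=1)
        rng = total.max() - total.min()
        if rng > 0:
            out[sub.subdomain_id] = (total - total.min()) / rng
        else:
            out[sub.subdomain_id] = pd.Series(0.0, index=std.index)
    return pd.DataFrame(out, index=std.index)


def score_overall(sub: pd.DataFrame, registry: Registry) -> pd.Series:
    """Weighted sum of subdomain scores; weights sum to 1 so the result is in [0,1]."""
    if set(sub.columns) != set(registry.subdomain_ids):
        raise RegistryError("subdomain score columns do not match the registry")
    weights = pd.Series({s: float(w) for s, w in registry.weights().items()})
    return (sub * weights).sum(axis=1).rename("overall")


def score_domains(sub: pd.DataFrame, registry: Registry) -> pd.DataFrame:
    """Unweighted mean of each domain's subdomain scores (tracts x domains)."""
    return pd.DataFrame(
        {d.domain_id: sub[list(d.subdomain_ids)].mean(axis=1) for d in registry.domains},
        index=sub.index,
    )


def run_nevi_pipeline(table: pd.DataFrame, registry: Registry) -> pd.DataFrame:
    """Full scoring pipeline on a filtered feature table.

    Returns a score table indexed by geoid with columns ``overall``, one per
    domain, and one per subdomain — 1 + 4 + 24 = 29 columns for the default
    registry. Deterministic for a fixed input; tract row order is immaterial.
    """
    std = standardize_features(table, registry)
    sub = score_subdomains(std, registry)
    domains = score_domains(sub, registry)
    overall = score_overall(sub, registry)
    return pd.concat([overall, domains, sub], axis=1)
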