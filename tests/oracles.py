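"""Independent brute-force oracles used to cross-check the library.

These are deliberately naive pure-Python transcriptions of the arithmetic
(loops, no pandas/scipy vectorization, no calls into nevi.scoring or
nevi.clustering), so agreement with the package is a two-route check.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def naive_scores(table: pd.DataFrame, registry) -> pd.DataFrame:
    """Loop-based transcription of the scoring arithmetic.

    z-score each feature (sample sd), negate inverse features, shift each
    column min to zero, sum within subdomains, min-max each subdomain,
    weight-sum to the overall score, average subdomains per domain.
    """
    geoids = list(table.index)
    n = len(geoids)

    std: dict[str, list[float]] = {}
    for feat in registry.features:
        vals = [float(table.loc[g, feat.feature_id]) for g in geoids]
        mean = sum(vals) / n
        var = sum((v - mean) ** 2 for v in vals) / (n - 1)
        sd = math.sqrt(var)
        z = [(v - mean) / sd if sd > 0 else 0.0 for v in vals]
        if feat.direction == "inverse":
            z = [-v for v in z]
        lo = min(z)
        std[feat.feature_id] = [v - lo for v in z]

    sub: dict[str, list[float]] = {}
    for s in registry.subdomains:
        sums = [sum(std[fid][i] for fid in s.feature_ids) for i in range(n)]
        lo, hi = min(sums), max(sums)
        if hi > lo:
            sub[s.subdomain_id] = [(v - lo) / (hi - lo) for v in sums]
        else:
            sub[s.subdomain_id] = [0.0] * n

    out = {}
    out["overall"] = [
        sum(float(registry.subdomain_weight(sid)) * sub[sid][i] for sid in registry.subdomain_ids)
        for i in range(n)
    ]
    for d in registry.domains:
        out[d.domain_id] = [
            sum(sub[sid][i] for sid in d.subdomain_ids) / len(d.subdomain_ids) for i in range(n)
        ]
    out.update(sub)
    return pd.DataFrame(out, index=table.index)


def naive_complete_linkage(x: np.ndarray, k: int) -> frozenset[frozenset[int]]:
    """O(n^3) agglomerative complete-linkage clustering; returns the partition.

    Merges the pair of clusters with the smallest maximum pairwise point
    distance until k clusters remain. Ties broken by the lexicographically
    smallest cluster-index pair (immaterial for tie-free inputs).
    """
    n = len(x)
    clusters: list[list[int]] = [[i] for i in range(n)]
    while len(clusters) > k:
        best = None
        best_d = math.inf
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(
                    math.dist(x[a], x[b]) for a in clusters[i] for b in clusters[j]
                )
                if d < best_d:
                    best_d = d
                    best = (i, j)
        i, j = best
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return frozenset(frozenset(c) for c in clusters)


def partition_of(labels) -> frozenset[frozenset[int]]:
    """Positional-index partition induced by a label sequence."""
    groups: dict[object, set[int]] = {}
    for i, lab in enumerate(list(labels)):
        groups.setdefault(lab, set()).add(i)
    return frozenset(frozenset(g) for g in groups.values())


def make_random_table(registry, n_tracts: int, seed: int) -> pd.DataFrame:
    """A valid (filter-passing) feature table of i.i.d. positive values."""
    rng = np.random.default_rng(seed)
    geoids = [f"99999{i:06d}" for i in range(n_tracts)]
    table = pd.DataFrame(index=pd.Index(geoids, name="geoid"))
    table["borough"] = rng.choice(["A", "B"], size=n_tracts)
    table["population"] = rng.integers(100, 10000, size=n_tracts)
    for fid in registry.feature_ids:
        table[fid] = rng.uniform(0.0, 100.0, size=n_tracts)
    return table
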