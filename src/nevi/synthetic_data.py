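"""Synthetic census-tract data with the correlation structure the index assumes.

The generator emulates a tract-by-feature table from a latent factor model:
each tract carries one shared vulnerability factor V (plus a borough-level
mean shift), each domain carries its own factor, and every feature is

    raw = base + scale * s * (feature_loading * V
                              + domain_loading * D_domain
                              + Normal(0, noise_sd))

where s is -1 for inverse-coded features (e.g. median income falls as
latent vulnerability rises) and +1 otherwise. This induces the positive
within-subdomain correlation (after direction alignment) that a composite
index presumes, and a ground-truth latent vulnerability against which
recovery can be measured. Base/scale/clipping constants put each feature
on a plausible raw scale (percent prevalences clipped to [0, 100] — a mild
distortion of the factor model at the tails); z-scoring makes the scores
invariant to those constants.

Defaults mirror the study setting: 2,167 tracts across five boroughs, a
small fraction forced below the population-20 exclusion threshold (51
tracts) and a small fraction given one missing feature value (30 tracts),
so the filtered table retains 2,086 tracts by construction. Borough latent
shifts are highest for the Bronx and lowest for Staten Island.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .registry import Registry

__all__ = [
    "BoroughSpec",
    "SimConfig",
    "generate_feature_table",
    "generate_composition_table",
    "toy_registry",
    "toy_fixture",
]


@dataclass(frozen=True)
class BoroughSpec:
    """One stratum: sampling weight, latent mean shift, and a county code for GEOIDs."""

    weight: float
    latent_shift: float
    county: str


DEFAULT_BOROUGHS: dict[str, BoroughSpec] = {
    "Bronx": BoroughSpec(0.16, 0.8, "005"),
    "Brooklyn": BoroughSpec(0.35, 0.2, "047"),
    "Manhattan": BoroughSpec(0.13, 0.0, "061"),
    "Queens": BoroughSpec(0.31, 0.0, "081"),
    "Staten Island": BoroughSpec(0.05, -0.8, "085"),
}

COMPOSITION_GROUPS = (
    "hispanic",
    "black_nh",
    "asian_nh",
    "white_nh",
    "aian",
    "nhpi",
    "multiple_race",
    "other",
)

# group -> (logit intercept, default loading on standardized latent V)
_COMPOSITION_PARAMS: dict[str, tuple[float, float]] = {
    "hispanic": (-1.0, 0.9),
    "black_nh": (-1.2, 0.8),
    "asian_nh": (-1.5, 0.0),
    "white_nh": (-0.5, -0.9),
    "aian": (-4.0, 0.5),
    "nhpi": (-4.5, 0.0),
    "multiple_race": (-3.0, 0.2),
    "other": (-2.5, 0.2),
}


@dataclass
class SimConfig:
    """Parameters of the synthetic tract generator (defaults = study conditions)."""

    n_tracts: int = 2167
    boroughs: dict[str, BoroughSpec] = field(default_factory=lambda: dict(DEFAULT_BOROUGHS))
    latent_sd: float = 1.0
    feature_loading: float = 1.0
    domain_loading: float = 0.5
    noise_sd: float = 0.5
    frac_low_population: float = 51 / 2167
    frac_missing: float = 30 / 2167
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tracts < 4:
            raise ValueError("n_tracts must be >= 4")
        for name, frac in (("frac_low_population", self.frac_low_population),
                           ("frac_missing", self.frac_missing)):
            if not 0 <= frac <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


def _feature_scale(units: str) -> tuple[float, float, float | None, float | None]:
    """(base, scale, lo, hi) raw-scale constants for a feature's units."""
    if units == "percent":
        return 25.0, 8.0, 0.0, 100.0
    if units.startswith("USD"):
        return 60000.0, 15000.0, 5000.0, None
    if units.startswith("person-minutes"):
        return 50000.0, 15000.0, 0.0, None
    if units.startswith("index"):
        return 0.45, 0.06, 0.0, 1.0
    if units.startswith("persons per"):
        return 30000.0, 12000.0, 100.0, None
    if units == "years":
        return 60.0, 12.0, 0.0, None
    return 0.0, 1.0, None, None


def generate_feature_table(
    cfg: SimConfig, registry: Registry
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw a synthetic feature table; return it with the true latent vulnerability.

    Deterministic given ``cfg.seed``. Exactly ``round(frac_low_population *
    n_tracts)`` tracts get population below 20, and ``round(frac_missing *
    n_tracts)`` of the remaining tracts get exactly one missing feature.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_tracts

    names = list(cfg.boroughs)
    weights = np.array([cfg.boroughs[b].weight for b in names], dtype=float)
    weights /= weights.sum()
    borough = rng.choice(names, size=n, p=weights)
    shifts = np.array([cfg.boroughs[b].latent_shift for b in borough])

    latent = rng.normal(0.0, cfg.latent_sd, n) + shifts
    domain_ids = registry.domain_ids
    domain_factors = rng.normal(0.0, 1.0, (n, len(domain_ids)))

    geoids = [f"36{cfg.boroughs[b].county}{i + 1:06d}" for i, b in enumerate(borough)]
    table = pd.DataFrame(index=pd.Index(geoids, name="geoid"))
    table["borough"] = borough

    population = np.maximum(20, np.round(rng.lognormal(8.2, 0.5, n))).astype(int)
    n_low = round(cfg.frac_low_population * n)
    low_idx = rng.choice(n, size=n_low, replace=False)
    population[low_idx] = rng.integers(0, 20, size=n_low)
    table["population"] = population

    for feat in registry.features:
        d = domain_ids.index(feat.domain_id)
        signal = (
            cfg.feature_loading * latent
            + cfg.domain_loading * domain_factors[:, d]
            + rng.normal(0.0, cfg.noise_sd, n)
        )
        sgn = -1.0 if feat.direction == "inverse" else 1.0
        base, scale, lo, hi = _feature_scale(feat.units)
        table[feat.feature_id] = np.clip(base + scale * sgn * signal, lo, hi)

    n_miss = round(cfg.frac_missing * n)
    eligible = np.setdiff1d(np.arange(n), low_idx)
    miss_idx = rng.choice(eligible, size=min(n_miss, len(eligible)), replace=False)
    feat_ids = registry.feature_ids
    for i in miss_idx:
        table.iloc[i, table.columns.get_loc(feat_ids[rng.integers(len(feat_ids))])] = np.nan

    truth = pd.Series(latent, index=table.index, name="latent_vulnerability")
    return table, truth


def generate_composition_table(
    cfg: SimConfig,
    truth: pd.Series,
    association: float | dict[str, float] | None = None,
) -> pd.DataFrame:
    """Group proportions from logistic transforms of the latent vulnerability.

    ``association`` rescales (float) or replaces (dict, per group) the
    default loadings of each group's logit on the standardized latent; 0
    severs the link entirely, enabling null-simulation tests. Proportions
    always land in [0, 1]. Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng([cfg.seed, 7])
    v = (truth - truth.mean()) / truth.std(ddof=1)
    out = pd.DataFrame(index=truth.index)
    for group in COMPOSITION_GROUPS:
        alpha, beta = _COMPOSITION_PARAMS[group]
        if isinstance(association, dict):
            beta = association.get(group, beta)
        elif association is not None:
            beta = beta * association
        logit = alpha + beta * v.to_numpy() + rng.normal(0.0, 0.5, len(truth))
        out[group] = 1.0 / (1.0 + np.exp(-logit))
    return out


def toy_registry() -> Registry:
    """A hand-sized 2-domain / 3-subdomain / 4-feature registry."""
    return Registry.from_dict(
        {
            "variant": "toy",
            "domains": [
                {"domain_id": "env", "label": "Environmental burden"},
                {"domain_id": "health", "label": "Health"},
            ],
            "subdomains": [
                {"subdomain_id": "air", "label": "Air quality", "domain_id": "env"},
                {"subdomain_id": "noise", "label": "Noise", "domain_id": "env"},
                {"subdomain_id": "asthma", "label": "Asthma burden", "domain_id": "health"},
            ],
            "features": [
                {"feature_id": "pm25", "label": "PM2.5", "subdomain_id": "air",
                 "source": "ACS", "direction": "direct", "units": "ug/m3"},
                {"feature_id": "income", "label": "Median income", "subdomain_id": "air",
                 "source": "ACS", "direction": "inverse", "units": "USD (thousands)"},
                {"feature_id": "noise_db", "label": "Noise level", "subdomain_id": "noise",
                 "source": "ACS", "direction": "direct", "units": "dB"},
                {"feature_id": "asthma_pct", "label": "Asthma prevalence", "subdomain_id": "asthma",
                 "source": "PLACES", "direction": "direct", "units": "percent"},
            ],
        }
    )


def toy_fixture() -> tuple[pd.DataFrame, Registry, pd.DataFrame]:
    """Five tracts, the toy registry, and their expected scores.

    The expected score table was computed with a brute-force transcription
    of the scoring arithmetic (z-score, direction-align, re-center, sum
    within subdomain, min-max, weight-sum) independent of the pipeline
    code, and is frozen here to 12 decimal places. Subdomain weights are
    air 1/4, noise 1/4 (two subdomains in a 2-domain registry's env
    domain), asthma 1/2.
    """
    geoids = [f"36005{i:06d}" for i in range(1, 6)]
    table = pd.DataFrame(
        {
            "borough": ["Bronx"] * 5,
            "population": [1500, 2200, 3100, 900, 4000],
            "pm25": [5.0, 7.0, 9.0, 11.0, 13.0],
            "income": [100.0, 80.0, 60.0, 40.0, 20.0],
            "noise_db": [50.0, 50.0, 70.0, 60.0, 55.0],
            "asthma_pct": [2.0, 4.0, 8.0, 16.0, 10.0],
        },
        index=pd.Index(geoids, name="geoid"),
    )
    # exact values: air (0, 1/4, 1/2, 3/4, 1); noise (0, 0, 1, 1/2, 1/4);
    # asthma (0, 1/7, 3/7, 1, 4/7); overall (0, 15/112, 33/56, 13/16, 67/112)
    expected = pd.DataFrame(
        {
            "overall": [0.0, 15 / 112, 33 / 56, 13 / 16, 67 / 112],
            "env": [0.0, 1 / 8, 3 / 4, 5 / 8, 5 / 8],
            "health": [0.0, 1 / 7, 3 / 7, 1.0, 4 / 7],
            "air": [0.0, 0.25, 0.5, 0.75, 1.0],
            "noise": [0.0, 0.0, 1.0, 0.5, 0.25],
            "asthma": [0.0, 1 / 7, 3 / 7, 1.0, 4 / 7],
        },
        index=table.index,
    )
    return table, toy_registry(), expected
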