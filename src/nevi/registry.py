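"""Declarative feature registry for the NEVI hierarchy.

The Neighborhood Environmental Vulnerability Index (NEVI) aggregates
area-level features through a two-level hierarchy: features are grouped
into subdomains (the "slices" of a ToxPi-style profile), subdomains into
domains. Domains are equally weighted, and subdomains are equally
weighted *within* their domain, so a subdomain's overall weight is

    w_s = (1 / n_domains) * (1 / n_subdomains_in_its_domain)

e.g. 1/28 = (1/4)(1/7) for a subdomain in a 7-subdomain domain of the
default 4-domain registry. Weights are kept as exact :class:`~fractions.Fraction`
values so conservation (sum to 1) holds without floating-point drift.

The default registry (4 domains, 24 subdomains, 54 features) is data, not
code: it lives in ``data/registry_default.yaml`` and can be edited or
replaced to adapt the index to other settings. A sensitivity variant adds
a racial/ethnic-composition subdomain to the demographics domain.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from pathlib import Path

import yaml

from .errors import RegistryError

__all__ = [
    "FeatureDef",
    "SubdomainDef",
    "DomainDef",
    "Registry",
    "build_default_registry",
    "build_sensitivity_registry",
    "subdomain_weight",
    "load_registry",
    "save_registry",
]

_SOURCES = frozenset({"ACS", "PLACES"})
_DIRECTIONS = frozenset({"direct", "inverse"})


@dataclass(frozen=True)
class FeatureDef:
    """One area-level feature (a column of the tract table).

    ``direction`` is the vulnerability coding: ``direct`` means a larger raw
    value indicates greater vulnerability; ``inverse`` (e.g. median household
    income) means a larger raw value indicates *less* vulnerability and the
    feature is negated before aggregation.
    """

    feature_id: str
    label: str
    domain_id: str
    subdomain_id: str
    source: str
    direction: str
    units: str = ""

    def __post_init__(self) -> None:
        if self.source not in _SOURCES:
            raise RegistryError(f"unknown source {self.source!r} for feature {self.feature_id!r}")
        if self.direction not in _DIRECTIONS:
            raise RegistryError(
                f"unknown direction {self.direction!r} for feature {self.feature_id!r}"
            )


@dataclass(frozen=True)
class SubdomainDef:
    """A slice of the index: an ordered group of features within one domain."""

    subdomain_id: str
    label: str
    domain_id: str
    feature_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class DomainDef:
    """A top-level grouping of subdomains."""

    domain_id: str
    label: str
    subdomain_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class Registry:
    """The full domain -> subdomain -> feature tree with derived weights."""

    domains: tuple[DomainDef, ...]
    subdomains: tuple[SubdomainDef, ...]
    features: tuple[FeatureDef, ...]
    variant: str = "default"

    # -- lookups ---------------------------------------------------------
    @property
    def domain_ids(self) -> list[str]:
        return [d.domain_id for d in self.domains]

    @property
    def subdomain_ids(self) -> list[str]:
        return [s.subdomain_id for s in self.subdomains]

    @property
    def feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    def get_domain(self, domain_id: str) -> DomainDef:
        for d in self.domains:
            if d.domain_id == domain_id:
                return d
        raise RegistryError(f"unknown domain {domain_id!r}")

    def get_subdomain(self, subdomain_id: str) -> SubdomainDef:
        for s in self.subdomains:
            if s.subdomain_id == subdomain_id:
                return s
        raise RegistryError(f"unknown subdomain {subdomain_id!r}")

    def get_feature(self, feature_id: str) -> FeatureDef:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise RegistryError(f"unknown feature {feature_id!r}")

    def subdomains_of(self, domain_id: str) -> list[SubdomainDef]:
        return [self.get_subdomain(s) for s in self.get_domain(domain_id).subdomain_ids]

    def features_of(self, subdomain_id: str) -> list[FeatureDef]:
        return [self.get_feature(f) for f in self.get_subdomain(subdomain_id).feature_ids]

    # -- weights ---------------------------------------------------------
    def subdomain_weight(self, subdomain_id: str) -> Fraction:
        """Exact overall weight of a subdomain: (1/n_domains)(1/n_subdomains_in_domain)."""
        sub = self.get_subdomain(subdomain_id)
        n_in_domain = len(self.get_domain(sub.domain_id).subdomain_ids)
        return Fraction(1, len(self.domains)) * Fraction(1, n_in_domain)

    def weights(self) -> dict[str, Fraction]:
        return {s: self.subdomain_weight(s) for s in self.subdomain_ids}

    def directions(self) -> dict[str, str]:
        return {f.feature_id: f.direction for f in self.features}

    # -- validation ------------------------------------------------------
    def validate(self) -> "Registry":
        """Check the partition and weight-conservation invariants; return self."""
        if len(set(self.domain_ids)) != len(self.domains):
            raise RegistryError("duplicate domain_id")
        if len(set(self.subdomain_ids)) != len(self.subdomains):
            raise RegistryError("duplicate subdomain_id")
        if len(set(self.feature_ids)) != len(self.features):
            raise RegistryError("duplicate feature_id")

        sub_by_id = {s.subdomain_id: s for s in self.subdomains}
        claimed = [s for d in self.domains for s in d.subdomain_ids]
        if sorted(claimed) != sorted(self.subdomain_ids):
            raise RegistryError("subdomains do not partition exactly across domains")
        for d in self.domains:
            for sid in d.subdomain_ids:
                if sub_by_id[sid].domain_id != d.domain_id:
                    raise RegistryError(f"subdomain {sid!r} disagrees with domain {d.domain_id!r}")

        claimed_f = [f for s in self.subdomains for f in s.feature_ids]
        if sorted(claimed_f) != sorted(self.feature_ids):
            raise RegistryError("features do not partition exactly across subdomains")
        for s in self.subdomains:
            if not s.feature_ids:
                raise RegistryError(f"subdomain {s.subdomain_id!r} has no features")
            if len(set(s.feature_ids)) != len(s.feature_ids):
                raise RegistryError(f"subdomain {s.subdomain_id!r} repeats a feature")
        for f in self.features:
            sub = sub_by_id.get(f.subdomain_id)
            if sub is None:
                raise RegistryError(f"feature {f.feature_id!r} names unknown subdomain")
            if f.domain_id != sub.domain_id:
                raise RegistryError(f"feature {f.feature_id!r} disagrees with its subdomain's domain")

        total = sum(self.weights().values())
        if total != 1:
            raise RegistryError(f"subdomain weights sum to {total}, not 1")
        per_domain = Fraction(1, len(self.domains))
        for d in self.domains:
            s = sum(self.subdomain_weight(sid) for sid in d.subdomain_ids)
            if s != per_domain:
                raise RegistryError(f"weights in domain {d.domain_id!r} sum to {s}, not {per_domain}")
        return self

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "domains": [{"domain_id": d.domain_id, "label": d.label} for d in self.domains],
            "subdomains": [
                {"subdomain_id": s.subdomain_id, "label": s.label, "domain_id": s.domain_id}
                for s in self.subdomains
            ],
            "features": [
                {
                    "feature_id": f.feature_id,
                    "label": f.label,
                    "subdomain_id": f.subdomain_id,
                    "source": f.source,
                    "direction": f.direction,
                    "units": f.units,
                }
                for f in self.features
            ],
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "Registry":
        sub_domain = {s["subdomain_id"]: s["domain_id"] for s in raw.get("subdomains", [])}
        features = tuple(
            FeatureDef(
                feature_id=f["feature_id"],
                label=f.get("label", f["feature_id"]),
                domain_id=sub_domain[f["subdomain_id"]],
                subdomain_id=f["subdomain_id"],
                source=f["source"],
                direction=f["direction"],
                units=f.get("units", ""),
            )
            for f in raw.get("features", [])
        )
        subdomains = tuple(
            SubdomainDef(
                subdomain_id=s["subdomain_id"],
                label=s.get("label", s["subdomain_id"]),
                domain_id=s["domain_id"],
                feature_ids=tuple(
                    f.feature_id for f in features if f.subdomain_id == s["subdomain_id"]
                ),
            )
            for s in raw.get("subdomains", [])
        )
        domains = tuple(
            DomainDef(
                domain_id=d["domain_id"],
                label=d.get("label", d["domain_id"]),
                subdomain_ids=tuple(
                    s.subdomain_id for s in subdomains if s.domain_id == d["domain_id"]
                ),
            )
            for d in raw.get("domains", [])
        )
        return cls(
            domains=domains,
            subdomains=subdomains,
            features=features,
            variant=raw.get("variant", "default"),
        ).validate()


def _read_packaged_yaml(name: str) -> dict:
    text = resources.files("nevi.data").joinpath(name).read_text(encoding="utf-8")
    return yaml.safe_load(text)


def build_default_registry() -> Registry:
    """Load the default 4-domain / 24-subdomain / 54-feature registry."""
    return Registry.from_dict(_read_packaged_yaml("registry_default.yaml"))


def build_sensitivity_registry() -> Registry:
    """Default registry plus a racial/ethnic-composition demographics subdomain.

    The demographics domain then has 8 equally weighted subdomains, each
    carrying an overall weight of (1/4)(1/8) = 1/32; other domains are
    unchanged.
    """
    base = _read_packaged_yaml("registry_default.yaml")
    ext = _read_packaged_yaml("registry_race_ethnicity.yaml")
    merged = {
        "variant": ext.get("variant", "race_ethnicity"),
        "domains": base["domains"],
        "subdomains": base["subdomains"] + ext.get("subdomains", []),
        "features": base["features"] + ext.get("features", []),
    }
    return Registry.from_dict(merged)


def subdomain_weight(registry: Registry, subdomain_id: str) -> Fraction:
    """Overall index weight of one subdomain (exact rational)."""
    return registry.subdomain_weight(subdomain_id)


def load_registry(path: str | Path) -> Registry:
    """Read a registry from a YAML config file."""
    with open(path, "r", encoding="utf-8") as fh:
        return Registry.from_dict(yaml.safe_load(fh))


def save_registry(registry: Registry, path: str | Path) -> None:
    """Write a registry to a YAML config file (round-trips via load_registry)."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(registry.to_dict(), fh, sort_keys=False, allow_unicode=True)
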