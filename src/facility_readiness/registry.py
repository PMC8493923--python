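"""Item registry and index definitions.

The three shipped framework registries (SARA tracer items, the DHS
analytical-study indicators, and items mapped to the WHO standards for
quality of maternal and newborn care) live as YAML documents under
``facility_readiness/data``. Each registry lists items with a readiness
domain, tier applicability (health centres get the base list, hospitals
an expanded one), an optional WHO standard, and an optional
conditional-applicability flag for items asked only of a facility subset
(government-managed facilities).

Shipped item counts per framework and tier:

========== ============== ========
framework  health centre  hospital
========== ============== ========
SARA       15             22
DHS        30             33
WHO        44             52
========== ============== ========

An :class:`IndexSpec` is the per-(framework, tier) view used by scoring:
the ordered item list, its partition into domains, and any domains
excluded from domain-weighted aggregation (the DHS "guidelines, staff
training and supervision" domain).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional

import yaml

from .core import Framework, Tier, TierApplicability, WhoStandard
from .errors import ConfigurationError

#: Item counts the shipped registries must reproduce: (health-centre, hospital).
EXPECTED_ITEM_COUNTS: dict[Framework, tuple[int, int]] = {
    Framework.SARA: (15, 22),
    Framework.DHS: (30, 33),
    Framework.WHO_STANDARDS: (44, 52),
}

_DATA_FILES = {
    Framework.SARA: "sara.yaml",
    Framework.DHS: "dhs.yaml",
    Framework.WHO_STANDARDS: "who_standards.yaml",
}


@dataclass(frozen=True)
class ItemDefinition:
    """One survey item: what it measures and where it applies."""

    item_id: str
    label: str
    domain: str
    frameworks: frozenset[Framework]
    tier_applicability: TierApplicability = TierApplicability.BOTH
    who_standard: Optional[WhoStandard] = None
    #: None = asked everywhere; "government_only" = not applicable to
    #: privately managed facilities.
    conditional_applicability: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.domain:
            raise ConfigurationError(f"item {self.item_id!r}: empty domain")
        has_std = self.who_standard is not None
        in_who = Framework.WHO_STANDARDS in self.frameworks
        if has_std != in_who:
            raise ConfigurationError(
                f"item {self.item_id!r}: who_standard must be present exactly "
                f"when the item belongs to the WHO_standards framework"
            )

    def applies_to(self, tier: Tier) -> bool:
        return self.tier_applicability.applies_to(tier)


class ItemRegistry:
    """Mapping of item_id -> :class:`ItemDefinition` with framework views."""

    def __init__(self, items: Iterable[ItemDefinition],
                 excluded_from_weighting: Mapping[Framework, frozenset[str]] | None = None):
        self._items: dict[str, ItemDefinition] = {}
        for item in items:
            if item.item_id in self._items:
                raise ConfigurationError(f"duplicate item_id {item.item_id!r} in registry")
            self._items[item.item_id] = item
        self._excluded = {fw: frozenset(doms) for fw, doms in
                          (excluded_from_weighting or {}).items()}

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._items

    def __getitem__(self, item_id: str) -> ItemDefinition:
        return self._items[item_id]

    def __len__(self) -> int:
        return len(self._items)

    @property
    def item_ids(self) -> list[str]:
        return list(self._items)

    def items_for(self, framework: Framework, tier: Tier) -> list[ItemDefinition]:
        """Items of one framework applicable to one tier, registry order."""
        return [it for it in self._items.values()
                if framework in it.frameworks and it.applies_to(tier)]

    def excluded_domains(self, framework: Framework) -> frozenset[str]:
        return self._excluded.get(framework, frozenset())


@dataclass(frozen=True)
class IndexSpec:
    """Validated (framework, tier) index definition for scoring."""

    name: Framework
    tier: Tier
    items: tuple[str, ...]
    domains: Mapping[str, tuple[str, ...]]
    excluded_domains_for_weighting: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for dom, members in self.domains.items():
            for item in members:
                if item in seen:
                    raise ConfigurationError(
                        f"item {item!r} appears in domains {seen[item]!r} and {dom!r}")
                seen[item] = dom
        if set(seen) != set(self.items):
            raise ConfigurationError(
                f"{self.name.value}/{self.tier.value}: domain partition does not "
                f"cover the item list exactly")

    @property
    def n_items(self) -> int:
        return len(self.items)


def _parse_item(raw: dict, framework: Framework) -> ItemDefinition:
    std = raw.get("standard")
    return ItemDefinition(
        item_id=raw["id"],
        label=raw.get("label", raw["id"]),
        domain=raw["domain"],
        frameworks=frozenset({framework}),
        tier_applicability=TierApplicability(raw.get("tier", "both")),
        who_standard=WhoStandard(std) if std is not None else None,
        conditional_applicability=raw.get("conditional"),
    )


def load_registry_document(text: str) -> tuple[list[ItemDefinition], Framework, frozenset[str]]:
    """Parse one framework YAML document into item definitions."""
    doc = yaml.safe_load(text)
    try:
        framework = Framework(doc["framework"])
        raw_items = doc["items"]
    except (KeyError, ValueError, TypeError) as exc:
        raise ConfigurationError(f"malformed registry document: {exc}") from exc
    items = [_parse_item(raw, framework) for raw in raw_items]
    declared = doc.get("domains")
    if declared is not None:
        used = {it.domain for it in items}
        if not used <= set(declared):
            raise ConfigurationError(
                f"{framework.value}: items use undeclared domains {used - set(declared)}")
    excluded = frozenset(doc.get("excluded_from_weighting", []))
    unknown = excluded - {it.domain for it in items}
    if unknown:
        raise ConfigurationError(
            f"{framework.value}: excluded_from_weighting names unknown domains {set(unknown)}")
    return items, framework, excluded


def default_registry() -> ItemRegistry:
    """The shipped three-framework registry."""
    all_items: list[ItemDefinition] = []
    excluded: dict[Framework, frozenset[str]] = {}
    for framework, fname in _DATA_FILES.items():
        text = resources.files("facility_readiness.data").joinpath(fname).read_text()
        items, fw, excl = load_registry_document(text)
        if fw is not framework:
            raise ConfigurationError(f"{fname}: declares framework {fw.value}")
        all_items.extend(items)
        if excl:
            excluded[fw] = excl
    return ItemRegistry(all_items, excluded)


def load_index_spec(framework: Framework | str, tier: Tier | str,
                    registry: ItemRegistry,
                    expected_counts: Mapping[Framework, tuple[int, int]] | None = None,
                    ) -> IndexSpec:
    """Build the validated IndexSpec for one framework and tier.

    ``expected_counts`` defaults to the published per-framework totals;
    a registry that cannot reproduce them is rejected. Pass ``{}`` to
    skip count validation (toy registries in tests).
    """
    framework = Framework(framework)
    tier = Tier(tier)
    if expected_counts is None:
        expected_counts = EXPECTED_ITEM_COUNTS
    items = registry.items_for(framework, tier)
    if not items:
        raise ConfigurationError(f"registry has no items for {framework.value}/{tier.value}")
    if framework in expected_counts:
        hc, hosp = expected_counts[framework]
        expected = hosp if tier is Tier.HOSPITAL else hc
        if len(items) != expected:
            raise ConfigurationError(
                f"{framework.value}/{tier.value}: registry yields {len(items)} items, "
                f"expected {expected}")
    domains: dict[str, list[str]] = {}
    for it in items:
        domains.setdefault(it.domain, []).append(it.item_id)
    return IndexSpec(
        name=framework,
        tier=tier,
        items=tuple(it.item_id for it in items),
        domains={d: tuple(ids) for d, ids in domains.items()},
        excluded_domains_for_weighting=registry.excluded_domains(framework),
    )


def domain_partition(spec: IndexSpec) -> dict[str, tuple[str, ...]]:
    """Domain -> item_ids partition of an index (validated at construction)."""
    return dict(spec.domains)
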