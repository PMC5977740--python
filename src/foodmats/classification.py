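"""Rule-based classification of marketing occasions.

Healthfulness uses three ordered classes:

* **Most Healthy** — unprocessed foods/beverages with no added fat, sugar,
  or salt (products); grocery stores, farmers' markets, salad/sandwich/
  smoothie outlets (retailers).
* **Less Healthy** — some added fat, sugar, or salt; sit-down restaurants,
  cafeterias, coffee outlets, prepared grocery and supplement stores.
* **Least Healthy** — processed energy-dense, nutrient-poor items; pizza,
  burger, taco, fried chicken, ice-cream and similar outlets, pubs/lounges.

Product rules here are keyword/category driven rather than driven by exact
nutrient thresholds: collecting full nutrient data for everything marketed
in a facility is rarely feasible, so the default rule set encodes the same
kind of simplifying category judgements a trained dietitian applies, with an
optional added-fat/sugar/salt override hook for when that information is
known.  Brands classify as the product they most closely represent
(Coca-Cola -> sweetened soft drinks, Aquafina -> water); retailers without a
recognized category fall back to their most prominent product sold.

The default rule set ships as an editable JSON config
(``data/default_rules.json``) so deployments can extend the brand map and
keyword lists case by case without touching code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

from .audit import HealthClass, PricingIndicatorRecord, Setting, SizeClass, N_PRICING_INDICATORS
from .errors import DomainError, UnclassifiedError

#: Accepted values for the added fat/sugar/salt override hook.
ADDITION_LEVELS = ("none", "some", "high")

_ADDITION_TO_CLASS = {
    "none": HealthClass.MOST_HEALTHY,
    "some": HealthClass.LESS_HEALTHY,
    "high": HealthClass.LEAST_HEALTHY,
}

# Physical size thresholds in letter-sheet (8.5 x 11 in) equivalents.
# SMALL is strictly below 1 sheet in both settings; the MEDIUM interval is
# closed at both ends (1-3 indoor, 1-10 outdoor); LARGE is strictly above.
INDOOR_MEDIUM_MAX = 3.0
OUTDOOR_MEDIUM_MAX = 10.0


@dataclass(frozen=True)
class ClassificationRuleSet:
    """Ordered keyword rules, retailer categories, and brand representations.

    ``product_rules`` and ``retailer_rules`` are ordered ``(pattern, class)``
    lists; patterns are matched case-insensitively as substrings and the
    first match wins, so more specific patterns must precede general ones.
    """

    product_rules: tuple[tuple[str, HealthClass], ...]
    retailer_rules: tuple[tuple[str, HealthClass], ...]
    brand_map: dict[str, str]
    child_tags: frozenset[str]
    sports_tags: frozenset[str]
    pricing_overeating_ids: tuple[int, ...] = (1, 2, 3, 4)
    pricing_comparison_ids: tuple[int, ...] = (5, 6, 7, 8, 9, 10, 11)
    item_labels: dict[int, str] = field(default_factory=dict)
    version: str = "1.0"

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassificationRuleSet":
        with open(path, encoding="utf-8") as fh:
            return cls._from_payload(json.load(fh))

    @classmethod
    def default(cls) -> "ClassificationRuleSet":
        payload = json.loads(
            resources.files("foodmats.data").joinpath("default_rules.json").read_text("utf-8")
        )
        return cls._from_payload(payload)

    @classmethod
    def _from_payload(cls, payload: dict) -> "ClassificationRuleSet":
        return cls(
            product_rules=tuple(
                (str(pat).lower(), HealthClass.parse(hc)) for pat, hc in payload["product_rules"]
            ),
            retailer_rules=tuple(
                (str(pat).lower(), HealthClass.parse(hc)) for pat, hc in payload["retailer_rules"]
            ),
            brand_map={str(k).lower(): str(v) for k, v in payload["brand_map"].items()},
            child_tags=frozenset(payload["child_tags"]),
            sports_tags=frozenset(payload["sports_tags"]),
            pricing_overeating_ids=tuple(payload.get("pricing_overeating_ids", (1, 2, 3, 4))),
            pricing_comparison_ids=tuple(payload.get("pricing_comparison_ids", tuple(range(5, 12)))),
            item_labels={int(k): str(v) for k, v in payload.get("item_labels", {}).items()},
            version=str(payload.get("version", "unversioned")),
        )


_DEFAULT_RULES: Optional[ClassificationRuleSet] = None


def default_rules() -> ClassificationRuleSet:
    """The packaged default rule set (cached)."""
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = ClassificationRuleSet.default()
    return _DEFAULT_RULES


def _first_match(text: str, rules: tuple[tuple[str, HealthClass], ...]) -> Optional[HealthClass]:
    for pattern, health in rules:
        if pattern in text:
            return health
    return None


def classify_product(
    name: str,
    category_hint: str = "",
    added_fat_sugar_salt: Optional[str] = None,
    rules: Optional[ClassificationRuleSet] = None,
) -> HealthClass:
    """Classify a food or beverage product by healthfulness.

    Keyword rules run first (on ``name`` plus ``category_hint``); if none
    match, the added fat/sugar/salt level decides (none -> Most Healthy,
    some -> Less, high -> Least).  With neither, :class:`UnclassifiedError`
    asks for manual assignment.
    """
    if not name or not name.strip():
        raise DomainError("product name must be non-empty")
    rules = rules or default_rules()
    text = f"{name} {category_hint}".lower()
    match = _first_match(text, rules.product_rules)
    if match is not None:
        return match
    if added_fat_sugar_salt is not None:
        level = added_fat_sugar_salt.lower()
        if level not in _ADDITION_TO_CLASS:
            raise DomainError(
                f"added_fat_sugar_salt must be one of {ADDITION_LEVELS}, got {added_fat_sugar_salt!r}"
            )
        return _ADDITION_TO_CLASS[level]
    raise UnclassifiedError(
        f"no rule classifies product {name!r} (hint {category_hint!r}); assign manually"
    )


def classify_brand(brand: str, rules: Optional[ClassificationRuleSet] = None) -> HealthClass:
    """Classify a brand as the product it most closely represents."""
    rules = rules or default_rules()
    representative = rules.brand_map.get(brand.strip().lower())
    if representative is None:
        # A brand name that itself matches a product keyword is resolvable.
        match = _first_match(brand.lower(), rules.product_rules)
        if match is not None:
            return match
        raise UnclassifiedError(f"brand {brand!r} is not in the brand map; assign manually")
    return classify_product(representative, rules=rules)


def classify_retailer(
    name: str,
    category: str = "",
    rules: Optional[ClassificationRuleSet] = None,
) -> HealthClass:
    """Classify a food retailer by its category, falling back to its most
    prominent product (e.g. ice cream for a soft-serve fast-food outlet)."""
    rules = rules or default_rules()
    text = f"{category} {name}".lower()
    match = _first_match(text, rules.retailer_rules)
    if match is not None:
        return match
    match = _first_match(text, rules.product_rules)  # most-prominent-product fallback
    if match is not None:
        return match
    raise UnclassifiedError(
        f"retailer {name!r} (category {category!r}) matches no rule; assign manually"
    )


def classify_size(sheet_equivalents: float, setting: Setting | str) -> SizeClass:
    """Classify the physical size of a promotion.

    ``sheet_equivalents`` is the promotion's area in multiples of a letter
    sheet (8.5 x 11 in).  Indoor: small < 1, medium 1-3, large > 3.
    Outdoor: small < 1, medium 1-10, large > 10.
    """
    if not (sheet_equivalents > 0):
        raise DomainError(f"sheet_equivalents must be positive, got {sheet_equivalents}")
    setting = Setting(setting)
    if sheet_equivalents < 1:
        return SizeClass.SMALL
    upper = INDOOR_MEDIUM_MAX if setting is Setting.INDOOR else OUTDOOR_MEDIUM_MAX
    return SizeClass.MEDIUM if sheet_equivalents <= upper else SizeClass.LARGE


def classify_technique(
    tags: set[str] | frozenset[str],
    rules: Optional[ClassificationRuleSet] = None,
) -> tuple[bool, bool]:
    """Map observer-entered technique tags to (child_targeted, sports_related).

    Child-targeting covers characters, taste appeals, humour,
    action-adventure, fantasy, fun shapes/colours, contests and giveaways,
    cartoonish fonts, and child actors; sports-relation covers any reference
    to physical activity, exercise, sport, game, recreation, performance, or
    competition.  The two flags are independent.
    """
    rules = rules or default_rules()
    tags = set(tags)
    vocabulary = rules.child_tags | rules.sports_tags
    unknown = sorted(tags - vocabulary)
    if unknown:
        raise DomainError(
            f"unknown technique tags {unknown}; known tags: {sorted(vocabulary)}"
        )
    return (bool(tags & rules.child_tags), bool(tags & rules.sports_tags))


def classify_pricing(indicator_id: int, triggered: bool) -> PricingIndicatorRecord:
    """Build a pricing-indicator record.

    A triggered indicator — pricing that encourages overeating or repeat
    visits, or prices unhealthy options below healthy ones — is classified
    Least Healthy; an untriggered one carries no classification.
    """
    if not 1 <= indicator_id <= N_PRICING_INDICATORS:
        raise DomainError(
            f"indicator_id must be in 1..{N_PRICING_INDICATORS}, got {indicator_id}"
        )
    return PricingIndicatorRecord(
        indicator_id=indicator_id,
        triggered=triggered,
        classification=HealthClass.LEAST_HEALTHY if triggered else None,
    )
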