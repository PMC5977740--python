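"""The site scoring algorithm: exposure x power + repetition.

A site's score summarises the theoretical impact of its food-marketing
environment on food preferences, purchases, and consumption.  It combines

* **exposure** — the count of marketing occasions per area (food, sport,
  other) and the repetition of marketed entities site-wide, and
* **power** — the persuasive strength of each occasion: unhealthy content,
  child-targeted design, sports-related design, and physical size.

Each occasion contributes one exposure point plus weighted power points::

    points(occ) = 1 + w_content * content(occ) + w_child * [child-targeted]
                    + w_sport * [sports-related] + w_size * size(occ)

where ``content`` is 1 for Least Healthy, ``w_less_fraction`` (default 0.5)
for Less Healthy and 0 for Most Healthy, and ``size`` is 0 / 0.5 / 1 for
small / medium / large (0 when no size was recorded — size is excluded for
some pricing and place occasions).  An area's score is the sum over its
occasions, which for fully-sized areas equals the familiar
``frequency x (1 + power proportions)`` form; summing per occasion keeps the
score strictly monotone in exposure and in every power attribute.  Each
triggered pricing indicator enters the food area as a Least-Healthy
pseudo-occasion with no design flags and no size.

The site score adds a repetition factor::

    S = sum_a A_a + w_repetition * R

with ``R`` the number of distinct (entity name, kind) pairs marketed at
least ``repetition_threshold`` (default 3) times site-wide.  All constants
are configuration-driven (:class:`ScoringConfig`) so alternative point
schemes can be dropped in; the defaults weight every power characteristic
equally against one exposure point.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

from pydantic import BaseModel, Field

from .audit import AreaKind, HealthClass, SiteAudit, SizeClass
from .errors import UnclassifiedError

_CONTENT_VALUE = {
    HealthClass.MOST_HEALTHY: 0.0,
    HealthClass.LEAST_HEALTHY: 1.0,
    # LESS_HEALTHY handled via w_less_fraction
}


class ScoringConfig(BaseModel):
    """Weights and thresholds of the scoring algorithm (all configurable)."""

    w_content: float = Field(default=1.0, ge=0)
    w_child: float = Field(default=1.0, ge=0)
    w_sport: float = Field(default=1.0, ge=0)
    w_size: float = Field(default=1.0, ge=0)
    #: Less Healthy content counts this fraction of Least Healthy content,
    #: keeping the ordered three-class scheme score-visible.
    w_less_fraction: float = Field(default=0.5, ge=0, le=1)
    w_repetition: float = Field(default=2.0, ge=0)
    #: an entity is 'repeated' when recorded this many times per site
    repetition_threshold: int = Field(default=3, ge=2)
    #: count triggered pricing indicators as Least-Healthy occasions in FOOD
    include_pricing_as_occasions: bool = True


DEFAULT_CONFIG = ScoringConfig()


@dataclass(frozen=True)
class PowerProfile:
    """Per-area summary of 'powerful' marketing characteristics.

    Proportions are over the area's occasions (including pricing
    pseudo-occasions in the food area); ``mean_size`` averages 0/0.5/1 size
    values over the occasions that have a recorded size only.  All
    components are zero for an empty area.
    """

    p_least: float = 0.0
    p_less: float = 0.0
    p_child: float = 0.0
    p_sport: float = 0.0
    mean_size: float = 0.0
    n_occasions: int = 0
    n_sized: int = 0


@dataclass(frozen=True)
class ScoreBreakdown:
    """Full decomposition of a site score."""

    site_id: str
    frequency: dict[AreaKind, int]
    power: dict[AreaKind, PowerProfile]
    area_scores: dict[AreaKind, float]
    repetition_count: int
    total: float
    config: ScoringConfig = field(default_factory=ScoringConfig)

    def to_dict(self) -> dict:
        return {
            "site_id": self.site_id,
            "frequency": {a.value: self.frequency[a] for a in AreaKind},
            "power": {
                a.value: {
                    "p_least": p.p_least, "p_less": p.p_less, "p_child": p.p_child,
                    "p_sport": p.p_sport, "mean_size": p.mean_size,
                    "n_occasions": p.n_occasions, "n_sized": p.n_sized,
                }
                for a, p in self.power.items()
            },
            "area_scores": {a.value: self.area_scores[a] for a in AreaKind},
            "repetition_count": self.repetition_count,
            "total": self.total,
            "config": self.config.model_dump(),
        }


@dataclass(frozen=True)
class _Unit:
    """One scoring unit: an occasion or a triggered-pricing pseudo-occasion."""

    health: HealthClass
    child: bool
    sport: bool
    size: Optional[SizeClass]


def _area_units(audit: SiteAudit, area: AreaKind, config: ScoringConfig) -> list[_Unit]:
    units = []
    for i, occ in enumerate(audit.occasions):
        if occ.area != area:
            continue
        if occ.entity.health_class is None:
            raise UnclassifiedError(
                f"site {audit.site_id}: occasion {i} (item {occ.item_id}, "
                f"entity {occ.entity.name!r}) has no healthfulness class"
            )
        units.append(_Unit(occ.entity.health_class, occ.child_targeted,
                           occ.sports_related, occ.size_class))
    if area is AreaKind.FOOD and config.include_pricing_as_occasions:
        for rec in audit.pricing:
            if rec.triggered:
                units.append(_Unit(HealthClass.LEAST_HEALTHY, False, False, None))
    return units


def area_frequency(audit: SiteAudit, area: AreaKind,
                   config: ScoringConfig = DEFAULT_CONFIG) -> int:
    """Number of marketing occasions in an area (exposure frequency E_a).

    Triggered pricing indicators count as occasions in the food area.
    Unclassified entities are permitted here; only power computations
    require classification.
    """
    n = sum(1 for occ in audit.occasions if occ.area == area)
    if area is AreaKind.FOOD and config.include_pricing_as_occasions:
        n += sum(1 for rec in audit.pricing if rec.triggered)
    return n


def power_profile(audit: SiteAudit, area: AreaKind,
                  config: ScoringConfig = DEFAULT_CONFIG) -> PowerProfile:
    """Proportions of powerful characteristics among an area's occasions."""
    units = _area_units(audit, area, config)
    n = len(units)
    if n == 0:
        return PowerProfile()
    sized = [u.size.score_value for u in units if u.size is not None]
    return PowerProfile(
        p_least=sum(u.health is HealthClass.LEAST_HEALTHY for u in units) / n,
        p_less=sum(u.health is HealthClass.LESS_HEALTHY for u in units) / n,
        p_child=sum(u.child for u in units) / n,
        p_sport=sum(u.sport for u in units) / n,
        mean_size=(sum(sized) / len(sized)) if sized else 0.0,
        n_occasions=n,
        n_sized=len(sized),
    )


def repetition_count(audit: SiteAudit, threshold: int = 3) -> int:
    """Distinct (entity name, kind) pairs recorded >= ``threshold`` times
    site-wide, across all areas.  Pricing indicators carry no entity and
    never contribute."""
    if threshold < 2:
        raise ValueError(f"repetition threshold must be >= 2, got {threshold}")
    counts = Counter(occ.entity.key for occ in audit.occasions)
    return sum(1 for c in counts.values() if c >= threshold)


def _unit_points(unit: _Unit, config: ScoringConfig) -> float:
    content = _CONTENT_VALUE.get(unit.health, config.w_less_fraction)
    return (
        1.0
        + config.w_content * content
        + config.w_child * (1.0 if unit.child else 0.0)
        + config.w_sport * (1.0 if unit.sport else 0.0)
        + config.w_size * (unit.size.score_value if unit.size is not None else 0.0)
    )


def area_score(audit: SiteAudit, area: AreaKind,
               config: ScoringConfig = DEFAULT_CONFIG) -> float:
    """Area score A_a: one exposure point plus weighted power points per
    occasion, summed over the area.  Zero for an empty area."""
    return sum(_unit_points(u, config) for u in _area_units(audit, area, config))


def site_score(audit: SiteAudit, config: ScoringConfig = DEFAULT_CONFIG) -> ScoreBreakdown:
    """Score a site: S = sum of area scores + w_repetition x repetition count.

    Higher totals represent higher exposure to, and more powerful
    (unhealthy, child-targeted, sports-related, large) food marketing.
    The total is zero exactly when the audit records nothing.
    """
    frequency = {a: area_frequency(audit, a, config) for a in AreaKind}
    power = {a: power_profile(audit, a, config) for a in AreaKind}
    scores = {a: area_score(audit, a, config) for a in AreaKind}
    rep = repetition_count(audit, config.repetition_threshold)
    total = sum(scores.values()) + config.w_repetition * rep
    return ScoreBreakdown(
        site_id=audit.site_id,
        frequency=frequency,
        power=power,
        area_scores=scores,
        repetition_count=rep,
        total=total,
        config=config,
    )
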