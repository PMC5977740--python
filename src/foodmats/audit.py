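"""Domain types and file I/O for settings-based food-marketing audits.

An *audit* records every food or beverage **marketing occasion** a trained
rater observed in one site (a single building of a recreation/sport
facility), together with the site's pricing indicators and two size
covariates (number of concessions, number of sports areas).

A marketing occasion is any commercial advertising, promotion, or messaging
of a food or beverage product, brand, or retailer; product packaging is not
an occasion.  Each occasion is tied to one of 37 audit items — 26 location
items (windows, scoreboards, checkouts, ...) and 11 pricing indicators —
and to one of three facility areas: food (concession), sports, or other.

File formats
------------
``CSV``: one row per occasion, UTF-8, comma-delimited, header required.
Core columns::

    site_id, area, item_id, entity_name, entity_kind, health_class,
    child_targeted, sports_related, size_class, setting

Optional columns ``indicator_id`` and ``triggered`` encode pricing-indicator
rows (which leave the occasion columns empty), and ``n_concessions`` /
``n_sports_areas`` carry the site covariates (repeated on every row; a file
may consist of a single covariate-only row when no marketing was observed).
Booleans are serialized as ``true``/``false``; a missing ``size_class`` is an
empty field (size is excluded for some pricing and place occasions).
Unknown columns are ignored with a logged warning.

``JSON`` mirrors the CSV fields with ``occasions`` and ``pricing`` arrays and
an embedded ``schema_version`` string.

Two geographically separate buildings are two sites; no merge operation is
offered.
"""

from __future__ import annotations

import csv
import enum
import json
import logging
from pathlib import Path
from typing import Iterable, Optional

from pydantic import BaseModel, Field, ValidationError

from .errors import AuditValidationError

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"

#: 26 location items followed by 11 pricing items; the two id sets are disjoint.
N_LOCATION_ITEMS = 26
N_PRICING_INDICATORS = 11
LOCATION_ITEM_IDS = tuple(range(1, N_LOCATION_ITEMS + 1))
PRICING_ITEM_IDS = tuple(range(N_LOCATION_ITEMS + 1, N_LOCATION_ITEMS + N_PRICING_INDICATORS + 1))
ALL_ITEM_IDS = LOCATION_ITEM_IDS + PRICING_ITEM_IDS


def pricing_item_id(indicator_id: int) -> int:
    """Map a pricing indicator id (1..11) onto the audit item-id space (27..37)."""
    return N_LOCATION_ITEMS + indicator_id


class HealthClass(enum.IntEnum):
    """Ordered healthfulness class for products, brands, and retailers.

    The ordering MOST < LESS < LEAST is score-relevant: "Least Healthy"
    content is the most 'powerful' marketing.
    """

    MOST_HEALTHY = 0
    LESS_HEALTHY = 1
    LEAST_HEALTHY = 2

    @classmethod
    def parse(cls, token: str) -> "HealthClass":
        t = str(token).strip().lower()
        aliases = {
            "most": cls.MOST_HEALTHY, "most_healthy": cls.MOST_HEALTHY,
            "less": cls.LESS_HEALTHY, "less_healthy": cls.LESS_HEALTHY,
            "least": cls.LEAST_HEALTHY, "least_healthy": cls.LEAST_HEALTHY,
        }
        if t not in aliases:
            raise ValueError(f"unknown health class {token!r}")
        return aliases[t]

    @property
    def token(self) -> str:
        return self.name.lower()


class SizeClass(enum.IntEnum):
    """Ordered physical-size class of a promotion, in letter-sheet terms."""

    SMALL = 0
    MEDIUM = 1
    LARGE = 2

    @classmethod
    def parse(cls, token: str) -> "SizeClass":
        t = str(token).strip().upper()
        if t not in cls.__members__:
            raise ValueError(f"unknown size class {token!r}")
        return cls[t]

    @property
    def token(self) -> str:
        return self.name.lower()

    @property
    def score_value(self) -> float:
        """Numeric size used by the scoring algorithm: SMALL 0, MEDIUM 0.5, LARGE 1."""
        return self.value / 2.0


class AreaKind(str, enum.Enum):
    """The three facility areas every audit item maps into."""

    FOOD = "food"
    SPORT = "sport"
    OTHER = "other"


class Setting(str, enum.Enum):
    INDOOR = "indoor"
    OUTDOOR = "outdoor"


class EntityKind(str, enum.Enum):
    PRODUCT = "product"
    BRAND = "brand"
    RETAILER = "retailer"


class MarketedEntity(BaseModel):
    """A product, brand, or retailer featured in a marketing occasion.

    ``(name, kind)`` is the identity used for repetition counting.
    ``health_class`` may be left unset until post-audit classification.
    """

    name: str = Field(min_length=1)
    kind: EntityKind
    health_class: Optional[HealthClass] = None

    @property
    def key(self) -> tuple[str, EntityKind]:
        return (self.name, self.kind)


class MarketingOccasion(BaseModel):
    """One observed promotion of a food/beverage product, brand, or retailer."""

    site_id: str = Field(min_length=1)
    area: AreaKind
    item_id: int = Field(ge=1, le=37)
    entity: MarketedEntity
    child_targeted: bool = False
    sports_related: bool = False
    size_class: Optional[SizeClass] = None
    setting: Setting = Setting.INDOOR


class PricingIndicatorRecord(BaseModel):
    """One of the 11 pricing indicators for a site.

    A triggered indicator (pricing that encourages overeating, repeat
    visits, or makes unhealthy options cheaper) is classified
    "Least Healthy"; an untriggered one carries no classification.
    """

    indicator_id: int = Field(ge=1, le=N_PRICING_INDICATORS)
    triggered: bool
    classification: Optional[HealthClass] = None


class SiteAudit(BaseModel):
    """Everything observed in one site: the unit of scoring."""

    site_id: str = Field(min_length=1)
    occasions: list[MarketingOccasion] = Field(default_factory=list)
    pricing: list[PricingIndicatorRecord] = Field(default_factory=list)
    n_concessions: int = Field(default=0, ge=0)
    n_sports_areas: int = Field(default=0, ge=0)


class RaterAudit(BaseModel):
    """One rater's completed audit plus the per-item presence checklist."""

    rater_id: str = Field(min_length=1)
    audit: SiteAudit
    item_presence: dict[int, bool]


def derive_item_presence(audit: SiteAudit) -> dict[int, bool]:
    """Presence flags for all 37 items implied by an audit.

    A location item is present when at least one occasion references it; a
    pricing item is present when its indicator was triggered.
    """
    present = {i: False for i in ALL_ITEM_IDS}
    for occ in audit.occasions:
        present[occ.item_id] = True
    for rec in audit.pricing:
        if rec.triggered:
            present[pricing_item_id(rec.indicator_id)] = True
    return present


def validate_audit(audit: SiteAudit) -> list[str]:
    """Check cross-record invariants; returns messages (never raises).

    The verdict is deterministic and does not depend on record order.
    """
    violations: list[str] = []
    for i, occ in enumerate(sorted(audit.occasions, key=lambda o: (o.item_id, o.entity.name))):
        if occ.site_id != audit.site_id:
            violations.append(
                f"occasion (item {occ.item_id}, entity {occ.entity.name!r}) has "
                f"site_id {occ.site_id!r}, expected {audit.site_id!r}"
            )
    if len(audit.pricing) > N_PRICING_INDICATORS:
        violations.append(
            f"{len(audit.pricing)} pricing records exceed the {N_PRICING_INDICATORS} indicators"
        )
    seen: dict[int, int] = {}
    for rec in audit.pricing:
        seen[rec.indicator_id] = seen.get(rec.indicator_id, 0) + 1
    for ind_id in sorted(k for k, v in seen.items() if v > 1):
        violations.append(f"duplicate pricing indicator_id {ind_id}")
    for rec in sorted(audit.pricing, key=lambda r: r.indicator_id):
        if rec.triggered and rec.classification != HealthClass.LEAST_HEALTHY:
            violations.append(
                f"triggered pricing indicator {rec.indicator_id} must be classified least_healthy"
            )
        if not rec.triggered and rec.classification is not None:
            violations.append(
                f"untriggered pricing indicator {rec.indicator_id} must carry no classification"
            )
    return violations


def validate_rater_audit(rater: RaterAudit) -> list[str]:
    """Validate a rater audit: base-audit invariants plus checklist coverage."""
    violations = validate_audit(rater.audit)
    missing = sorted(set(ALL_ITEM_IDS) - set(rater.item_presence))
    if missing:
        violations.append(f"item_presence missing items {missing}")
    implied = derive_item_presence(rater.audit)
    for item_id in ALL_ITEM_IDS:
        if implied[item_id] and not rater.item_presence.get(item_id, False):
            violations.append(
                f"item {item_id} has recorded occasions but presence flag is false"
            )
    return violations


# ---------------------------------------------------------------------------
# Serialization

_CORE_COLUMNS = [
    "site_id", "area", "item_id", "entity_name", "entity_kind", "health_class",
    "child_targeted", "sports_related", "size_class", "setting",
]
_OPT_COLUMNS = ["indicator_id", "triggered", "n_concessions", "n_sports_areas"]
_ALL_COLUMNS = _CORE_COLUMNS + _OPT_COLUMNS

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


def _parse_bool(token: str, field: str) -> bool:
    t = str(token).strip().lower()
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    raise ValueError(f"field {field!r}: {token!r} is not a boolean")


def _blank(value) -> bool:
    return value is None or str(value).strip() == ""


def _occasion_from_row(row: dict, rownum: int) -> MarketingOccasion:
    try:
        size = None if _blank(row.get("size_class")) else SizeClass.parse(row["size_class"])
        health = None if _blank(row.get("health_class")) else HealthClass.parse(row["health_class"])
        return MarketingOccasion(
            site_id=str(row["site_id"]).strip(),
            area=AreaKind(str(row["area"]).strip().lower()),
            item_id=int(row["item_id"]),
            entity=MarketedEntity(
                name=str(row["entity_name"]).strip(),
                kind=EntityKind(str(row["entity_kind"]).strip().lower()),
                health_class=health,
            ),
            child_targeted=_parse_bool(row.get("child_targeted", "false"), "child_targeted"),
            sports_related=_parse_bool(row.get("sports_related", "false"), "sports_related"),
            size_class=size,
            setting=Setting(str(row.get("setting") or "indoor").strip().lower()),
        )
    except (ValueError, KeyError, ValidationError) as exc:
        raise AuditValidationError(f"row {rownum}: invalid occasion: {exc}") from exc


def _pricing_from_row(row: dict, rownum: int) -> PricingIndicatorRecord:
    try:
        triggered = _parse_bool(row.get("triggered", "false"), "triggered")
        return PricingIndicatorRecord(
            indicator_id=int(row["indicator_id"]),
            triggered=triggered,
            classification=HealthClass.LEAST_HEALTHY if triggered else None,
        )
    except (ValueError, KeyError, ValidationError) as exc:
        raise AuditValidationError(f"row {rownum}: invalid pricing record: {exc}") from exc


def load_audit(path: str | Path, format: str | None = None) -> SiteAudit:
    """Read and validate a site audit from CSV or JSON.

    ``format`` is inferred from the file suffix when omitted.  Schema
    violations raise :class:`AuditValidationError` naming the row and field.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        return _load_csv(path)
    if fmt == "json":
        return _load_json(path)
    raise AuditValidationError(f"{path}: unsupported format {fmt!r} (expected csv or json)")


def _load_csv(path: Path) -> SiteAudit:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise AuditValidationError(f"{path}: empty file (header required)")
        unknown = [c for c in reader.fieldnames if c not in _ALL_COLUMNS]
        if unknown:
            logger.warning("%s: ignoring unknown columns %s", path, unknown)
        missing = [c for c in ("site_id",) if c not in reader.fieldnames]
        if missing:
            raise AuditValidationError(f"{path}: missing required columns {missing}")
        rows = list(reader)
    if not rows:
        raise AuditValidationError(f"{path}: no data rows")

    site_id: Optional[str] = None
    occasions: list[MarketingOccasion] = []
    pricing: list[PricingIndicatorRecord] = []
    n_concessions = 0
    n_sports_areas = 0
    for rownum, row in enumerate(rows, start=2):  # header is line 1
        rid = str(row.get("site_id") or "").strip()
        if not rid:
            raise AuditValidationError(f"row {rownum}: field 'site_id': empty")
        if site_id is None:
            site_id = rid
        elif rid != site_id:
            raise AuditValidationError(
                f"row {rownum}: field 'site_id': {rid!r} differs from {site_id!r} "
                "(one file per site)"
            )
        for field, setter in (("n_concessions", "n_concessions"), ("n_sports_areas", "n_sports_areas")):
            if not _blank(row.get(field)):
                try:
                    value = int(row[field])
                except ValueError as exc:
                    raise AuditValidationError(f"row {rownum}: field {field!r}: {exc}") from exc
                if setter == "n_concessions":
                    n_concessions = value
                else:
                    n_sports_areas = value
        if not _blank(row.get("indicator_id")):
            pricing.append(_pricing_from_row(row, rownum))
        elif not _blank(row.get("item_id")) or not _blank(row.get("area")):
            occasions.append(_occasion_from_row(row, rownum))
        # else: covariate-only row

    try:
        return SiteAudit(
            site_id=site_id,
            occasions=occasions,
            pricing=pricing,
            n_concessions=n_concessions,
            n_sports_areas=n_sports_areas,
        )
    except ValidationError as exc:
        raise AuditValidationError(f"{path}: {exc}") from exc


def _load_json(path: Path) -> SiteAudit:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    known = {"schema_version", "site_id", "n_concessions", "n_sports_areas", "occasions", "pricing"}
    unknown = sorted(set(payload) - known)
    if unknown:
        logger.warning("%s: ignoring unknown keys %s", path, unknown)
    occasions = []
    for i, occ in enumerate(payload.get("occasions", [])):
        row = dict(occ)
        row.setdefault("site_id", payload.get("site_id"))
        occasions.append(_occasion_from_row(row, i))
    pricing = [_pricing_from_row(dict(rec), i) for i, rec in enumerate(payload.get("pricing", []))]
    try:
        return SiteAudit(
            site_id=str(payload["site_id"]),
            occasions=occasions,
            pricing=pricing,
            n_concessions=int(payload.get("n_concessions", 0)),
            n_sports_areas=int(payload.get("n_sports_areas", 0)),
        )
    except (KeyError, ValueError, ValidationError) as exc:
        raise AuditValidationError(f"{path}: {exc}") from exc


def _occasion_row(occ: MarketingOccasion, audit: SiteAudit) -> dict:
    return {
        "site_id": occ.site_id,
        "area": occ.area.value,
        "item_id": occ.item_id,
        "entity_name": occ.entity.name,
        "entity_kind": occ.entity.kind.value,
        "health_class": "" if occ.entity.health_class is None else occ.entity.health_class.token,
        "child_targeted": "true" if occ.child_targeted else "false",
        "sports_related": "true" if occ.sports_related else "false",
        "size_class": "" if occ.size_class is None else occ.size_class.token,
        "setting": occ.setting.value,
        "indicator_id": "",
        "triggered": "",
        "n_concessions": audit.n_concessions,
        "n_sports_areas": audit.n_sports_areas,
    }


def _pricing_row(rec: PricingIndicatorRecord, audit: SiteAudit) -> dict:
    row = {c: "" for c in _ALL_COLUMNS}
    row.update(
        site_id=audit.site_id,
        indicator_id=rec.indicator_id,
        triggered="true" if rec.triggered else "false",
        n_concessions=audit.n_concessions,
        n_sports_areas=audit.n_sports_areas,
    )
    return row


def save_audit(audit: SiteAudit, path: str | Path, format: str | None = None) -> Path:
    """Write an audit to CSV or JSON; loading it back yields an identical audit."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        rows: list[dict] = [_occasion_row(o, audit) for o in audit.occasions]
        rows += [_pricing_row(p, audit) for p in audit.pricing]
        if not rows:  # covariate-only row keeps empty audits round-trippable
            row = {c: "" for c in _ALL_COLUMNS}
            row.update(site_id=audit.site_id, n_concessions=audit.n_concessions,
                       n_sports_areas=audit.n_sports_areas)
            rows = [row]
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=_ALL_COLUMNS)
            writer.writeheader()
            writer.writerows(rows)
    elif fmt == "json":
        payload = {
            "schema_version": SCHEMA_VERSION,
            "site_id": audit.site_id,
            "n_concessions": audit.n_concessions,
            "n_sports_areas": audit.n_sports_areas,
            "occasions": [
                {k: v for k, v in _occasion_row(o, audit).items()
                 if k in _CORE_COLUMNS and k != "site_id"}
                for o in audit.occasions
            ],
            "pricing": [
                {"indicator_id": p.indicator_id,
                 "triggered": "true" if p.triggered else "false"}
                for p in audit.pricing
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
    else:
        raise AuditValidationError(f"{path}: unsupported format {fmt!r}")
    return path


def load_audits(paths: Iterable[str | Path]) -> list[SiteAudit]:
    """Convenience loader for a batch of audit files."""
    return [load_audit(p) for p in paths]
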