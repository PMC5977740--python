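import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from foodmats.audit import (
    AreaKind, EntityKind, HealthClass, MarketedEntity, MarketingOccasion,
    Setting, SiteAudit, SizeClass,
)
from foodmats.classification import classify_pricing


def make_occasion(
    site_id="site_a",
    area=AreaKind.FOOD,
    item_id=1,
    name="brand_x",
    kind=EntityKind.BRAND,
    health=HealthClass.LEAST_HEALTHY,
    child=False,
    sport=False,
    size=SizeClass.MEDIUM,
    setting=Setting.INDOOR,
):
    return MarketingOccasion(
        site_id=site_id,
        area=area,
        item_id=item_id,
        entity=MarketedEntity(name=name, kind=kind, health_class=health),
        child_targeted=child,
        sports_related=sport,
        size_class=size,
        setting=setting,
    )


@pytest.fixture
def empty_audit():
    return SiteAudit(site_id="site_a", n_concessions=1, n_sports_areas=2)


@pytest.fixture
def small_audit():
    """Three classified occasions plus two triggered pricing indicators."""
    return SiteAudit(
        site_id="site_a",
        occasions=[
            make_occasion(item_id=1, name="cola", kind=EntityKind.PRODUCT,
                          health=HealthClass.LEAST_HEALTHY, child=True,
                          size=SizeClass.LARGE),
            make_occasion(item_id=2, area=AreaKind.SPORT, name="water_co",
                          health=HealthClass.MOST_HEALTHY, sport=True,
                          size=SizeClass.SMALL),
            make_occasion(item_id=3, area=AreaKind.OTHER, name="granola",
                          kind=EntityKind.PRODUCT,
                          health=HealthClass.LESS_HEALTHY, size=None),
        ],
        pricing=[classify_pricing(1, True), classify_pricing(2, True),
                 classify_pricing(3, False)],
        n_concessions=1,
        n_sports_areas=3,
    )
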