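"""Site scoring: worked examples, invariants, and the brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from foodmats.audit import (
    AreaKind, EntityKind, HealthClass, SiteAudit, SizeClass,
)
from foodmats.classification import classify_pricing
from foodmats.errors import UnclassifiedError
from foodmats.scoring import (
    ScoringConfig, area_frequency, area_score, power_profile,
    repetition_count, site_score,
)
from conftest import make_occasion
from oracles import score_brute


def audit_of(occasions, pricing=(), site_id="site_a"):
    return SiteAudit(site_id=site_id, occasions=list(occasions),
                     pricing=list(pricing))


class TestAreaFrequency:
    def test_direct_count(self):
        audit = audit_of([make_occasion(item_id=i) for i in (1, 2, 3)])
        assert area_frequency(audit, AreaKind.FOOD) == 3
        assert area_frequency(audit, AreaKind.SPORT) == 0

    def test_empty_audit(self, empty_audit):
        assert all(area_frequency(empty_audit, a) == 0 for a in AreaKind)

    def test_triggered_pricing_counts_in_food(self):
        audit = audit_of([], pricing=[classify_pricing(1, True),
                                      classify_pricing(2, True),
                                      classify_pricing(3, False)])
        assert area_frequency(audit, AreaKind.FOOD) == 2
        assert area_frequency(audit, AreaKind.SPORT) == 0

    def test_pricing_exclusion_configurable(self):
        audit = audit_of([], pricing=[classify_pricing(1, True)])
        cfg = ScoringConfig(include_pricing_as_occasions=False)
        assert area_frequency(audit, AreaKind.FOOD, cfg) == 0


class TestPowerProfile:
    def test_proportions(self):
        occasions = (
            [make_occasion(item_id=i, health=HealthClass.LEAST_HEALTHY) for i in (1, 2)]
            + [make_occasion(item_id=i, health=HealthClass.MOST_HEALTHY) for i in (3, 4)]
        )
        profile = power_profile(audit_of(occasions), AreaKind.FOOD)
        assert profile.p_least == 0.5
        assert profile.p_less == 0.0

    def test_empty_area_all_zero(self, empty_audit):
        profile = power_profile(empty_audit, AreaKind.OTHER)
        assert (profile.p_least, profile.p_less, profile.p_child,
                profile.p_sport, profile.mean_size) == (0, 0, 0, 0, 0)

    def test_mean_size_averages_sized_occasions_only(self):
        occasions = [make_occasion(item_id=1, size=SizeClass.LARGE),
                     make_occasion(item_id=2, size=SizeClass.SMALL),
                     make_occasion(item_id=3, size=None)]
        profile = power_profile(audit_of(occasions), AreaKind.FOOD)
        assert profile.mean_size == 0.5  # mean of 1 and 0
        assert profile.n_sized == 2

    def test_unclassified_entity_names_occasion(self):
        audit = audit_of([make_occasion(health=None, name="mystery")])
        with pytest.raises(UnclassifiedError, match="mystery"):
            power_profile(audit, AreaKind.FOOD)


class TestRepetition:
    def test_threshold_exactly_three(self):
        three = audit_of([make_occasion(item_id=i) for i in (1, 2, 3)])
        two = audit_of([make_occasion(item_id=i) for i in (1, 2)])
        assert repetition_count(three) == 1
        assert repetition_count(two) == 0

    def test_empty_audit(self, empty_audit):
        assert repetition_count(empty_audit) == 0

    def test_counting_is_site_wide_across_areas(self):
        split = audit_of([
            make_occasion(item_id=1, area=AreaKind.FOOD),
            make_occasion(item_id=2, area=AreaKind.SPORT),
            make_occasion(item_id=3, area=AreaKind.OTHER),
        ])
        assert repetition_count(split) == 1

    def test_same_name_different_kind_is_distinct(self):
        occasions = (
            [make_occasion(item_id=i, kind=EntityKind.BRAND) for i in (1, 2)]
            + [make_occasion(item_id=3, kind=EntityKind.PRODUCT)]
        )
        assert repetition_count(audit_of(occasions)) == 0


class TestWorkedExamples:
    def test_single_most_healthy_plain_small_scores_one(self):
        audit = audit_of([make_occasion(health=HealthClass.MOST_HEALTHY,
                                        size=SizeClass.SMALL)])
        assert area_score(audit, AreaKind.FOOD) == 1.0
        assert site_score(audit).total == 1.0

    def test_single_maximal_occasion_scores_five(self):
        audit = audit_of([make_occasion(health=HealthClass.LEAST_HEALTHY,
                                        child=True, sport=True,
                                        size=SizeClass.LARGE)])
        assert area_score(audit, AreaKind.FOOD) == 5.0

    def test_three_repeats_of_maximal_brand(self):
        audit = audit_of([make_occasion(item_id=i, health=HealthClass.LEAST_HEALTHY,
                                        child=True, sport=True, size=SizeClass.LARGE)
                          for i in (1, 2, 3)])
        breakdown = site_score(audit)
        assert breakdown.total == 17.0  # 3 x 5 + 2 x 1
        assert breakdown.repetition_count == 1

    def test_empty_audit_scores_zero(self, empty_audit):
        breakdown = site_score(empty_audit)
        assert breakdown.total == 0.0
        assert all(v == 0 for v in breakdown.area_scores.values())

    def test_breakdown_total_consistent_with_components(self, small_audit):
        b = site_score(small_audit)
        assert b.total == pytest.approx(
            sum(b.area_scores.values()) + b.config.w_repetition * b.repetition_count)


occasion_strategy = st.builds(
    make_occasion,
    area=st.sampled_from(AreaKind),
    item_id=st.integers(1, 26),
    name=st.sampled_from(["a", "b", "c"]),
    kind=st.sampled_from(EntityKind),
    health=st.sampled_from(HealthClass),
    child=st.booleans(),
    sport=st.booleans(),
    size=st.one_of(st.none(), st.sampled_from(SizeClass)),
)


class TestInvariants:
    @settings(max_examples=60, deadline=None)
    @given(occasions=st.lists(occasion_strategy, max_size=6),
           pricing_triggers=st.lists(st.booleans(), max_size=5))
    def test_matches_brute_force_oracle(self, occasions, pricing_triggers):
        pricing = [classify_pricing(i + 1, t) for i, t in enumerate(pricing_triggers)]
        audit = audit_of(occasions, pricing)
        assert site_score(audit).total == pytest.approx(score_brute(audit), abs=1e-12)

    @settings(max_examples=40, deadline=None)
    @given(occasions=st.lists(occasion_strategy, max_size=5),
           extra=occasion_strategy)
    def test_appending_an_occasion_never_decreases_total(self, occasions, extra):
        base = site_score(audit_of(occasions)).total
        grown = site_score(audit_of(occasions + [extra])).total
        assert grown >= base

    @settings(max_examples=40, deadline=None)
    @given(occasions=st.lists(occasion_strategy, min_size=1, max_size=5),
           index=st.integers(0, 4))
    def test_upgrading_power_never_decreases_total(self, occasions, index):
        index %= len(occasions)
        base = site_score(audit_of(occasions)).total
        target = occasions[index]
        upgrades = [
            target.model_copy(update={"entity": target.entity.model_copy(
                update={"health_class": HealthClass.LEAST_HEALTHY})}),
            target.model_copy(update={"child_targeted": True}),
            target.model_copy(update={"sports_related": True}),
            target.model_copy(update={"size_class": SizeClass.LARGE}),
        ]
        for upgraded in upgrades:
            modified = list(occasions)
            modified[index] = upgraded
            assert site_score(audit_of(modified)).total >= base

    @settings(max_examples=30, deadline=None)
    @given(occasions=st.lists(occasion_strategy, max_size=6))
    def test_pure_exposure_limit_counts_occasions(self, occasions):
        cfg = ScoringConfig(w_content=0, w_child=0, w_sport=0, w_size=0,
                            w_repetition=0)
        assert site_score(audit_of(occasions), cfg).total == len(occasions)

    @settings(max_examples=30, deadline=None)
    @given(occasions=st.lists(occasion_strategy, min_size=3, max_size=3),
           areas=st.tuples(*[st.sampled_from(AreaKind)] * 3))
    def test_repetition_unchanged_by_area_split(self, occasions, areas):
        same_entity = [o.model_copy(update={
            "area": area,
            "entity": occasions[0].entity.model_copy(),
        }) for o, area in zip(occasions, areas)]
        assert repetition_count(audit_of(same_entity)) == 1

    def test_total_zero_iff_empty(self):
        assert site_score(audit_of([])).total == 0
        one = audit_of([make_occasion(health=HealthClass.MOST_HEALTHY, size=None)])
        assert site_score(one).total > 0
        pricing_only = audit_of([], [classify_pricing(1, True)])
        assert site_score(pricing_only).total > 0
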