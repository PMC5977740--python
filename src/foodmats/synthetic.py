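"""Seeded generator of synthetic audits, rater pairs, and site outcomes.

The generator emulates the statistical structure of a multi-site audit
study so every analysis in the package can be exercised with known ground
truth: per-area occasion counts are Poisson, occasion attributes follow
configurable mixtures, entity names are drawn from a skewed (Zipf-like)
pool so some entities repeat three or more times per site, a second rater
is simulated by independently perturbing each recorded attribute with a
small probability, and sponsorship/sales outcomes are coupled to the site
score on the square-root scale (the scale on which those variables are
analysed).

Default parameters describe a medium-sized study: 50 sites averaging 18
marketing occasions each (8 food, 6 sport, 4 other), a marketing mix
dominated by Least-Healthy content (55%), a quarter of occasions
child-targeted and about a third sports-related, and outcome couplings
strong enough that food sponsorship correlates strongly with the score and
the score explains a substantial increment of variance in weekly
Least-Healthy concession sales over facility size.  Setting a coupling to zero yields the
corresponding null model.  A fixed seed fully determines all output.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .audit import (
    AreaKind, EntityKind, HealthClass, MarketedEntity, MarketingOccasion,
    RaterAudit, Setting, SiteAudit, SizeClass, derive_item_presence,
    N_LOCATION_ITEMS, N_PRICING_INDICATORS,
)
from .classification import classify_pricing
from .errors import DomainError
from .scoring import ScoringConfig, site_score
from .validity import OUTCOME_COLUMNS


class GeneratorParams(BaseModel):
    """All knobs of the synthetic study, with documented defaults."""

    n_sites: int = Field(default=50, ge=1)
    seed: int = 0

    # --- audit structure ---------------------------------------------------
    #: expected marketing occasions per area
    lambda_area: dict[AreaKind, float] = Field(
        default_factory=lambda: {AreaKind.FOOD: 8.0, AreaKind.SPORT: 6.0, AreaKind.OTHER: 4.0}
    )
    #: probabilities of (most, less, least) healthy entities
    health_mix: tuple[float, float, float] = (0.15, 0.30, 0.55)
    p_child: float = Field(default=0.25, ge=0, le=1)
    p_sport: float = Field(default=0.35, ge=0, le=1)
    #: probabilities of (small, medium, large) among sized occasions
    size_mix: tuple[float, float, float] = (0.35, 0.45, 0.20)
    #: fraction of occasions with no recorded size (some pricing/place occasions)
    p_unsized: float = Field(default=0.10, ge=0, le=1)
    p_outdoor: float = Field(default=0.20, ge=0, le=1)
    #: size of the shared entity pool and the Zipf exponent of its reuse
    entity_pool: int = Field(default=30, ge=1)
    entity_skew: float = Field(default=1.2, gt=0)
    #: probabilities of entity kinds (product, brand, retailer)
    kind_mix: tuple[float, float, float] = (0.5, 0.3, 0.2)
    p_pricing_trigger: float = Field(default=0.30, ge=0, le=1)
    #: covariates: n_concessions = 1 + Poisson(extra), n_sports_areas >= 1
    mean_extra_concessions: float = Field(default=0.3, ge=0)
    mean_sports_areas: float = Field(default=3.0, gt=0)

    # --- rater disagreement ------------------------------------------------
    rater_flip: float = Field(default=0.05, ge=0, lt=1)

    # --- outcome couplings (square-root scale) -----------------------------
    alpha_sponsorship: float = 0.0
    #: sqrt(food sponsorship $) gained per unit sqrt(score)
    beta_sponsorship: float = 6.0
    sponsorship_noise_sd: float = Field(default=3.0, ge=0)
    #: score-independent component of total sponsorship, sqrt-$ scale
    total_extra_sqrt_mean: float = 110.0
    total_extra_sqrt_sd: float = Field(default=40.0, ge=0)
    #: sqrt(weekly Least-Healthy sales $): intercept, per sports area, per score point
    gamma0_concession: float = 10.0
    gamma_sports_concession: float = 3.0
    gamma_score_concession: float = 0.5
    concession_noise_sd: float = Field(default=8.0, ge=0)
    gamma0_vending: float = 5.0
    gamma_sports_vending: float = 1.0
    gamma_score_vending: float = 0.15
    vending_noise_sd: float = Field(default=4.0, ge=0)

    # --- missingness -------------------------------------------------------
    p_missing_food_sponsorship: float = Field(default=0.30, ge=0, lt=1)
    p_missing_total_sponsorship: float = Field(default=0.35, ge=0, lt=1)
    p_missing_concession: float = Field(default=0.20, ge=0, lt=1)
    p_missing_vending: float = Field(default=0.25, ge=0, lt=1)

    @model_validator(mode="after")
    def _check_mixtures(self):
        for name in ("health_mix", "size_mix", "kind_mix"):
            mix = getattr(self, name)
            if any(p < 0 for p in mix) or not math.isclose(sum(mix), 1.0, abs_tol=1e-9):
                raise ValueError(f"{name} must be non-negative and sum to 1, got {mix}")
        if any(lam < 0 for lam in self.lambda_area.values()):
            raise ValueError("lambda_area rates must be non-negative")
        return self


def _entity_pool(params: GeneratorParams, rng: np.random.Generator) -> list[MarketedEntity]:
    """Fixed pool of classified entities; occasions sample from it with
    Zipf-skewed reuse so repetition occurs at a controllable rate."""
    kinds = rng.choice(len(EntityKind), size=params.entity_pool, p=list(params.kind_mix))
    healths = rng.choice(3, size=params.entity_pool, p=list(params.health_mix))
    kind_list = list(EntityKind)
    return [
        MarketedEntity(
            name=f"entity_{i:03d}",
            kind=kind_list[int(kinds[i])],
            health_class=HealthClass(int(healths[i])),
        )
        for i in range(params.entity_pool)
    ]


def _zipf_weights(n: int, skew: float) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1) ** skew
    return w / w.sum()


def generate_audits(params: GeneratorParams) -> list[SiteAudit]:
    """Generate ``n_sites`` fully classified site audits."""
    rng = np.random.default_rng(params.seed)
    pool = _entity_pool(params, rng)
    weights = _zipf_weights(params.entity_pool, params.entity_skew)
    size_classes = list(SizeClass)
    audits = []
    for s in range(params.n_sites):
        site_id = f"site_{s:03d}"
        occasions = []
        for area, lam in params.lambda_area.items():
            count = int(rng.poisson(lam))
            for _ in range(count):
                entity = pool[int(rng.choice(params.entity_pool, p=weights))]
                unsized = rng.random() < params.p_unsized
                occasions.append(MarketingOccasion(
                    site_id=site_id,
                    area=area,
                    item_id=int(rng.integers(1, N_LOCATION_ITEMS + 1)),
                    entity=entity.model_copy(),
                    child_targeted=bool(rng.random() < params.p_child),
                    sports_related=bool(rng.random() < params.p_sport),
                    size_class=None if unsized else size_classes[
                        int(rng.choice(3, p=list(params.size_mix)))],
                    setting=Setting.OUTDOOR if rng.random() < params.p_outdoor
                    else Setting.INDOOR,
                ))
        pricing = [
            classify_pricing(i + 1, bool(rng.random() < params.p_pricing_trigger))
            for i in range(N_PRICING_INDICATORS)
        ]
        audits.append(SiteAudit(
            site_id=site_id,
            occasions=occasions,
            pricing=pricing,
            n_concessions=1 + int(rng.poisson(params.mean_extra_concessions)),
            n_sports_areas=max(1, int(rng.poisson(params.mean_sports_areas))),
        ))
    return audits


def generate_rater_pair(
    audit: SiteAudit, flip: float, seed: int
) -> tuple[RaterAudit, RaterAudit]:
    """Simulate a two-rater design: rater 1 records the truth, rater 2 has
    each boolean/categorical attribute independently perturbed with
    probability ``flip``.

    Perturbations: boolean flags are negated; a recorded size moves to one
    of the other two classes uniformly; the marketed entity is replaced by
    a uniform draw from the other distinct entities in the audit; a pricing
    trigger is negated.  Occasion detection itself is not perturbed.
    """
    if not 0 <= flip < 1:
        raise DomainError(f"flip probability must be in [0, 1), got {flip}")
    rng = np.random.default_rng(seed)
    entity_keys: list[tuple] = []
    entities_by_key = {}
    for occ in audit.occasions:
        if occ.entity.key not in entities_by_key:
            entities_by_key[occ.entity.key] = occ.entity
            entity_keys.append(occ.entity.key)

    occasions2 = []
    for occ in audit.occasions:
        entity = occ.entity
        if len(entity_keys) > 1 and rng.random() < flip:
            others = [k for k in entity_keys if k != occ.entity.key]
            entity = entities_by_key[others[int(rng.integers(len(others)))]]
        child = occ.child_targeted ^ (rng.random() < flip)
        sport = occ.sports_related ^ (rng.random() < flip)
        size = occ.size_class
        if size is not None and rng.random() < flip:
            others_s = [s for s in SizeClass if s != size]
            size = others_s[int(rng.integers(2))]
        occasions2.append(occ.model_copy(update={
            "entity": entity.model_copy(),
            "child_targeted": bool(child),
            "sports_related": bool(sport),
            "size_class": size,
        }))
    pricing2 = [
        classify_pricing(rec.indicator_id, rec.triggered ^ (rng.random() < flip))
        for rec in audit.pricing
    ]
    audit2 = audit.model_copy(update={"occasions": occasions2, "pricing": pricing2})
    rater1 = RaterAudit(rater_id="rater_1", audit=audit,
                        item_presence=derive_item_presence(audit))
    rater2 = RaterAudit(rater_id="rater_2", audit=audit2,
                        item_presence=derive_item_presence(audit2))
    return rater1, rater2


def generate_outcomes(
    audits: list[SiteAudit],
    params: GeneratorParams,
    scoring_config: Optional[ScoringConfig] = None,
) -> pd.DataFrame:
    """Score the audits and attach sponsorship/sales outcomes.

    sqrt(food sponsorship) = alpha + beta * sqrt(score) + noise, floored at
    zero; total sponsorship adds a score-independent component (attenuating
    its correlation with the score).  sqrt(weekly Least-Healthy sales) =
    gamma0 + gamma_sports * n_sports_areas + gamma_score * score + noise
    per channel; total sales is the concession + vending sum and is present
    only when both channels are.  Missingness is applied per outcome.
    """
    cfg = scoring_config or ScoringConfig()
    rng = np.random.default_rng(params.seed + 1)  # independent of audit stream
    rows = []
    for audit in audits:
        score = site_score(audit, cfg).total
        sqrt_food = (params.alpha_sponsorship
                     + params.beta_sponsorship * math.sqrt(score)
                     + rng.normal(0.0, params.sponsorship_noise_sd))
        food = max(0.0, sqrt_food) ** 2
        extra = max(0.0, rng.normal(params.total_extra_sqrt_mean,
                                    params.total_extra_sqrt_sd)) ** 2
        total_spons = food + extra
        sqrt_conc = (params.gamma0_concession
                     + params.gamma_sports_concession * audit.n_sports_areas
                     + params.gamma_score_concession * score
                     + rng.normal(0.0, params.concession_noise_sd))
        conc = max(0.0, sqrt_conc) ** 2
        sqrt_vend = (params.gamma0_vending
                     + params.gamma_sports_vending * audit.n_sports_areas
                     + params.gamma_score_vending * score
                     + rng.normal(0.0, params.vending_noise_sd))
        vend = max(0.0, sqrt_vend) ** 2

        miss_food = rng.random() < params.p_missing_food_sponsorship
        miss_total = rng.random() < params.p_missing_total_sponsorship
        miss_conc = rng.random() < params.p_missing_concession
        miss_vend = rng.random() < params.p_missing_vending
        rows.append({
            "site_id": audit.site_id,
            "foodmats_score": score,
            "food_sponsorship": np.nan if miss_food else food,
            "total_sponsorship": np.nan if miss_total else total_spons,
            "sales_least_concession": np.nan if miss_conc else conc,
            "sales_least_vending": np.nan if miss_vend else vend,
            "sales_least_total": np.nan if (miss_conc or miss_vend) else conc + vend,
            "n_concessions": audit.n_concessions,
            "n_sports_areas": audit.n_sports_areas,
        })
    return pd.DataFrame(rows, columns=OUTCOME_COLUMNS)


def generate_study(params: GeneratorParams) -> tuple[list[SiteAudit], pd.DataFrame]:
    """Convenience wrapper: audits plus their outcome table."""
    audits = generate_audits(params)
    return audits, generate_outcomes(audits, params)
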