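# foodmats

Settings-based auditing of food and beverage marketing: a data model for
observational marketing audits, a site scoring algorithm, two-rater
reliability statistics, and a validity-analysis pipeline, plus a seeded
synthetic-study generator that makes all of it testable end to end.

## The problem

Children encounter food marketing in the places they gather — recreation
and sport facilities prominently among them — through many simultaneous
channels: signs, scoreboards, vending fronts, concession menus, pricing
promotions. Most food-environment instruments capture one channel or one
marketing approach at a time. This package implements a whole-setting audit
built around the four marketing-mix approaches (product, price, place,
promotion) and the exposure/power model of marketing impact: the effect of
marketing on food preferences, purchases, and consumption grows with the
*exposure* (reach and frequency) and *power* (persuasive design) of the
messages.

A trained rater walks a **site** (one building) and records every
**marketing occasion** — any commercial advertising, promotion, or
messaging of a food or beverage product, brand, or retailer (product
packaging excluded) — against 26 location items and 11 pricing indicators,
grouped into three facility areas: food (concession), sports, and other.
Each occasion carries the marketed entity, its ordered healthfulness class
(Most / Less / Least Healthy), child-targeted and sports-related technique
flags, and a physical size class measured in letter-sheet equivalents.

## The score

Each occasion contributes one exposure point plus weighted power points:

```
points(occ) = 1 + w_content·content + w_child·child + w_sport·sport + w_size·size
```

with `content` = 1 (Least Healthy), ½ (Less), 0 (Most); `size` = 0 / 0.5 / 1
for small / medium / large; and unit default weights. Triggered pricing
indicators enter the food area as Least-Healthy occasions. The site score
sums the three area scores and adds a repetition factor:

```
S = Σ_a A_a + w_repetition · R
```

where `R` counts distinct entities marketed ≥ 3 times site-wide. Higher
scores mean more, and more powerful (unhealthy, child-targeted,
sports-related, large), food marketing. Every constant is configurable
(`ScoringConfig`).

Around the score sit the audit psychometrics: percent agreement, Cohen's κ,
linear/quadratic weighted κ_w, and two-way random ICC(2,1)/ICC(2,k) with
95% CIs and interpretation bands for reliability; Pearson/Spearman/partial
correlations and sequential regression with ΔR² and F-change tests for
validity against sponsorship dollars and weekly "Least Healthy" sales.

## Worked example

```python
import foodmats as fm

cola = lambda: fm.MarketedEntity(name="Coca-Cola", kind=fm.EntityKind.BRAND,
                                 health_class=fm.classify_brand("Coca-Cola"))
audit = fm.SiteAudit(
    site_id="rink_a",
    occasions=[
        fm.MarketingOccasion(site_id="rink_a", area=fm.AreaKind.FOOD, item_id=3,
                             entity=cola(), sports_related=True,
                             size_class=fm.classify_size(6, fm.Setting.INDOOR)),
        fm.MarketingOccasion(site_id="rink_a", area=fm.AreaKind.SPORT, item_id=12,
                             entity=cola(), child_targeted=True, sports_related=True,
                             size_class=fm.SizeClass.MEDIUM),
        fm.MarketingOccasion(site_id="rink_a", area=fm.AreaKind.SPORT, item_id=14,
                             entity=cola(), sports_related=True,
                             size_class=fm.SizeClass.LARGE),
    ],
    pricing=[fm.classify_pricing(2, True)],   # cheaper pop than water
    n_concessions=1, n_sports_areas=3,
)
breakdown = fm.site_score(audit)
```

This prints, per area and in total:

```
area food: E=2 A=6.0      # 1 sports-related large Least-Healthy sign (4.0)
                          # + 1 triggered pricing indicator (2.0)
area sport: E=2 A=8.5     # 4.5 (child+sport, medium) + 4.0 (sport, large)
area other: E=0 A=0
repetition: 1 total: 16.5 # 6.0 + 8.5 + 2·1 (Coca-Cola seen 3 times)
```

Reliability works on paired rating vectors:

```python
r = fm.PairedRatings(x=[0]*50 + [1]*50, y=[0]*45 + [1]*5 + [0]*5 + [1]*45)
fm.cohens_kappa(r)   # kappa=0.800 CI=(0.682, 0.918) band=good
```

A full synthetic study — 50 audits, a rater pair, and outcome tables with
known couplings — is one command:

```bash
foodmats simulate --seed 5 --out study/
foodmats score study/audits/site_000.csv
foodmats reliability study/rater1.csv study/rater2.csv
foodmats validate study/outcomes.csv
```

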