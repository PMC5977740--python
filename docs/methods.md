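# Methods

This note documents the models, parameters, numerical conventions, and
open design choices behind the package, in the spirit of a statistical
software methods appendix. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The audit model

A *site* is one building; geographically separate buildings of the same
facility are separate sites and no merge operation is offered, because a
patron typically visits one building at a time. An audit records marketing
*occasions* (any commercial promotion of a food/beverage product, brand, or
retailer; product packaging excluded), one of 37 items each — item ids
1–26 are location items, and the 11 pricing indicators are mapped onto ids
27–37 so the two id sets are disjoint within one integer space. Pricing
indicators split 4 / 7: four concern overeating or repeat-visit rewards,
seven compare prices of healthy versus unhealthy options; their individual
semantics live in the editable rules config, since only the split and the
classification rule (triggered ⇒ Least Healthy) are fixed. The 26 location
labels are likewise opaque ids with an optional label table in config.

Healthfulness is a strictly ordered three-class scale
(Most < Less < Least Healthy), size a strictly ordered three-class scale
(small < medium < large). Size uses letter-sheet (8.5×11 in) equivalents
with closed medium intervals — 1–3 sheets indoors, 1–10 outdoors — so the
strict inequalities sit only on small (< 1) and large (> 3 / > 10);
consequently a sub-sheet promotion classifies identically indoors and
outdoors, a property the tests check.

Product classification is keyword/category driven rather than
nutrient-threshold driven: full nutrient data is rarely collectable for
everything marketed in a facility, so the default rule set encodes category
judgements (water → Most; granola bar → Less; cola, chips, ice cream →
Least) with an added-fat/sugar/salt override hook (`none`/`some`/`high` →
Most/Less/Least) for when composition is known. Keyword rules are an
*ordered* list — first match wins — so specific patterns ("chocolate milk",
"prepared grocery") must precede general ones ("chocolate", "grocery").
Brands classify as the product they most closely represent via an editable
brand map; retailers by category list, falling back to their most prominent
product. Anything unresolvable raises an explicit "assign manually" error
rather than guessing.

## The scoring algorithm

Scoring operationalises exposure × power. Each occasion contributes

    1 + w_content·content + w_child·child + w_sport·sport + w_size·size

with content ∈ {0, w_less_fraction, 1} for Most/Less/Least, size ∈
{0, 0.5, 1}, and flags in {0, 1}. Area scores sum these per-occasion
points; the site total adds `w_repetition · R`, with `R` the number of
distinct (entity name, kind) pairs recorded at least
`repetition_threshold` = 3 times site-wide.

Design notes:

* **Per-occasion additivity.** For areas in which every occasion carries a
  size, the area score is algebraically identical to the familiar
  `frequency × (1 + weighted power proportions)` form. We compute the sum
  rather than the product-of-means because occasions without a recorded
  size (excluded from the mean-size denominator) would otherwise let an
  appended occasion *lower* the total — the additive form is the unique
  version of the formula that keeps the score strictly monotone in
  exposure and in every power attribute, which is the ordering semantics
  the score exists to express. The reported `PowerProfile.mean_size` still
  averages over sized occasions only.
* **Half weight for Less Healthy** (`w_less_fraction` = 0.5) keeps the
  three-class ordering visible in the score; it is a tunable default.
* **Pricing indicators.** Each triggered indicator enters the food area as
  a Least-Healthy pseudo-occasion with no design flags and no size (and
  it joins the food-area content-proportion denominator). Whether pricing
  should enter the occasion count at all is a genuinely open choice;
  `include_pricing_as_occasions=False` confines it to nothing. Pricing
  pseudo-occasions carry no entity and never count toward repetition.
* **Defaults are unit weights** with `w_repetition` = 2. The qualitative
  properties — score rises with every occasion, every power upgrade, and
  repetition; zero exactly for an empty audit; pure-exposure limit equals
  the occasion count — hold for any non-negative weights and are checked
  exhaustively on all ≤ 4-occasion audits over a 12-template grid plus
  random audits. No claim is made that these constants reproduce any
  particular published site scores; the constants are config so an
  external point scheme can be dropped in.

## Reliability statistics

Kappa is computed from the 2-rater contingency table as
κ = (p_o − p_e)/(1 − p_e), weighted form via agreement weights
`1 − |i−j|/(k−1)` (linear, the conservative convention for 3-level ordinal
scales and therefore the default) or `1 − ((i−j)/(k−1))²` (quadratic);
identity weights recover unweighted κ, and on two categories all schemes
coincide. Confidence intervals use the Fleiss–Cohen–Everitt asymptotic
variance (the estimates and variances agree with
`statsmodels.stats.inter_rater.cohens_kappa` to machine precision — see the
tests); significance is a z-test against the κ = 0 variance. The upper CI
bound is clipped at 1. Degenerate conventions: perfect agreement on a
single observed category returns κ = 1 with a warning (p_e = 1 makes the
ratio formally undefined, but the data contain no disagreement); chance
agreement of 1 with imperfect agreement raises an error.

ICCs are two-way random-effects, absolute agreement, computed through
`pingouin.intraclass_corr`: ICC(2,1) for a single rater's measurement and
ICC(2,k) for the k-rater average, with F-based 95% CIs. Both forms are
always reported because instrument users may deploy one rater or average
two. When the residual mean square is exactly zero the F-based interval
degenerates and is collapsed to the point estimate. Zero between-subject
variance raises an undefined-statistic error. Occasion counts are
square-root transformed before the ICC to improve normality.

Interpretation bands reproduce the source conventions for this instrument
family verbatim: κ 0.0–0.2 "fair", 0.21–0.40 "poor", 0.41–0.60 "moderate",
0.61–0.80 "good", 0.81–1.00 "very good"; ICC < 0.40 "poor", 0.40–0.59
"fair", 0.60–0.74 "good", 0.75–1.00 "excellent". The first two κ labels run
opposite to the usual Landis–Koch ordering; they are implemented as
published, with `corrected_low_bands=True` to swap them.

The per-site reliability report restricts the entity/child/sports/size
rows to occasions both raters identified, matching on the
`(area, item_id, entity)` key with duplicates paired after a stable sort —
the narrowest defensible definition of "co-identified", under which the
entity row reaches κ = 1 whenever both raters record the same entities.
Unmatched occasions still count toward the presence and per-area-count
rows. Rows whose statistic is undefined are emitted with a note, never
silently dropped.

## Validity pipeline

Transforms and truncation come first: scores and sponsorship dollars are
square-root transformed, then outliers beyond mean ± 3 sample SDs (SD
computed with the n−1 estimator, outliers included) are truncated to one
unit above the most extreme value inside the threshold, per offending
value, iterating to a fixed point so truncation is idempotent; every
replacement is logged. "One unit" is on the analysed (transformed) scale
and configurable. Sales are square-root transformed as outcomes; the score
enters regressions untransformed.

Weekly Least-Healthy sales take itemized two-week sales tables, classify
each row with the product rules, sum Least-Healthy dollars per channel,
and halve. Channels containing unclassifiable rows are flagged excluded
(the analogue of discarding poorly itemized data) rather than partially
summed.

Correlations report Pearson, Spearman, and partial Pearson r; the partial
correlation controls for facility size as *two separate covariates*
(number of concessions, number of sports areas) and is computed through
`pingouin.partial_corr` (degrees-of-freedom-correct p-values); the
residual-regression identity is enforced in tests at 1e-10. Total
sponsorship is screened for a linear relationship with the score first and
analysis stops there when the screen fails, with a log entry.

Sequential regression standardizes all variables and fits nested OLS
models (facility size; then size + score) via statsmodels, reporting
standardized betas with 95% CIs, R², adjusted R², ΔR², and
F-change = (ΔR²/Δk)/((1−R²_full)/(n−k_full−1)) with its F-test p-value.
Predictors correlated beyond |r| > 0.7 are screened first; the member not
itself associated with the outcome (p ≥ 0.05) is recommended for dropping,
and the pipeline never drops the score itself — collinearity is resolved
against the size covariates. Missing-data impact uses Welch's t-test
(unequal variances, the safer default for an unspecified "independent
t-test") comparing mean scores of sites with and without each outcome.
Significance is two-sided p < 0.05 throughout with no multiple-testing
correction, matching the analysis conventions this pipeline mirrors.

## Synthetic studies

The generator emulates the structure the analyses assume, not any real
dataset. Defaults describe a medium multi-site study: 50 sites; per-area
occasion counts Poisson with means 8 (food), 6 (sport), 4 (other) — the
minimal count model, with nothing in the audit design suggesting
overdispersion; entity pool of 30 with Zipf(1.2) reuse so repetition ≥ 3
occurs at a realistic rate; healthfulness mixture (0.15, 0.30, 0.55)
dominated by Least-Healthy content as unhealthy marketing dominates such
venues; child-targeting 0.25, sports-relation 0.35 (elevated for sport
settings); sizes (0.35, 0.45, 0.20) with 10% of occasions unsized; 30% of
pricing indicators triggered. Covariates mimic small facilities:
concessions = 1 + Poisson(0.3), sports areas ≈ Poisson(3), floored at 1.

Rater 2 is rater 1 with each attribute independently perturbed with
probability `rater_flip` (default 0.05): booleans negate, sizes move
uniformly to one of the other two classes, entities resample uniformly
from the other distinct entities in the audit. This yields closed-form
expected kappas (e.g. for a binary flag with prevalence p, p_o = 1 − f and
p_e from the perturbed marginal), which the tests recover within ±0.05
over ~1000 occasions.

Outcomes couple to the score on the square-root scale, where the analyses
operate: √(food sponsorship) = 6·√(score) + N(0, 3), floored at zero;
total sponsorship adds a large score-independent component
(√-scale N(110, 40)) so that total sponsorship is *not* linearly related
to the score — reproducing the attenuation one expects when most
sponsorship money is unrelated to food. √(weekly sales) =
γ₀ + γ_sports·(sports areas) + γ_score·score + noise per channel, with
concession coupling 0.5 and a weaker vending coupling 0.15; total sales is
the channel sum and present only when both channels are. Outcome
missingness (20–35% per outcome) exercises the pipeline's exclusion logs
and t-tests. With these defaults the pipeline recovers a positive
significant partial sponsorship correlation and a significant concession
ΔR² in well over 80% of seeded replicates, and zeroed couplings produce ≈ 5%
significance calls.

What the generator does *not* emulate: spatial/temporal correlation within
sites, rater drift, entity-attribute correlations (a cartoon-branded
product is no more likely to be Least Healthy), non-Poisson count
dispersion (an overdispersed alternative would be a natural extension),
or real dollar distributions. Passing tests therefore demonstrate
statistical correctness and parameter recovery under the assumed model,
not field validity of the instrument.

## Problem sizes

The test suite runs exhaustive scoring checks over all ≤ 4-occasion
audits on a 12-template attribute grid (~1.8k audits plus ~5.5k append
comparisons), 100 random tables for agreement-statistic oracle
equivalence, ~1000-occasion audits for rater-noise recovery, and 200
seeded replicates each for the coupled and null pipeline studies — sizes
chosen to make every probabilistic margin comfortable while the whole
suite stays fast enough to run habitually.

## Known limitations

* The default scoring constants are a theory-faithful parameterisation,
  not a reproduction of any published point scheme; comparisons of
  absolute score levels across studies require agreeing on a config.
* Keyword-based healthfulness rules misclassify products whose names
  mislead ("fruit drink" matches "fruit"); the override hook and manual
  assignment path exist for exactly that reason.
* Kappa CIs are asymptotic and anti-conservative for very small n.
* The reliability report's co-identification key cannot distinguish two
  identical promotions at the same item observed by only one rater from
  a genuine disagreement about a third occasion.
* `truncate_outliers` iterates to a fixed point, which in pathological
  configurations may truncate values a single-pass reading of the rule
  would leave alone; the log makes every replacement auditable.
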