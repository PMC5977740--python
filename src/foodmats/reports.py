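"""Report builders that tie the statistics modules to audit data.

The central product here is the site reliability report: given two raters'
audits of the same site, it emits one row per reliability component —

(a) presence of food marketing by item (37 items, unweighted kappa),
(b) count of marketing occasions by area (square-root transformed,
    two-way random ICC, both single- and average-rater forms),
(c) product/brand/retailer marketed,
(d) child-targeted marketing,
(e) sports-related marketing, and
(f) physical size (ordinal, linear-weighted kappa),

where rows (c)-(f) are restricted to occasions both raters identified.
Co-identification matches occasions between raters on the
``(area, item_id, entity)`` key, pairing duplicates after a stable sort on
the remaining attributes; occasions without a partner count only toward
rows (a)-(b).  Rows whose statistic is undefined for the data at hand
(e.g. no co-identified occasions) are emitted with a note instead.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd

from .audit import ALL_ITEM_IDS, AreaKind, RaterAudit, SiteAudit, derive_item_presence
from .errors import DomainError, UndefinedStatisticError
from .psychometrics import (
    AgreementResult, PairedRatings, cohens_kappa, icc_two_way_random,
    percent_agreement, sqrt_transform, weighted_kappa,
)

REPORT_COLUMNS = [
    "component", "n", "percent_agreement", "statistic", "estimate",
    "ci_low", "ci_high", "p_value", "band", "note",
]


def as_rater_audit(audit: SiteAudit, rater_id: str) -> RaterAudit:
    """Wrap a plain site audit as a rater audit with derived presence flags."""
    return RaterAudit(rater_id=rater_id, audit=audit,
                      item_presence=derive_item_presence(audit))


def _match_occasions(a1: SiteAudit, a2: SiteAudit):
    """Pair occasions co-identified by both raters on (area, item_id, entity)."""
    def keyed(audit):
        groups: dict[tuple, list] = {}
        for occ in audit.occasions:
            key = (occ.area, occ.item_id, occ.entity.key)
            groups.setdefault(key, []).append(occ)
        for occs in groups.values():
            occs.sort(key=lambda o: (o.child_targeted, o.sports_related,
                                     -1 if o.size_class is None else int(o.size_class)))
        return groups

    g1, g2 = keyed(a1), keyed(a2)
    pairs = []
    for key in sorted(g1, key=lambda k: (k[0].value, k[1], k[2][0], k[2][1].value)):
        if key in g2:
            for o1, o2 in zip(g1[key], g2[key]):
                pairs.append((o1, o2))
    return pairs


def _row(component: str, n: int, pct: Optional[float],
         result: Optional[AgreementResult], note: str = "") -> dict:
    row = {c: np.nan for c in REPORT_COLUMNS}
    row.update(component=component, n=n, note=note)
    if pct is not None:
        row["percent_agreement"] = pct
    if result is not None:
        row.update(statistic=result.statistic, estimate=result.estimate,
                   ci_low=result.ci_low, ci_high=result.ci_high,
                   p_value=result.p_value, band=result.band)
    return row


def _kappa_row(component: str, ratings: PairedRatings, kind: str = "kappa",
               scheme: str = "linear") -> dict:
    pct = percent_agreement(ratings)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = (cohens_kappa(ratings) if kind == "kappa"
                      else weighted_kappa(ratings, scheme))
        return _row(component, len(ratings.x), pct, result)
    except UndefinedStatisticError as exc:
        return _row(component, len(ratings.x), pct, None, note=str(exc))


def site_reliability_report(rater1: RaterAudit, rater2: RaterAudit) -> pd.DataFrame:
    """Inter-rater reliability report for one site, one row per component."""
    a1, a2 = rater1.audit, rater2.audit
    if a1.site_id != a2.site_id:
        raise DomainError(
            f"rater audits cover different sites ({a1.site_id!r} vs {a2.site_id!r})"
        )
    rows = []

    # (a) presence of food marketing by item
    presence = PairedRatings(
        x=[rater1.item_presence.get(i, False) for i in ALL_ITEM_IDS],
        y=[rater2.item_presence.get(i, False) for i in ALL_ITEM_IDS],
    )
    rows.append(_kappa_row("presence_by_item", presence))

    # (b) count of occasions by area: ICC on square-root counts
    counts1 = [sum(o.area == a for o in a1.occasions) for a in AreaKind]
    counts2 = [sum(o.area == a for o in a2.occasions) for a in AreaKind]
    pct_counts = float(np.mean(np.asarray(counts1) == np.asarray(counts2)))
    matrix = np.column_stack([sqrt_transform(counts1), sqrt_transform(counts2)])
    for form, label in (("single", "count_by_area_icc_single"),
                        ("average", "count_by_area_icc_average")):
        try:
            rows.append(_row(label, len(counts1), pct_counts,
                             icc_two_way_random(matrix, form=form)))
        except UndefinedStatisticError as exc:
            rows.append(_row(label, len(counts1), pct_counts, None, note=str(exc)))

    # (c)-(f): restricted to occasions both raters identified
    pairs = _match_occasions(a1, a2)
    if not pairs:
        for comp in ("entity_marketed", "child_targeted", "sports_related", "physical_size"):
            rows.append(_row(comp, 0, None, None, note="no co-identified occasions"))
        return pd.DataFrame(rows, columns=REPORT_COLUMNS)

    entity = PairedRatings(
        x=[f"{o1.entity.kind.value}:{o1.entity.name}" for o1, _ in pairs],
        y=[f"{o2.entity.kind.value}:{o2.entity.name}" for _, o2 in pairs],
    )
    rows.append(_kappa_row("entity_marketed", entity))
    rows.append(_kappa_row("child_targeted", PairedRatings(
        x=[o1.child_targeted for o1, _ in pairs],
        y=[o2.child_targeted for _, o2 in pairs])))
    rows.append(_kappa_row("sports_related", PairedRatings(
        x=[o1.sports_related for o1, _ in pairs],
        y=[o2.sports_related for _, o2 in pairs])))

    sized = [(o1, o2) for o1, o2 in pairs
             if o1.size_class is not None and o2.size_class is not None]
    if sized:
        size = PairedRatings(
            x=[int(o1.size_class) for o1, _ in sized],
            y=[int(o2.size_class) for _, o2 in sized],
            scale="ordinal", categories=[0, 1, 2],
        )
        rows.append(_kappa_row("physical_size", size, kind="weighted"))
    else:
        rows.append(_row("physical_size", 0, None, None,
                         note="no co-identified occasions with recorded size"))
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
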