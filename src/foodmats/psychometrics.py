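"""Inter-rater reliability statistics for two-rater audit designs.

Implements the agreement measures used to evaluate paired audits: exact
percent agreement, Cohen's kappa for nominal ratings, weighted kappa for
ordinal ratings (linear weights by default, quadratic available), and the
two-way random-effects intraclass correlation (Shrout-Fleiss ICC(2,1) and
ICC(2,k)) for continuous data such as per-area occasion counts, which are
square-root transformed before the ICC to improve normality.

Kappa is ``(p_o - p_e) / (1 - p_e)`` with observed agreement ``p_o`` and
chance agreement ``p_e`` from the marginal products; confidence intervals
use the Fleiss-Cohen-Everitt asymptotic standard error and significance is
tested against the null-hypothesis variance.  Weighted kappa uses agreement
weights ``1 - |i-j|/(k-1)`` (linear) or ``1 - ((i-j)/(k-1))^2`` (quadratic);
identity weights recover the unweighted statistic.  The ICC point estimates,
F-based 95% CIs, and p-values come from :mod:`pingouin`.

Two degenerate conventions are documented rather than raised: perfect
agreement on a single observed category returns kappa = 1 with a warning
(chance agreement is 1, making the ratio formally undefined), while
imperfect agreement with chance agreement 1 raises
:class:`UndefinedStatisticError`.

Interpretation bands follow the source conventions for this instrument
family: kappa 0.0-0.2 'fair', 0.21-0.40 'poor', 0.41-0.60 'moderate',
0.61-0.80 'good', 0.81-1.00 'very good' — note the first two labels run
counter to the usual Landis-Koch ordering; they are reproduced as published,
with ``corrected_low_bands=True`` available to swap them — and ICC < 0.40
'poor', 0.40-0.59 'fair', 0.60-0.74 'good', 0.75-1.00 'excellent'.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, UndefinedStatisticError

__all__ = [
    "PairedRatings", "AgreementResult", "percent_agreement", "cohens_kappa",
    "weighted_kappa", "icc_two_way_random", "sqrt_transform", "interpret",
]


@dataclass(frozen=True)
class PairedRatings:
    """Ratings of the same items by two independent raters.

    ``categories`` fixes the category order for ordinal scales (required
    when the data alone do not determine it); for nominal scales it may
    enumerate categories that were never observed.
    """

    x: Sequence
    y: Sequence
    scale: str = "nominal"  # nominal | ordinal | continuous
    categories: Optional[Sequence] = None

    def __post_init__(self):
        if len(self.x) != len(self.y):
            raise DomainError(
                f"rating vectors differ in length ({len(self.x)} vs {len(self.y)})"
            )
        if len(self.x) == 0:
            raise DomainError("rating vectors must be non-empty")
        if self.scale not in ("nominal", "ordinal", "continuous"):
            raise DomainError(f"unknown scale {self.scale!r}")


@dataclass(frozen=True)
class AgreementResult:
    """An inter-rater statistic with its 95% CI and interpretation band."""

    statistic: str
    estimate: float
    ci_low: float
    ci_high: float
    n: int
    p_value: Optional[float] = None
    band: str = ""
    p_observed: Optional[float] = None
    p_expected: Optional[float] = None


def percent_agreement(r: PairedRatings) -> float:
    """Proportion of items on which the raters agree exactly."""
    x, y = np.asarray(r.x), np.asarray(r.y)
    return float(np.mean(x == y))


def contingency_table(r: PairedRatings) -> tuple[np.ndarray, list]:
    """k x k cross-classification of the two raters over a shared category set."""
    if r.categories is not None:
        cats = list(r.categories)
        extra = set(r.x) | set(r.y)
        missing = extra - set(cats)
        if missing:
            raise DomainError(f"observed categories {sorted(map(str, missing))} not in `categories`")
    else:
        cats = sorted(set(r.x) | set(r.y), key=str)
    index = {c: i for i, c in enumerate(cats)}
    table = np.zeros((len(cats), len(cats)))
    for a, b in zip(r.x, r.y):
        table[index[a], index[b]] += 1
    return table, cats


def _agreement_weights(k: int, scheme: str) -> np.ndarray:
    i, j = np.indices((k, k))
    if scheme == "identity":
        return (i == j).astype(float)
    d = np.abs(i - j) / (k - 1) if k > 1 else np.zeros((k, k))
    if scheme == "linear":
        return 1.0 - d
    if scheme == "quadratic":
        return 1.0 - d**2
    raise DomainError(f"unknown weight scheme {scheme!r}")


def _kappa_from_table(table: np.ndarray, weights: np.ndarray):
    """Weighted kappa with Fleiss-Cohen-Everitt variances.

    Returns (kappa, var, var0, p_o, p_e) where ``var`` is the variance of
    the estimate (for CIs) and ``var0`` the variance under kappa = 0 (for
    the significance test).
    """
    n = table.sum()
    if n == 0:
        raise UndefinedStatisticError("empty contingency table")
    p = table / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    p_o = float((weights * p).sum())
    p_e = float((weights * np.outer(row, col)).sum())
    if np.isclose(p_e, 1.0):
        if np.isclose(p_o, 1.0):
            warnings.warn(
                "perfect agreement on a single observed category; "
                "returning kappa = 1 by convention",
                stacklevel=3,
            )
            return 1.0, 0.0, 0.0, p_o, p_e
        raise UndefinedStatisticError(
            "chance agreement is 1 with imperfect agreement; kappa undefined"
        )
    kappa = (p_o - p_e) / (1.0 - p_e)
    wbar_row = weights @ col           # E[w | rater-1 category i]
    wbar_col = row @ weights           # E[w | rater-2 category j]
    cross = wbar_row[:, None] + wbar_col[None, :]
    # variance of the estimate (Fleiss, Cohen & Everitt 1969)
    term = (weights * (1.0 - p_e) - cross * (1.0 - p_o)) ** 2
    var = ((p * term).sum() - (p_o * p_e - 2.0 * p_e + p_o) ** 2) / (n * (1.0 - p_e) ** 4)
    # variance under H0: kappa = 0 (expected cell proportions row x col)
    term0 = (weights - cross) ** 2
    var0 = ((np.outer(row, col) * term0).sum() - p_e**2) / (n * (1.0 - p_e) ** 2)
    return float(kappa), max(float(var), 0.0), max(float(var0), 0.0), p_o, p_e


def _kappa_result(r: PairedRatings, scheme: str, name: str) -> AgreementResult:
    table, _ = contingency_table(r)
    if table.shape[0] < 2 and not np.isclose(percent_agreement(r), 1.0):
        raise UndefinedStatisticError("kappa needs at least two observed categories")
    weights = _agreement_weights(table.shape[0], scheme)
    kappa, var, var0, p_o, p_e = _kappa_from_table(table, weights)
    se = np.sqrt(var)
    z = stats.norm.ppf(0.975)
    ci_low = kappa - z * se
    ci_high = min(kappa + z * se, 1.0)  # kappa cannot exceed 1
    if var0 > 0:
        p_value = float(2 * stats.norm.sf(abs(kappa) / np.sqrt(var0)))
    else:
        p_value = float("nan")
    return AgreementResult(
        statistic=name,
        estimate=kappa,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n=int(table.sum()),
        p_value=p_value,
        band=interpret("kappa", kappa),
        p_observed=p_o,
        p_expected=p_e,
    )


def cohens_kappa(r: PairedRatings) -> AgreementResult:
    """Unweighted Cohen's kappa for nominal paired ratings."""
    return _kappa_result(r, "identity", "kappa")


def weighted_kappa(r: PairedRatings, scheme: str = "linear") -> AgreementResult:
    """Weighted kappa for ordinal paired ratings.

    ``scheme`` is ``linear`` (default), ``quadratic``, or ``identity``
    (which recovers the unweighted statistic).  Ordinal scales should pass
    an explicit category ordering via ``PairedRatings.categories``.
    """
    return _kappa_result(r, scheme, "weighted_kappa")


def icc_two_way_random(matrix, form: str = "single") -> AgreementResult:
    """Two-way random-effects ICC for a subjects x raters matrix.

    ``form='single'`` returns ICC(2,1) — reliability of a single rater's
    measurement — and ``form='average'`` returns ICC(2,k), the reliability
    of the k-rater average.  Absolute-agreement definition, F-based 95% CI.
    """
    if form not in ("single", "average"):
        raise DomainError(f"form must be 'single' or 'average', got {form!r}")
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise DomainError("ICC needs a 2-D matrix with >= 2 subjects and >= 2 raters")
    if np.isnan(m).any():
        raise DomainError("ICC requires complete data (no missing cells)")
    if np.allclose(m.mean(axis=1), m.mean(axis=1)[0]):
        raise UndefinedStatisticError("zero between-subject variance; ICC undefined")

    n_subj, n_raters = m.shape
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n_subj), n_raters),
        "rater": np.tile(np.arange(n_raters), n_subj),
        "score": m.ravel(),
    })
    import pingouin as pg  # deferred: pingouin import is heavy

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        icc = pg.intraclass_corr(data=long, targets="subject", raters="rater",
                                 ratings="score").set_index("Type")
    # two-way random, absolute agreement; label differs across pingouin versions
    labels = ("ICC2", "ICC(A,1)") if form == "single" else ("ICC2k", "ICC(A,k)")
    key = next(lbl for lbl in labels if lbl in icc.index)
    row = icc.loc[key]
    estimate = float(row["ICC"])
    if not np.isfinite(estimate):
        raise UndefinedStatisticError("ICC is undefined for these data")
    ci_col = "CI95%" if "CI95%" in icc.columns else "CI95"
    ci_low, ci_high = (float(v) for v in row[ci_col])
    if not (np.isfinite(ci_low) and np.isfinite(ci_high)):
        # degenerate F (zero residual variance): the interval collapses
        ci_low, ci_high = estimate, estimate
    return AgreementResult(
        statistic="icc_single" if form == "single" else "icc_average",
        estimate=estimate,
        ci_low=ci_low,
        ci_high=min(ci_high, 1.0),
        n=n_subj,
        p_value=float(row["pval"]),
        band=interpret("icc", estimate),
    )


def sqrt_transform(values: Sequence[float]) -> np.ndarray:
    """Element-wise square root (used on counts/dollars to improve normality)."""
    arr = np.asarray(values, dtype=float)
    if arr.size and np.nanmin(arr) < 0:
        raise DomainError("sqrt transform requires non-negative values")
    return np.sqrt(arr)


_KAPPA_BANDS = [(0.20, "fair"), (0.40, "poor"), (0.60, "moderate"),
                (0.80, "good"), (1.00, "very good")]
_KAPPA_BANDS_CORRECTED = [(0.20, "poor"), (0.40, "fair"), (0.60, "moderate"),
                          (0.80, "good"), (1.00, "very good")]
_ICC_BANDS = [(0.40, "poor"), (0.60, "fair"), (0.75, "good"), (1.00, "excellent")]


def interpret(statistic: str, value: float, corrected_low_bands: bool = False) -> str:
    """Qualitative interpretation band for a kappa or ICC value.

    ``corrected_low_bands`` swaps the published (inverted) fair/poor labels
    for kappa below 0.41 into the conventional ordering.
    """
    if value > 1:
        raise DomainError(f"agreement statistics cannot exceed 1, got {value}")
    if statistic == "kappa":
        bands = _KAPPA_BANDS_CORRECTED if corrected_low_bands else _KAPPA_BANDS
        for upper, label in bands:
            if value <= upper + 1e-12:
                return label
        return bands[-1][1]
    if statistic == "icc":
        for upper, label in _ICC_BANDS:
            if value < upper:
                return label
        return _ICC_BANDS[-1][1]
    raise DomainError(f"unknown statistic {statistic!r} (expected 'kappa' or 'icc')")
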