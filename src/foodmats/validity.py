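"""Validity analyses linking site scores to sponsorship and sales.

The pipeline mirrors a convergent-validity design for an environmental
audit score: if the score captures the exposure and power of food marketing
in a site, it should (1) correlate with the food-related sponsorship
dollars the facility receives, after controlling for facility size, and
(2) explain variance in weekly "Least Healthy" food and beverage sales over
and above facility size.

Preprocessing follows the analysis conventions for this kind of data:
dollar amounts and scores are square-root transformed to improve normality,
extreme values are truncated to one unit above the next closest value
within ``z`` (default 3) sample standard deviations, and itemized two-week
sales are classified by healthfulness and halved to weekly dollars.

Statistics: Pearson and Spearman correlations (scipy), partial Pearson
correlations controlling for facility size (pingouin, equivalent to the
correlation of the residuals from regressing each variable on the
controls), and sequential (hierarchical) OLS regression with standardized
betas, R-squared change, and the F-change test

    F = (dR2 / dk) / ((1 - R2_full) / (n - k_full - 1))

on ``(dk, n - k_full - 1)`` degrees of freedom.  Predictor pairs correlated
beyond ``|r| > 0.7`` are screened before regression; the member of the pair
not itself associated with the outcome is recommended for exclusion.
Missing-data impact is assessed with Welch's t-test comparing mean scores
of sites that did and did not provide each outcome.  Significance is
two-sided p < 0.05 throughout; no multiple-testing correction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .classification import ClassificationRuleSet, classify_product, default_rules
from .errors import DomainError, UndefinedStatisticError, UnclassifiedError
from .psychometrics import sqrt_transform

logger = logging.getLogger(__name__)

#: Column order of a site-outcomes table.
OUTCOME_COLUMNS = [
    "site_id", "foodmats_score", "food_sponsorship", "total_sponsorship",
    "sales_least_concession", "sales_least_vending", "sales_least_total",
    "n_concessions", "n_sports_areas",
]

SALES_CHANNELS = ("concession", "vending")


# ---------------------------------------------------------------------------
# Preprocessing


@dataclass(frozen=True)
class TruncationEntry:
    index: int
    original: float
    replacement: float


def truncate_outliers(
    values: Sequence[float], z: float = 3.0, unit: float = 1.0
) -> tuple[np.ndarray, list[TruncationEntry]]:
    """Truncate extreme values to reduce their leverage.

    A value beyond ``mean +/- z * SD`` (sample SD, outliers included) is
    replaced by the most extreme value within the threshold plus ``unit``
    in the offending direction ("one point above the next closest value").
    The rule is applied per value and re-applied until stable, so the
    operation is idempotent; the log records each original/replacement
    pair.  NaNs pass through untouched.
    """
    arr = np.asarray(values, dtype=float).copy()
    finite = ~np.isnan(arr)
    if finite.sum() < 3:
        raise DomainError("truncation needs at least 3 non-missing values")
    log: list[TruncationEntry] = []
    for _ in range(10):  # converges in one pass in practice
        vals = arr[finite]
        mean, sd = vals.mean(), vals.std(ddof=1)
        lo, hi = mean - z * sd, mean + z * sd
        inside = vals[(vals >= lo) & (vals <= hi)]
        if inside.size == 0 or inside.size == vals.size:
            break
        changed = False
        for idx in np.flatnonzero(finite):
            v = arr[idx]
            repl = inside.max() + unit if v > hi else (inside.min() - unit if v < lo else v)
            if repl != v:
                log.append(TruncationEntry(int(idx), float(v), float(repl)))
                arr[idx] = repl
                changed = True
        if not changed:
            break
    return arr, log


@dataclass(frozen=True)
class WeeklySales:
    """Weekly Least-Healthy dollars per channel, with exclusion diagnostics."""

    weekly: dict[str, float]
    excluded_channels: list[str]
    unclassified_rows: list[int]


def weekly_least_healthy_sales(
    sales_rows: pd.DataFrame,
    rules: Optional[ClassificationRuleSet] = None,
    period_weeks: float = 2.0,
) -> WeeklySales:
    """Reduce itemized multi-week sales to weekly Least-Healthy dollars.

    ``sales_rows`` needs columns ``item``, ``channel`` (concession or
    vending), and ``dollars``; the period (default two weeks with no
    unusual day) is divided out.  Rows whose item cannot be classified are
    listed and their channel is flagged as excluded, mirroring the
    exclusion of poorly itemized sales data.
    """
    rules = rules or default_rules()
    required = {"item", "channel", "dollars"}
    missing = required - set(sales_rows.columns)
    if missing:
        raise DomainError(f"sales table missing columns {sorted(missing)}")
    bad = set(sales_rows["channel"]) - set(SALES_CHANNELS)
    if bad:
        raise DomainError(f"unknown sales channels {sorted(bad)}; expected {SALES_CHANNELS}")

    totals = {ch: 0.0 for ch in SALES_CHANNELS}
    unclassified: list[int] = []
    excluded: set[str] = set()
    for idx, row in sales_rows.reset_index(drop=True).iterrows():
        try:
            health = classify_product(str(row["item"]), rules=rules)
        except UnclassifiedError:
            unclassified.append(int(idx))
            excluded.add(row["channel"])
            continue
        if health.name == "LEAST_HEALTHY":
            totals[row["channel"]] += float(row["dollars"])
    weekly = {
        ch: (np.nan if ch in excluded else totals[ch] / period_weeks)
        for ch in SALES_CHANNELS
        if ch in set(sales_rows["channel"])
    }
    return WeeklySales(weekly=weekly, excluded_channels=sorted(excluded),
                       unclassified_rows=unclassified)


# ---------------------------------------------------------------------------
# Correlation


@dataclass(frozen=True)
class CorrelationResult:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    partial_r: float
    partial_p: float
    n: int
    controls: tuple[str, ...] = ()


def correlations(
    x: Sequence[float],
    y: Sequence[float],
    controls: Optional[pd.DataFrame] = None,
) -> CorrelationResult:
    """Pearson, Spearman, and partial Pearson correlation of x with y.

    The partial correlation controls for every column of ``controls`` and
    equals the Pearson correlation of the residuals from regressing each of
    x and y on the controls; with no controls it reduces to the plain
    Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise DomainError("x and y must have equal length")
    k = 0 if controls is None else controls.shape[1]
    if len(x) < 4 + k:
        raise DomainError(f"need at least {4 + k} observations, got {len(x)}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatisticError("correlation undefined for constant input")

    pearson = stats.pearsonr(x, y)
    spearman = stats.spearmanr(x, y)
    if controls is None or controls.shape[1] == 0:
        partial_r, partial_p = float(pearson.statistic), float(pearson.pvalue)
        names: tuple[str, ...] = ()
    else:
        import pingouin as pg  # deferred import; heavy

        df = pd.DataFrame({"x": x, "y": y}).join(controls.reset_index(drop=True))
        names = tuple(controls.columns)
        out = pg.partial_corr(data=df, x="x", y="y", covar=list(names), method="pearson")
        partial_r = float(out["r"].iloc[0])
        p_col = "p_val" if "p_val" in out.columns else "p-val"  # pingouin renamed this
        partial_p = float(out[p_col].iloc[0])
    return CorrelationResult(
        pearson_r=float(pearson.statistic), pearson_p=float(pearson.pvalue),
        spearman_rho=float(spearman.statistic), spearman_p=float(spearman.pvalue),
        partial_r=partial_r, partial_p=partial_p, n=len(x), controls=names,
    )


# ---------------------------------------------------------------------------
# Sequential regression


@dataclass(frozen=True)
class ModelFit:
    """One model of a sequential regression, in standardized form."""

    predictors: tuple[str, ...]
    betas: dict[str, float]
    beta_ci: dict[str, tuple[float, float]]
    beta_p: dict[str, float]
    r2: float
    adj_r2: float
    dr2: float
    f_change: float
    p_change: float
    n: int


@dataclass(frozen=True)
class RegressionReport:
    models: tuple[ModelFit, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, m in enumerate(self.models, start=1):
            for name in m.predictors:
                lo, hi = m.beta_ci[name]
                rows.append({
                    "model": i, "predictor": name, "beta": m.betas[name],
                    "beta_ci_low": lo, "beta_ci_high": hi, "beta_p": m.beta_p[name],
                    "r2": m.r2, "adj_r2": m.adj_r2, "r2_change": m.dr2,
                    "f_change": m.f_change, "p_change": m.p_change, "n": m.n,
                })
        return pd.DataFrame(rows)


def _zscore(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=1)


def sequential_regression(
    outcome: Sequence[float],
    block1: pd.DataFrame,
    block2: pd.DataFrame,
) -> RegressionReport:
    """Nested OLS models: block 1 alone, then block 1 + block 2.

    All variables are standardized, so coefficients are standardized betas
    with 95% CIs.  Model 1's F-change is its overall F against the
    intercept-only model; Model 2's F-change tests the block-2 increment.
    Rank-deficient designs raise :class:`DomainError` naming the collinear
    columns.
    """
    y = np.asarray(outcome, dtype=float)
    X = pd.concat([block1.reset_index(drop=True), block2.reset_index(drop=True)], axis=1)
    if len(y) != len(X):
        raise DomainError("outcome and predictor blocks must have equal length")
    keep = ~(np.isnan(y) | X.isna().any(axis=1).to_numpy())
    y, X = y[keep], X.loc[keep].reset_index(drop=True)
    n, k_full = len(y), X.shape[1]
    if n <= k_full + 1:
        raise DomainError(f"need n > {k_full + 1} complete observations, got {n}")

    if any(X[c].std(ddof=1) == 0 for c in X.columns):
        constant = [c for c in X.columns if X[c].std(ddof=1) == 0]
        raise DomainError(f"constant predictor columns: {constant}")
    Z = X.apply(lambda c: _zscore(c.to_numpy()), axis=0)
    if np.linalg.matrix_rank(Z.to_numpy()) < k_full:
        corr = Z.corr().abs()
        pairs = [
            f"{a}~{b}"
            for i, a in enumerate(corr.columns)
            for b in corr.columns[i + 1:]
            if corr.loc[a, b] > 0.999
        ]
        raise DomainError(f"rank-deficient design; collinear columns: {pairs or list(X.columns)}")
    zy = _zscore(y)

    def fit(cols: list[str]) -> sm.regression.linear_model.RegressionResultsWrapper:
        return sm.OLS(zy, sm.add_constant(Z[cols].to_numpy())).fit()

    cols1 = list(block1.columns)
    cols_full = list(X.columns)
    fits = [fit(cols1), fit(cols_full)]
    models = []
    prev_r2, prev_k = 0.0, 0
    for cols, res in zip((cols1, cols_full), fits):
        r2 = float(res.rsquared)
        k = len(cols)
        dr2 = r2 - prev_r2
        dk = k - prev_k
        resid_df = n - k - 1
        if np.isclose(r2, 1.0):
            f_change, p_change = float("inf"), 0.0
        else:
            f_change = (dr2 / dk) / ((1.0 - r2) / resid_df)
            p_change = float(stats.f.sf(f_change, dk, resid_df))
        ci = res.conf_int()
        models.append(ModelFit(
            predictors=tuple(cols),
            betas={c: float(res.params[i + 1]) for i, c in enumerate(cols)},
            beta_ci={c: (float(ci[i + 1][0]), float(ci[i + 1][1])) for i, c in enumerate(cols)},
            beta_p={c: float(res.pvalues[i + 1]) for i, c in enumerate(cols)},
            r2=r2,
            adj_r2=float(res.rsquared_adj),
            dr2=dr2,
            f_change=float(f_change),
            p_change=p_change,
            n=n,
        ))
        prev_r2, prev_k = r2, k
    return RegressionReport(models=tuple(models))


@dataclass(frozen=True)
class CollinearityFlag:
    pair: tuple[str, str]
    r: float
    drop: str
    reason: str


def collinearity_screen(
    predictors: pd.DataFrame,
    outcome: Sequence[float],
    r_threshold: float = 0.7,
    alpha: float = 0.05,
) -> list[CollinearityFlag]:
    """Flag predictor pairs with |r| above threshold and recommend a drop.

    Within a flagged pair, the member not itself associated with the
    outcome (two-sided p >= alpha) is recommended for exclusion; if both or
    neither qualify, the member with the weaker outcome correlation goes.
    """
    if predictors.shape[1] < 2:
        raise DomainError("collinearity screen needs at least 2 predictors")
    y = np.asarray(outcome, dtype=float)
    flags: list[CollinearityFlag] = []
    cols = list(predictors.columns)
    assoc = {}
    for c in cols:
        v = predictors[c].to_numpy(dtype=float)
        keep = ~(np.isnan(v) | np.isnan(y))
        if keep.sum() < 3 or np.std(v[keep]) == 0:
            assoc[c] = (0.0, 1.0)
        else:
            r, p = stats.pearsonr(v[keep], y[keep])
            assoc[c] = (float(r), float(p))
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            va, vb = predictors[a].to_numpy(dtype=float), predictors[b].to_numpy(dtype=float)
            keep = ~(np.isnan(va) | np.isnan(vb))
            if keep.sum() < 3 or np.std(va[keep]) == 0 or np.std(vb[keep]) == 0:
                continue
            r = float(stats.pearsonr(va[keep], vb[keep]).statistic)
            if abs(r) > r_threshold:
                a_pred = assoc[a][1] < alpha
                b_pred = assoc[b][1] < alpha
                if a_pred and not b_pred:
                    drop, why = b, f"{b} not associated with outcome (p={assoc[b][1]:.3f})"
                elif b_pred and not a_pred:
                    drop, why = a, f"{a} not associated with outcome (p={assoc[a][1]:.3f})"
                else:
                    drop = a if abs(assoc[a][0]) < abs(assoc[b][0]) else b
                    why = f"{drop} has the weaker outcome correlation"
                flags.append(CollinearityFlag(pair=(a, b), r=r, drop=drop, reason=why))
    return flags


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class PipelineConfig:
    alpha: float = 0.05
    truncation_z: float = 3.0
    truncation_unit: float = 1.0
    collinearity_r: float = 0.7
    min_sites: int = 10


@dataclass
class ValidityReport:
    """End-to-end validity results: descriptives, correlations, regressions."""

    n_sites: int
    descriptives: pd.DataFrame
    sponsorship: dict = field(default_factory=dict)
    regressions: dict = field(default_factory=dict)
    missing_data_tests: dict = field(default_factory=dict)
    log: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def conv(obj):
            if isinstance(obj, pd.DataFrame):
                return obj.to_dict(orient="records")
            if isinstance(obj, RegressionReport):
                return obj.to_frame().to_dict(orient="records")
            if isinstance(obj, CorrelationResult):
                return obj.__dict__ | {"controls": list(obj.controls)}
            if isinstance(obj, dict):
                return {k: conv(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [conv(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj
        return {
            "n_sites": self.n_sites,
            "descriptives": conv(self.descriptives),
            "sponsorship": conv(self.sponsorship),
            "regressions": conv(self.regressions),
            "missing_data_tests": conv(self.missing_data_tests),
            "log": list(self.log),
        }


def _descriptives(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for col in df.columns:
        if col == "site_id":
            continue
        v = df[col].dropna().astype(float)
        rows.append({
            "variable": col, "n": len(v),
            "median": float(v.median()) if len(v) else np.nan,
            "q25": float(v.quantile(0.25)) if len(v) else np.nan,
            "q75": float(v.quantile(0.75)) if len(v) else np.nan,
        })
    return pd.DataFrame(rows)


def _missing_t_test(scores: pd.Series, present: pd.Series) -> dict:
    """Welch's t-test on mean score, sites providing vs not providing data."""
    a = scores[present].dropna()
    b = scores[~present].dropna()
    if len(a) < 2 or len(b) < 2:
        return {"n_present": int(len(a)), "n_missing": int(len(b)),
                "t": np.nan, "p": np.nan, "note": "too few sites in a group"}
    t = stats.ttest_ind(a, b, equal_var=False)
    return {"n_present": int(len(a)), "n_missing": int(len(b)),
            "t": float(t.statistic), "p": float(t.pvalue)}


def run_validity_pipeline(
    outcomes: pd.DataFrame,
    config: Optional[PipelineConfig] = None,
) -> ValidityReport:
    """Run the full validity analysis on a site-outcomes table.

    Sponsorship: square-root transform score and food sponsorship, truncate
    outliers, screen total sponsorship for a linear relationship, then
    Pearson/Spearman/partial correlations (controls: number of concessions
    and of sports areas, entered separately).  Sales: per channel
    (concession, vending, total), square-root transform sales, screen
    predictors for collinearity, then sequential regression with facility
    size in Model 1 and the site score added in Model 2.  Sites missing an
    outcome are excluded from that analysis with counts logged, and
    missing-vs-present mean-score t-tests are reported.
    """
    cfg = config or PipelineConfig()
    df = outcomes.reset_index(drop=True).copy()
    missing_cols = [c for c in ("foodmats_score", "n_concessions", "n_sports_areas")
                    if c not in df.columns]
    if missing_cols:
        raise DomainError(f"outcomes table missing columns {missing_cols}")
    n_sites = int(df["foodmats_score"].notna().sum())
    if n_sites < cfg.min_sites:
        raise DomainError(f"pipeline needs at least {cfg.min_sites} scored sites, got {n_sites}")

    report = ValidityReport(n_sites=n_sites, descriptives=_descriptives(df))
    score = df["foodmats_score"].astype(float)
    controls_cols = ["n_concessions", "n_sports_areas"]

    # --- sponsorship correlations -----------------------------------------
    if "food_sponsorship" in df.columns and df["food_sponsorship"].notna().sum() >= 4 + 2:
        present = df["food_sponsorship"].notna()
        report.missing_data_tests["food_sponsorship"] = _missing_t_test(score, present)
        sub = df.loc[present].reset_index(drop=True)
        s_t, s_log = truncate_outliers(sqrt_transform(sub["foodmats_score"]),
                                       cfg.truncation_z, cfg.truncation_unit)
        f_t, f_log = truncate_outliers(sqrt_transform(sub["food_sponsorship"]),
                                       cfg.truncation_z, cfg.truncation_unit)
        for name, tlog in (("score", s_log), ("food_sponsorship", f_log)):
            for entry in tlog:
                report.log.append(
                    f"truncated {name}[{entry.index}]: {entry.original:.3f} -> {entry.replacement:.3f}"
                )
        section: dict = {
            "food": correlations(s_t, f_t, sub[controls_cols]),
            "n": int(present.sum()),
        }
        if "total_sponsorship" in df.columns and df["total_sponsorship"].notna().sum() >= 4:
            both = df["total_sponsorship"].notna() & df["foodmats_score"].notna()
            tot = df.loc[both]
            screen = stats.pearsonr(sqrt_transform(tot["foodmats_score"]),
                                    sqrt_transform(tot["total_sponsorship"]))
            section["total_screen"] = {"r": float(screen.statistic),
                                       "p": float(screen.pvalue), "n": int(both.sum())}
            if screen.pvalue >= cfg.alpha:
                report.log.append(
                    "total sponsorship not linearly related to scores; no further analysis"
                )
            report.missing_data_tests["total_sponsorship"] = _missing_t_test(
                score, df["total_sponsorship"].notna())
        report.sponsorship = section
    else:
        report.log.append("sponsorship section skipped: fewer than 6 sites with food sponsorship")

    # --- sales regressions -------------------------------------------------
    channels = {
        "concession": "sales_least_concession",
        "vending": "sales_least_vending",
        "total": "sales_least_total",
    }
    for channel, col in channels.items():
        if col not in df.columns or df[col].notna().sum() == 0:
            report.log.append(f"{channel} sales regression skipped: no data")
            continue
        present = df[col].notna()
        report.missing_data_tests[col] = _missing_t_test(score, present)
        sub = df.loc[present & df["foodmats_score"].notna()].reset_index(drop=True)
        if len(sub) <= 4:
            report.log.append(f"{channel} sales regression skipped: n={len(sub)} too small")
            continue
        y = sqrt_transform(sub[col])
        predictors = sub[controls_cols + ["foodmats_score"]].astype(float)
        flags = collinearity_screen(predictors, y, cfg.collinearity_r, cfg.alpha)
        block1_cols = list(controls_cols)
        for flag in flags:
            # never drop the explanatory score; drop the collinear covariate
            victim = flag.drop if flag.drop != "foodmats_score" else (
                flag.pair[0] if flag.pair[1] == "foodmats_score" else flag.pair[1])
            if victim in block1_cols:
                block1_cols.remove(victim)
                report.log.append(
                    f"{channel}: dropped {victim} (|r|={abs(flag.r):.2f} with "
                    f"{flag.pair[0] if victim == flag.pair[1] else flag.pair[1]}; {flag.reason})"
                )
        if not block1_cols:
            block1_cols = ["n_sports_areas"]
            report.log.append(f"{channel}: all size covariates flagged; kept n_sports_areas")
        try:
            report.regressions[channel] = {
                "report": sequential_regression(
                    y, sub[block1_cols], sub[["foodmats_score"]]),
                "collinearity": flags,
                "n": int(len(sub)),
            }
        except DomainError as exc:
            report.log.append(f"{channel} sales regression skipped: {exc}")
    return report
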