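"""Independent brute-force reference implementations used only by tests.

Everything here is written from first principles (loops, closed forms,
explicit ANOVA sums of squares) and deliberately shares no code with the
package, so agreement between the two is evidence of correctness rather
than of shared bugs.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# Agreement statistics


def kappa_brute(x, y, scheme: str = "identity"):
    """Weighted kappa by explicit enumeration over category pairs."""
    cats = sorted(set(x) | set(y), key=str)
    k = len(cats)
    idx = {c: i for i, c in enumerate(cats)}
    n = len(x)

    def weight(i, j):
        if scheme == "identity":
            return 1.0 if i == j else 0.0
        d = abs(i - j) / (k - 1) if k > 1 else 0.0
        return 1.0 - d if scheme == "linear" else 1.0 - d * d

    p_o = 0.0
    for a, b in zip(x, y):
        p_o += weight(idx[a], idx[b]) / n
    row = [sum(1 for a in x if a == c) / n for c in cats]
    col = [sum(1 for b in y if b == c) / n for c in cats]
    p_e = 0.0
    for i in range(k):
        for j in range(k):
            p_e += weight(i, j) * row[i] * col[j]
    if np.isclose(p_e, 1.0):
        return 1.0 if np.isclose(p_o, 1.0) else np.nan
    return (p_o - p_e) / (1.0 - p_e)


def icc_brute(matrix, form: str = "single"):
    """Two-way random absolute-agreement ICC from explicit ANOVA mean squares."""
    m = np.asarray(matrix, dtype=float)
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ms_rows = k * ((row_means - grand) ** 2).sum() / (n - 1)
    ms_cols = n * ((col_means - grand) ** 2).sum() / (k - 1)
    resid = m - row_means[:, None] - col_means[None, :] + grand
    ms_err = (resid**2).sum() / ((n - 1) * (k - 1))
    if form == "single":
        denom = ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
    else:
        denom = ms_rows + (ms_cols - ms_err) / n
    return (ms_rows - ms_err) / denom


def expected_flip_kappa_binary(prevalence: float, flip: float) -> float:
    """Expected kappa when rater 2 negates a binary truth flag w.p. ``flip``."""
    p = prevalence
    p2 = p * (1 - flip) + (1 - p) * flip  # rater-2 marginal
    p_o = 1.0 - flip
    p_e = p * p2 + (1 - p) * (1 - p2)
    return (p_o - p_e) / (1 - p_e)


def expected_flip_kappa_categorical(probs, flip: float) -> float:
    """Expected kappa when rater 2 resamples uniformly among the *other*
    categories w.p. ``flip``; ``probs`` is the truth distribution."""
    q = np.asarray(probs, dtype=float)
    k = len(q)
    q2 = q * (1 - flip) + flip * (1 - q) / (k - 1)
    p_o = 1.0 - flip
    p_e = float((q * q2).sum())
    return (p_o - p_e) / (1 - p_e)


# ---------------------------------------------------------------------------
# Scoring


def score_brute(audit, config=None) -> float:
    """Site score by direct summation over occasions (<= a handful)."""
    from foodmats.audit import HealthClass
    from foodmats.scoring import ScoringConfig

    cfg = config or ScoringConfig()
    content = {HealthClass.MOST_HEALTHY: 0.0,
               HealthClass.LESS_HEALTHY: cfg.w_less_fraction,
               HealthClass.LEAST_HEALTHY: 1.0}
    total = 0.0
    for occ in audit.occasions:
        total += 1.0
        total += cfg.w_content * content[occ.entity.health_class]
        total += cfg.w_child if occ.child_targeted else 0.0
        total += cfg.w_sport if occ.sports_related else 0.0
        if occ.size_class is not None:
            total += cfg.w_size * occ.size_class.value / 2.0
    if cfg.include_pricing_as_occasions:
        for rec in audit.pricing:
            if rec.triggered:
                total += 1.0 + cfg.w_content
    tallies: dict = {}
    for occ in audit.occasions:
        key = (occ.entity.name, occ.entity.kind)
        tallies[key] = tallies.get(key, 0) + 1
    total += cfg.w_repetition * sum(
        1 for c in tallies.values() if c >= cfg.repetition_threshold
    )
    return total


# ---------------------------------------------------------------------------
# Regression / correlation


def partial_corr_residuals(x, y, controls) -> float:
    """Partial correlation as the Pearson r of OLS residuals."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    C = np.column_stack([np.ones(len(x)), np.asarray(controls, float)])
    rx = x - C @ np.linalg.lstsq(C, x, rcond=None)[0]
    ry = y - C @ np.linalg.lstsq(C, y, rcond=None)[0]
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def f_change_ss(y, X1, X2):
    """F-change for adding X2 to X1, from explicit residual sums of squares."""
    y = np.asarray(y, float)
    n = len(y)

    def rss(X):
        X = np.column_stack([np.ones(n), np.asarray(X, float)])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        r = y - X @ beta
        return float(r @ r), X.shape[1] - 1

    rss1, k1 = rss(X1)
    Xf = np.column_stack([np.asarray(X1, float), np.asarray(X2, float)])
    rss_full, k_full = rss(Xf)
    df = n - k_full - 1
    return ((rss1 - rss_full) / (k_full - k1)) / (rss_full / df)
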