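"""Univariate statistics: additive two-way ANOVA, fold changes, adaptive FDR.

The two-way ANOVA uses production system and year as crossed factors in an
additive (no-interaction) model on a balanced complete design; the
interaction sum of squares is pooled into the error term.  Multiple testing
is handled by the Benjamini-Hochberg step-up procedure in an adaptive
variant whose null-count estimate m0 comes from the least-slope reading of
the p-value quantile plot.  Helper routines reconstruct the same ANOVA from
printed cell means/SDs, assign compact-letter groupings from pairwise
Student t tests, and compare an observed overlap of two significant-feature
sets against the chance expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaResult", "FdrResult", "FoldChangeResult",
    "two_way_anova", "anova_from_summary", "anova_matrix",
    "fold_change", "adaptive_fdr", "estimate_m0_least_slope",
    "count_significant", "pairwise_letters", "overlap_vs_chance",
]


@dataclass
class AnovaResult:
    """Additive two-way decomposition for one response variable."""

    ss_a: float
    ss_b: float
    ss_error: float
    df_a: int
    df_b: int
    df_error: int
    f_a: float
    f_b: float
    p_a: float
    p_b: float


def _f_and_p(ss, df, ss_err, df_err):
    if ss <= 0:
        return 0.0, 1.0
    if ss_err <= 0:  # perfect fit: effect present with zero residual
        return math.inf, 0.0
    f = (ss / df) / (ss_err / df_err)
    return f, float(stats.f.sf(f, df, df_err))


def two_way_anova(values, factor_a, factor_b) -> AnovaResult:
    """Additive two-way ANOVA on a balanced complete design.

    ``SS_A`` and ``SS_B`` come from marginal means; ``SS_error`` is the
    total SS minus both (the interaction is pooled into the error).
    The design must have proportional cell frequencies (which includes the
    equal-cell balanced case and the pooled two-level comparison with
    cells of 3 and 6) so that the two factor SS are orthogonal.  Constant
    responses yield F = 0, p = 1 for both factors.
    """
    y = np.asarray(values, dtype=float)
    a_codes, a_levels = pd.factorize(np.asarray(factor_a), sort=True)
    b_codes, b_levels = pd.factorize(np.asarray(factor_b), sort=True)
    a, b = len(a_levels), len(b_levels)
    if a < 2 or b < 2:
        raise ValueError("each factor needs at least two levels")
    n_cell = np.zeros((a, b), dtype=int)
    np.add.at(n_cell, (a_codes, b_codes), 1)
    N = y.size
    n_a = n_cell.sum(axis=1)
    n_b = n_cell.sum(axis=0)
    if n_cell.min() < 1 or not np.allclose(n_cell, np.outer(n_a, n_b) / N):
        raise ValueError("design must be complete with proportional cell frequencies")
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    mean_a = np.array([y[a_codes == i].mean() for i in range(a)])
    mean_b = np.array([y[b_codes == j].mean() for j in range(b)])
    ss_a = float((n_a * (mean_a - grand) ** 2).sum())
    ss_b = float((n_b * (mean_b - grand) ** 2).sum())
    ss_err = max(ss_total - ss_a - ss_b, 0.0)
    df_a, df_b = a - 1, b - 1
    df_err = N - 1 - df_a - df_b
    f_a, p_a = _f_and_p(ss_a, df_a, ss_err, df_err)
    f_b, p_b = _f_and_p(ss_b, df_b, ss_err, df_err)
    return AnovaResult(ss_a, ss_b, ss_err, df_a, df_b, df_err, f_a, f_b, p_a, p_b)


def anova_from_summary(cell_means, cell_sds, n_per_cell: int) -> AnovaResult:
    """Additive two-way ANOVA reconstructed from per-cell means and SDs.

    ``cell_means`` and ``cell_sds`` are (a x b) arrays (factor A by factor
    B) with a common cell size ``n_per_cell``.  The within-cell SS is
    ``sum (n-1)*SD^2``; the interaction SS is pooled into the error term so
    the result equals :func:`two_way_anova` on any raw data having exactly
    these summaries.
    """
    means = np.asarray(cell_means, dtype=float)
    sds = np.asarray(cell_sds, dtype=float)
    if means.shape != sds.shape or means.ndim != 2:
        raise ValueError("cell_means and cell_sds must be matching 2-D arrays")
    if (sds < 0).any():
        raise ValueError("standard deviations must be >= 0")
    n = int(n_per_cell)
    if n < 2:
        raise ValueError("n_per_cell must be >= 2")
    a, b = means.shape
    grand = means.mean()
    ss_within = float(((n - 1) * sds ** 2).sum())
    ss_a = float(b * n * ((means.mean(axis=1) - grand) ** 2).sum())
    ss_b = float(a * n * ((means.mean(axis=0) - grand) ** 2).sum())
    resid = means - means.mean(axis=1, keepdims=True) - means.mean(axis=0, keepdims=True) + grand
    ss_int = float(n * (resid ** 2).sum())
    ss_err = ss_within + ss_int
    df_err = a * b * (n - 1) + (a - 1) * (b - 1)
    f_a, p_a = _f_and_p(ss_a, a - 1, ss_err, df_err)
    f_b, p_b = _f_and_p(ss_b, b - 1, ss_err, df_err)
    return AnovaResult(ss_a, ss_b, ss_err, a - 1, b - 1, df_err, f_a, f_b, p_a, p_b)


def anova_matrix(X, factor_a, factor_b) -> pd.DataFrame:
    """Vectorized additive two-way ANOVA over the columns of ``X``.

    ``X`` is a (samples x variables) array or DataFrame; returns a frame
    with columns ``p_a``, ``p_b``, ``f_a``, ``f_b`` per variable.
    """
    Xv = np.asarray(X, dtype=float)
    a_codes, a_levels = pd.factorize(np.asarray(factor_a), sort=True)
    b_codes, b_levels = pd.factorize(np.asarray(factor_b), sort=True)
    a, b = len(a_levels), len(b_levels)
    N = Xv.shape[0]
    grand = Xv.mean(axis=0)
    ss_total = ((Xv - grand) ** 2).sum(axis=0)
    # balanced design: marginal-mean SS weighted by group size
    ss_a = sum((a_codes == i).sum() * (Xv[a_codes == i].mean(axis=0) - grand) ** 2
               for i in range(a))
    ss_b = sum((b_codes == j).sum() * (Xv[b_codes == j].mean(axis=0) - grand) ** 2
               for j in range(b))
    ss_err = np.clip(ss_total - ss_a - ss_b, 0.0, None)
    df_a, df_b = a - 1, b - 1
    df_err = N - 1 - df_a - df_b
    with np.errstate(divide="ignore", invalid="ignore"):
        f_a = (ss_a / df_a) / (ss_err / df_err)
        f_b = (ss_b / df_b) / (ss_err / df_err)
    p_a = np.where(ss_a <= 0, 1.0, stats.f.sf(f_a, df_a, df_err))
    p_b = np.where(ss_b <= 0, 1.0, stats.f.sf(f_b, df_b, df_err))
    cols = X.columns if isinstance(X, pd.DataFrame) else pd.RangeIndex(Xv.shape[1])
    return pd.DataFrame({"f_a": f_a, "f_b": f_b, "p_a": p_a, "p_b": p_b}, index=cols)


# ---------------------------------------------------------------------------
# fold changes
# ---------------------------------------------------------------------------

@dataclass
class FoldChangeResult:
    """Group-mean ratio per year, averaged over years, with magnitude >= 1."""

    per_year: dict
    averaged_ratio: float
    magnitude: float
    direction: str  # "higher-in-C" | "higher-in-O" | "equal"


def fold_change(values, in_group_c, years) -> FoldChangeResult:
    """Ratio of mean intensities, C over pooled organic, averaged over years.

    ``in_group_c`` is a boolean vector marking the conventional samples;
    ratios are averaged arithmetically across years.  A non-positive group
    mean raises (callers flag and exclude such features).
    """
    y = np.asarray(values, dtype=float)
    c = np.asarray(in_group_c, dtype=bool)
    yr = np.asarray(years)
    per_year = {}
    for lab in pd.unique(yr):
        sel = yr == lab
        mc = y[sel & c].mean()
        mo = y[sel & ~c].mean()
        if not (mc > 0 and mo > 0):
            raise ValueError(f"non-positive group mean in year {lab}")
        per_year[lab] = mc / mo
    r = float(np.mean(list(per_year.values())))
    mag = max(r, 1.0 / r)
    direction = "equal" if r == 1.0 else ("higher-in-C" if r > 1.0 else "higher-in-O")
    return FoldChangeResult(per_year, r, mag, direction)


def fold_change_matrix(X: pd.DataFrame, in_group_c, years) -> pd.DataFrame:
    """Vectorized :func:`fold_change` over DataFrame columns.

    Features with a non-positive group mean get NaN and ``valid=False``.
    """
    c = np.asarray(in_group_c, dtype=bool)
    yr = np.asarray(years)
    ratios = []
    for lab in pd.unique(yr):
        sel = yr == lab
        mc = X.loc[sel & c].mean(axis=0)
        mo = X.loc[sel & ~c].mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = mc / mo
        r[(mc <= 0) | (mo <= 0)] = np.nan
        ratios.append(r)
    avg = pd.concat(ratios, axis=1).mean(axis=1)
    mag = np.maximum(avg, 1.0 / avg)
    direction = np.where(avg > 1, "higher-in-C", np.where(avg < 1, "higher-in-O", "equal"))
    return pd.DataFrame({"ratio": avg, "magnitude": mag, "direction": direction,
                         "valid": avg.notna()})


# ---------------------------------------------------------------------------
# adaptive FDR
# ---------------------------------------------------------------------------

@dataclass
class FdrResult:
    qvalues: np.ndarray
    m0_hat: int
    pvalues: np.ndarray


def estimate_m0_least_slope(pvalues) -> int:
    """Least-slope estimate of the number of true null hypotheses.

    Reads the p-value quantile plot: slopes l_i = (1 - p_(i)) / (m + 1 - i)
    are scanned from the smallest p upward; at the first decrease the
    current slope is taken to extrapolate the null line, giving
    m0 = min(ceil(1/l + 1), m).  All-equal slopes (e.g. all p = 1) give m.
    """
    p = np.sort(np.asarray(pvalues, dtype=float))
    m = p.size
    if m == 0:
        return 0
    idx = np.arange(1, m + 1)
    slopes = (1.0 - p) / (m + 1 - idx)
    for i in range(1, m):
        if slopes[i] < slopes[i - 1]:
            if slopes[i] <= 0:
                return m
            return int(min(math.ceil(1.0 / slopes[i] + 1.0), m))
    return m


def adaptive_fdr(pvalues, m0: int | None = None) -> FdrResult:
    """Adaptive Benjamini-Hochberg q-values.

    q_(i) = min_{j >= i} p_(j) * m0 / j, capped at 1, with m0 estimated by
    :func:`estimate_m0_least_slope` unless fixed by the caller (``m0 = m``
    reproduces plain BH).  Ties are broken by stable sort on input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m0 is None:
        m0 = estimate_m0_least_slope(p)
    if not 0 <= m0 <= m:
        raise ValueError("m0 must lie in [0, m]")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m0 / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return FdrResult(q, int(m0), p)


def count_significant(pvalues, qvalues, m0_hat: int, *,
                      p_thresholds=(0.001, 0.05), q_thresholds=(0.05, 0.1)) -> dict:
    """Counts of significant features at the standard reporting thresholds,
    plus the estimated number of true differences m - m0."""
    p = np.asarray(pvalues, dtype=float)
    q = np.asarray(qvalues, dtype=float)
    out = {}
    for t in p_thresholds:
        out[f"p<{t:g}"] = int((p < t).sum())
    for t in q_thresholds:
        out[f"FDR<{t:g}"] = int((q < t).sum())
    out["estimated_true_differences"] = int(p.size - m0_hat)
    return out


# ---------------------------------------------------------------------------
# pairwise letters and overlap
# ---------------------------------------------------------------------------

def pairwise_letters(means, sds, n: int, alpha: float = 0.05,
                     labels=None) -> dict:
    """Compact letter display from pairwise pooled-variance Student t tests.

    Groups that are *not* significantly different at ``alpha`` share a
    letter.  Letters are built from the maximal cliques of the
    non-significance graph, ordered by descending group mean.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    k = means.size
    if labels is None:
        labels = [str(i) for i in range(k)]
    if n < 2:
        raise ValueError("n must be >= 2")
    # adjacency of "not significantly different"
    same = np.eye(k, dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            sp2 = ((n - 1) * sds[i] ** 2 + (n - 1) * sds[j] ** 2) / (2 * n - 2)
            if sp2 == 0:
                differ = means[i] != means[j]
            else:
                t = (means[i] - means[j]) / math.sqrt(sp2 * 2.0 / n)
                differ = 2 * stats.t.sf(abs(t), 2 * n - 2) < alpha
            same[i, j] = same[j, i] = not differ
    # maximal cliques by brute force (k is tiny)
    from itertools import combinations

    cliques = []
    for size in range(k, 0, -1):
        for combo in combinations(range(k), size):
            if all(same[x, y] for x, y in combinations(combo, 2)):
                if not any(set(combo) <= set(c) for c in cliques):
                    cliques.append(combo)
    cliques.sort(key=lambda c: -max(means[list(c)]))
    letters = {lab: "" for lab in labels}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for i in clique:
            letters[labels[i]] += letter
    return letters


def overlap_vs_chance(n1: int, n2: int, m: int, observed: int) -> dict:
    """Compare an observed overlap of two feature sets with chance.

    Under independence the expected overlap of sets of sizes n1 and n2 in a
    universe of m is n1*n2/m; the upper-tail probability of the observed
    overlap is hypergeometric.
    """
    if not (0 <= n1 <= m and 0 <= n2 <= m):
        raise ValueError("set sizes must lie within the universe")
    if observed > min(n1, n2) or observed < 0:
        raise ValueError("observed overlap exceeds the smaller set")
    expected = n1 * n2 / m if m else 0.0
    p_upper = float(stats.hypergeom.sf(observed - 1, m, n1, n2))
    return {"expected": expected, "observed": observed,
            "excess": observed - expected, "p_upper": p_upper}
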