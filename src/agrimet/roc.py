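"""ROC curves, pair-counting AUC, and exact Mann-Whitney permutation p-values.

Built for very small validation sets (a handful of samples per class),
where the exact permutation distribution of the Mann-Whitney U statistic is
enumerable: the one-sided p-value is the fraction of all C(n, n_pos)
assignments of the positive labels to the observed score ranks whose U is
at least the observed one.  Ties are handled with midranks and half credit
throughout, so AUC = U / (n_pos * n_neg) holds exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import rankdata

__all__ = ["RocResult", "roc_curve", "auc", "exact_mw_pvalue"]

#: largest number of labelings enumerated exactly
MAX_ENUMERATION = 10 ** 6


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    u: float
    p: float
    n_pos: int
    n_neg: int


def _check(scores, labels):
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels).astype(bool)
    if s.shape != lab.shape or s.ndim != 1:
        raise ValueError("scores and labels must be matching 1-D vectors")
    n_pos = int(lab.sum())
    n_neg = int((~lab).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    return s, lab, n_pos, n_neg


def mann_whitney_u(scores, labels) -> float:
    """U statistic with half credit for ties (midranks)."""
    s, lab, n_pos, _ = _check(scores, labels)
    ranks = rankdata(s)  # midranks
    return float(ranks[lab].sum() - n_pos * (n_pos + 1) / 2.0)


def auc(scores, labels) -> float:
    """Pair-counting AUC: (concordant + tied/2) / (n_pos * n_neg)."""
    s, lab, n_pos, n_neg = _check(scores, labels)
    return mann_whitney_u(s, lab) / (n_pos * n_neg)


def roc_curve(scores, labels):
    """ROC points sweeping thresholds over unique scores, descending.

    Tied scores collapse into a single step.  The returned (fpr, tpr)
    arrays start at (0, 0) and end at (1, 1), both coordinates
    non-decreasing; the trapezoidal area under them equals :func:`auc`.
    """
    s, lab, n_pos, n_neg = _check(scores, labels)
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    lab_sorted = lab[order]
    # indices where the threshold changes (last occurrence of each value)
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), s_sorted.size - 1]
    tp = np.cumsum(lab_sorted)[distinct]
    fp = np.cumsum(~lab_sorted)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    return fpr, tpr


def exact_mw_pvalue(scores, labels):
    """One-sided exact Mann-Whitney permutation test (positives high).

    Enumerates every assignment of the positive labels to the observed
    (midrank tie-broken) score ranks; p = #(U_perm >= U_obs) / C(n, n_pos).
    Raises when the enumeration domain exceeds 10^6 labelings.
    """
    s, lab, n_pos, n_neg = _check(scores, labels)
    n = n_pos + n_neg
    total = math.comb(n, n_pos)
    if total > MAX_ENUMERATION:
        raise ValueError(
            f"C({n},{n_pos}) = {total} labelings exceed the exact enumeration "
            "domain; a large-sample approximation is not provided"
        )
    ranks = rankdata(s)
    offset = n_pos * (n_pos + 1) / 2.0
    u_obs = float(ranks[lab].sum() - offset)
    count = sum(
        1 for combo in combinations(range(n), n_pos)
        if ranks[list(combo)].sum() - offset >= u_obs - 1e-9
    )
    return u_obs, count / total


def roc_result(scores, labels) -> RocResult:
    """Full ROC summary: curve points, AUC, U, exact one-sided p."""
    s, lab, n_pos, n_neg = _check(scores, labels)
    fpr, tpr = roc_curve(s, lab)
    u = mann_whitney_u(s, lab)
    _, p = exact_mw_pvalue(s, lab)
    return RocResult(fpr, tpr, u / (n_pos * n_neg), u, p, n_pos, n_neg)
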