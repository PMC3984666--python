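"""Multivariate modeling: UV scaling, PCA, OPLS-DA, CV-ANOVA, VIP.

OPLS-DA splits the X-variation of a two-class problem into one predictive
component (correlated with the 0/1 class vector y) and ``n_ortho``
orthogonal components (structured variation uncorrelated with y), using the
single-y orthogonal-projections algorithm:

    w  = X'y / ||X'y||                       (predictive weights)
    repeat for each orthogonal component:
        t    = X w;  p = X't / t't
        w_o  = p - (w'p) w, normalized;  t_o = X w_o;  p_o = X't_o / t_o't_o
        X   <- X - t_o p_o'
    finally t = X w;  p = X't / t't;  c = y't / t't

Model quality is judged by sevenfold internal cross-validation: Q2(cum) =
1 - PRESS/SSY, a CV-ANOVA F test on the cross-validated residuals, and the
correct classification rate at the midpoint decision threshold.  VIP scores
(mean square 1 by construction) rank variables; VIP > 1 marks
above-average contributors.

Estimators follow the fit/transform convention with trailing-underscore
fitted attributes and plain ``get_params``/``set_params`` plumbing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "UnitVarianceScaler", "PCAModel", "OPLSDA", "CvReport",
    "cross_validate", "select_components", "cv_anova", "vip",
    "hotelling_ellipse", "refine_by_year", "external_validate",
    "impute_missing_by_year",
]


class _ParamsMixin:
    """Minimal get_params/set_params so estimators compose with pipelines."""

    _param_names: tuple = ()

    def get_params(self, deep: bool = True) -> dict:
        return {name: getattr(self, name) for name in self._param_names}

    def set_params(self, **params):
        for name, value in params.items():
            if name not in self._param_names:
                raise ValueError(f"unknown parameter {name!r} for {type(self).__name__}")
            setattr(self, name, value)
        return self

    def __repr__(self) -> str:
        args = ", ".join(f"{k}={v!r}" for k, v in self.get_params().items())
        return f"{type(self).__name__}({args})"


def _check_matrix(X) -> np.ndarray:
    Xv = np.asarray(X, dtype=float)
    if Xv.ndim != 2:
        raise ValueError("X must be a 2-D (samples x variables) matrix")
    if not np.isfinite(Xv).all():
        raise ValueError("X contains non-finite values; impute missing data first")
    return Xv


class UnitVarianceScaler(_ParamsMixin):
    """Mean-center each variable and divide by its sample SD (n-1).

    Zero-variance variables cannot be scaled and are dropped (their column
    indices are kept in ``dropped_``).
    """

    _param_names = ()

    def fit(self, X, y=None):
        Xv = _check_matrix(X)
        if Xv.shape[0] < 2:
            raise ValueError("unit-variance scaling needs at least two samples")
        self.mean_ = Xv.mean(axis=0)
        self.sd_ = Xv.std(axis=0, ddof=1)
        self.kept_ = np.flatnonzero(self.sd_ > 0)
        self.dropped_ = np.flatnonzero(self.sd_ == 0)
        if self.dropped_.size:
            import warnings

            warnings.warn(f"dropping {self.dropped_.size} zero-variance variable(s)",
                          stacklevel=2)
        return self

    def transform(self, X) -> np.ndarray:
        Xv = _check_matrix(X)
        return (Xv[:, self.kept_] - self.mean_[self.kept_]) / self.sd_[self.kept_]

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)


class PCAModel(_ParamsMixin):
    """Principal component analysis on a pre-scaled matrix.

    Components maximize explained variance in order; ``r2x_`` holds the
    fraction of total (centered) variance per component.  Loadings follow
    the sign convention that each component's largest-magnitude loading
    element is positive, so results do not depend on variable ordering.
    """

    _param_names = ("n_components",)

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        Xv = _check_matrix(X)
        n, k = Xv.shape
        if self.n_components > min(n - 1, k):
            raise ValueError(
                f"n_components={self.n_components} exceeds min(samples-1, variables)"
            )
        Xc = Xv - Xv.mean(axis=0)
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        A = self.n_components
        loadings = Vt[:A].T
        scores = U[:, :A] * s[:A]
        # fix signs: largest-magnitude loading element positive
        for a in range(A):
            j = np.argmax(np.abs(loadings[:, a]))
            if loadings[j, a] < 0:
                loadings[:, a] *= -1
                scores[:, a] *= -1
        total = (Xc ** 2).sum()
        self.scores_ = scores
        self.loadings_ = loadings
        self.r2x_ = (s[:A] ** 2) / total if total > 0 else np.zeros(A)
        self.mean_ = Xv.mean(axis=0)
        return self

    def transform(self, X) -> np.ndarray:
        Xv = _check_matrix(X)
        return (Xv - self.mean_) @ self.loadings_

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).scores_


def hotelling_ellipse(scores, alpha: float = 0.95):
    """Semi-axes of the Hotelling T2 confidence ellipse for a 2-D score plot.

    semi_axis_i = sqrt(var(score_i) * T2crit) with
    T2crit = 2 (n-1)(n+1) / (n (n-2)) * F_alpha(2, n-2).
    """
    S = np.asarray(scores, dtype=float)
    if S.ndim != 2 or S.shape[1] != 2:
        raise ValueError("scores must have exactly two columns")
    n = S.shape[0]
    if n < 4:
        raise ValueError("Hotelling ellipse needs at least 4 samples")
    t2crit = 2.0 * (n - 1) * (n + 1) / (n * (n - 2)) * stats.f.ppf(alpha, 2, n - 2)
    var = S.var(axis=0, ddof=1)
    return np.sqrt(var * t2crit)


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------

class OPLSDA(_ParamsMixin):
    """Two-class OPLS-DA with a single predictive component.

    Parameters
    ----------
    n_ortho:
        Number of orthogonal-in-X components removed before the predictive
        component is fitted.

    Fitted attributes (X assumed scaled, y coded 0/1): ``w_`` (unit-norm
    predictive weights), ``t_`` (predictive scores), ``p_`` (predictive
    loadings), ``c_`` (y loading), ``W_o_``/``T_o_``/``P_o_`` (orthogonal
    weights/scores/loadings, one column each per component), ``coef_``
    (regression vector on the deflated space), ``r2y_``, ``r2x_``
    (per component: orthogonal components first, predictive last).
    """

    _param_names = ("n_ortho",)

    def __init__(self, n_ortho: int = 0):
        self.n_ortho = n_ortho

    def fit(self, X, y):
        Xv = _check_matrix(X)
        yv = np.asarray(y, dtype=float).ravel()
        if yv.size != Xv.shape[0]:
            raise ValueError("X and y have incompatible shapes")
        classes = np.unique(yv)
        if classes.size != 2:
            raise ValueError("OPLS-DA needs exactly two classes present in y")
        if self.n_ortho < 0:
            raise ValueError("n_ortho must be >= 0")
        self.classes_ = classes
        self.y_mean_ = yv.mean()
        yc = yv - self.y_mean_
        ssx_total = float((Xv ** 2).sum())
        ssy_total = float((yc ** 2).sum())

        n_ortho = self.n_ortho
        max_ortho = max(min(Xv.shape[0] - 2, Xv.shape[1] - 1), 0)
        if n_ortho > max_ortho:
            import warnings

            warnings.warn(f"n_ortho truncated from {n_ortho} to rank limit {max_ortho}",
                          stacklevel=2)
            n_ortho = max_ortho

        Xd = Xv.copy()
        w = Xd.T @ yc
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValueError("y is uncorrelated with every variable; no model")
        w /= norm
        W_o, T_o, P_o, r2x = [], [], [], []
        for _ in range(n_ortho):
            t = Xd @ w
            p = Xd.T @ t / (t @ t)
            w_o = p - (w @ p) * w
            n_wo = np.linalg.norm(w_o)
            if n_wo < 1e-12:  # no orthogonal variation left
                break
            w_o /= n_wo
            t_o = Xd @ w_o
            p_o = Xd.T @ t_o / (t_o @ t_o)
            Xd = Xd - np.outer(t_o, p_o)
            W_o.append(w_o)
            T_o.append(t_o)
            P_o.append(p_o)
            r2x.append(float((t_o @ t_o) * (p_o @ p_o)) / ssx_total if ssx_total else 0.0)
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        c = float(yc @ t / (t @ t))
        self.w_ = w
        self.t_ = t
        self.p_ = p
        self.c_ = c
        self.W_o_ = np.column_stack(W_o) if W_o else np.empty((Xv.shape[1], 0))
        self.T_o_ = np.column_stack(T_o) if T_o else np.empty((Xv.shape[0], 0))
        self.P_o_ = np.column_stack(P_o) if P_o else np.empty((Xv.shape[1], 0))
        self.n_ortho_ = len(W_o)
        resid = yc - c * t
        self.r2y_ = 1.0 - float((resid ** 2).sum()) / ssy_total if ssy_total else 0.0
        self.r2x_ = np.array(r2x + [float((t @ t) * (p @ p)) / ssx_total if ssx_total else 0.0])
        self.ssy_pred_ = float(c * c * (t @ t))
        self.ssx_per_component_ = np.array(
            [float((T_o[i] @ T_o[i]) * (P_o[i] @ P_o[i])) for i in range(len(W_o))]
            + [float((t @ t) * (p @ p))]
        )
        return self

    def _deflate(self, X) -> np.ndarray:
        Xd = _check_matrix(X).copy()
        for a in range(self.n_ortho_):
            t_o = Xd @ self.W_o_[:, a]
            Xd = Xd - np.outer(t_o, self.P_o_[:, a])
        return Xd

    def transform(self, X):
        """Predictive and orthogonal scores of new (already scaled) data."""
        Xd = _check_matrix(X).copy()
        T_o = np.empty((Xd.shape[0], self.n_ortho_))
        for a in range(self.n_ortho_):
            T_o[:, a] = Xd @ self.W_o_[:, a]
            Xd = Xd - np.outer(T_o[:, a], self.P_o_[:, a])
        return Xd @ self.w_, T_o

    def predict(self, X) -> np.ndarray:
        """Continuous class prediction (around the 0/1 class codes)."""
        t, _ = self.transform(X)
        return self.y_mean_ + self.c_ * t

    def predict_class(self, X) -> np.ndarray:
        thr = self.classes_.mean()  # midpoint of the class codes
        return (self.predict(X) > thr).astype(int)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CvReport:
    """Sevenfold internal cross-validation summary of one OPLS-DA model."""

    folds: np.ndarray
    y_pred_cv: np.ndarray
    press: float
    q2: float
    n_ortho: int
    classification_rate: float
    n_correct: int
    n_total: int
    f: float = math.nan
    df1: int = 0
    df2: int = 0
    p: float = math.nan

    @property
    def components_string(self) -> str:
        return f"1 + {self.n_ortho} + 0"


def assign_folds(y, n_folds: int) -> np.ndarray:
    """Deterministic folds: contiguous blocks over samples ordered by
    (class, position).

    Blocks keep every training split in possession of both classes while a
    held-out fold may be single-class; this keeps cross-validation honest
    on null data (a fold's class mean is not mirrored in its training
    split), so pure-noise models score Q2 <= 0 essentially always.
    """
    yv = np.asarray(y)
    order = np.lexsort((np.arange(yv.size), yv))
    sizes = np.full(n_folds, yv.size // n_folds, dtype=int)
    sizes[: yv.size % n_folds] += 1
    folds = np.empty(yv.size, dtype=int)
    folds[order] = np.repeat(np.arange(n_folds), sizes)
    return folds


def cross_validate(X, y, n_ortho: int, folds: int = 7) -> CvReport:
    """Sevenfold internal cross-validation of an OPLS-DA model.

    Each sample is predicted exactly once by a model not trained on it.
    Q2 = 1 - PRESS/SSY with SSY the total (mean-centered) class-variable
    sum of squares; the classification rate uses the midpoint threshold.
    """
    Xv = _check_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    if folds > yv.size:
        raise ValueError("more folds than samples")
    fold_id = assign_folds(yv, folds)
    y_pred = np.empty_like(yv)
    for k in range(folds):
        test = fold_id == k
        if not test.any():
            continue
        train = ~test
        if np.unique(yv[train]).size < 2:
            raise ValueError(f"training split of fold {k} is missing a class")
        model = OPLSDA(n_ortho=n_ortho)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xv[train], yv[train])
        y_pred[test] = model.predict(Xv[test])
    press = float(((yv - y_pred) ** 2).sum())
    ssy = float(((yv - yv.mean()) ** 2).sum())
    q2 = 1.0 - press / ssy if ssy > 0 else 0.0
    thr = np.unique(yv).mean()
    correct = int(((y_pred > thr) == (yv > thr)).sum())
    return CvReport(folds=fold_id, y_pred_cv=y_pred, press=press, q2=q2,
                    n_ortho=n_ortho, classification_rate=correct / yv.size,
                    n_correct=correct, n_total=yv.size)


def cv_anova(press: float, ssy: float, n_components_total: int, n_samples: int):
    """CV-ANOVA: F test of cross-validated residuals against total y variance.

    F = ((SSY - PRESS)/df1) / (PRESS/df2), df1 = fitted components + 1,
    df2 = N - 1 - df1.  PRESS >= SSY clamps F to 0 (p = 1).
    """
    df1 = n_components_total + 1
    df2 = n_samples - 1 - df1
    if df2 <= 0:
        raise ValueError("not enough samples for CV-ANOVA degrees of freedom")
    if press >= ssy or press <= 0:
        f = 0.0 if press >= ssy else math.inf
    else:
        f = ((ssy - press) / df1) / (press / df2)
    p = float(stats.f.sf(f, df1, df2)) if math.isfinite(f) else 0.0
    return f, df1, df2, (1.0 if f == 0.0 else p)


def select_components(X, y, max_ortho: int = 10, folds: int = 7,
                      delta_q2: float = 0.01):
    """Choose the number of orthogonal components by internal CV.

    Starts at ``n_ortho = 0`` and adds an orthogonal component while
    Q2(cum) improves by more than ``delta_q2``.  If the best model's Q2 is
    <= 0, no model is suggested and ``(None, best_report)`` is returned
    (reported as "0 + 0 + 0").
    """
    best = cross_validate(X, y, 0, folds)
    for n_ortho in range(1, max_ortho + 1):
        try:
            rep = cross_validate(X, y, n_ortho, folds)
        except (ValueError, np.linalg.LinAlgError):
            break
        if rep.q2 > best.q2 + delta_q2:
            best = rep
        else:
            break
    if best.q2 <= 0:
        return None, best
    return best.n_ortho, best


def fit_cv_anova(report: CvReport, y) -> CvReport:
    """Attach CV-ANOVA statistics to a CV report (in place, returns it)."""
    yv = np.asarray(y, dtype=float)
    ssy = float(((yv - yv.mean()) ** 2).sum())
    f, df1, df2, p = cv_anova(report.press, ssy, report.n_ortho + 1, yv.size)
    report.f, report.df1, report.df2, report.p = f, df1, df2, p
    return report


# ---------------------------------------------------------------------------
# VIP and refinement
# ---------------------------------------------------------------------------

def vip(model: OPLSDA, kind: str = "total") -> np.ndarray:
    """Variable importance in the projection.

    VIP_j = sqrt( K * sum_a s_a (w_aj / ||w_a||)^2 / sum_a s_a ) where the
    sum runs over the predictive component (weighted by its explained
    y-variance) and, for ``kind="total"``, the orthogonal components
    (weighted by their explained X-variance).  ``kind="predictive"`` uses
    the predictive component only.  Mean VIP^2 is exactly 1.
    """
    if not hasattr(model, "w_"):
        raise ValueError("model must be fitted before computing VIP")
    K = model.w_.size
    # component shares on comparable (fraction-of-variance) scales:
    # predictive -> R2Y, orthogonal -> its R2X
    weights = [model.w_]
    shares = [model.r2y_]
    if kind == "total":
        for a in range(model.n_ortho_):
            weights.append(model.W_o_[:, a])
            shares.append(float(model.r2x_[a]))
    elif kind != "predictive":
        raise ValueError("kind must be 'total' or 'predictive'")
    shares = np.asarray(shares, dtype=float)
    if shares.sum() <= 0:
        shares = np.ones_like(shares)
    W = np.column_stack([w / np.linalg.norm(w) for w in weights])
    contrib = (W ** 2) @ shares
    return np.sqrt(K * contrib / shares.sum())


def refine_by_year(X, years, max_ortho: int = 10, folds: int = 7,
                   vip_threshold: float = 1.0, vip_kind: str = "total"):
    """Remove the year-dominated variables from a scaled matrix.

    Fits a year-vs-year OPLS-DA (components chosen by internal CV),
    computes VIP, and returns ``(kept variable indices, year model,
    CvReport)`` where kept variables have VIP <= ``vip_threshold``.
    Refinement is refused when no year model is suggested.
    """
    yr_codes, yr_levels = pd.factorize(np.asarray(years), sort=True)
    if yr_levels.size != 2:
        raise ValueError("refinement needs exactly two year labels")
    y = yr_codes.astype(float)
    n_ortho, report = select_components(X, y, max_ortho=max_ortho, folds=folds)
    if n_ortho is None:
        raise ValueError("no year model suggested (Q2 <= 0); refinement refused")
    model = OPLSDA(n_ortho=n_ortho).fit(X, y)
    scores = vip(model, kind=vip_kind)
    kept = np.flatnonzero(scores <= vip_threshold)
    if kept.size == 0:
        raise ValueError("refinement removed every variable; lower the VIP threshold")
    return kept, model, fit_cv_anova(report, y)


def external_validate(X_train, y_train, X_test, y_test, variables=None,
                      max_ortho: int = 10, folds: int = 7):
    """Train on one year, predict the other (external validation).

    Unit-variance scaling is fitted on the training data only and applied
    to the test data; model size is chosen by internal CV on the training
    set.  Returns a dict with predictions, scores (the continuous predicted
    y, used for ROC), the correct classification rate, and the model.
    """
    Xtr = _check_matrix(X_train)
    Xte = _check_matrix(X_test)
    if variables is not None:
        variables = np.asarray(variables)
        if variables.size == 0:
            raise ValueError("variable set must not be empty")
        Xtr = Xtr[:, variables]
        Xte = Xte[:, variables]
    ytr = np.asarray(y_train, dtype=float).ravel()
    yte = np.asarray(y_test, dtype=float).ravel()
    scaler = UnitVarianceScaler().fit(Xtr)
    Str = scaler.transform(Xtr)
    Ste = scaler.transform(Xte)
    n_ortho, report = select_components(Str, ytr, max_ortho=max_ortho, folds=folds)
    n_fit = 0 if n_ortho is None else n_ortho
    model = OPLSDA(n_ortho=n_fit).fit(Str, ytr)
    y_pred = model.predict(Ste)
    thr = model.classes_.mean()
    pred_class = (y_pred > thr).astype(int)
    correct = int((pred_class == yte.astype(int)).sum())
    return {
        "y_pred": y_pred,
        "pred_class": pred_class,
        "rate": correct / yte.size,
        "n_correct": correct,
        "n_total": int(yte.size),
        "model": model,
        "cv_report": report,
        "suggested": n_ortho is not None,
    }


def impute_missing_by_year(matrix: pd.DataFrame, years) -> pd.DataFrame:
    """Impute NaNs with the per-feature median of samples from the same year."""
    out = matrix.copy()
    yr = np.asarray(years)
    for lab in pd.unique(yr):
        sel = yr == lab
        block = out.loc[sel]
        med = block.median(axis=0, skipna=True)
        out.loc[sel] = block.fillna(med)
    if out.isna().any().any():
        out = out.fillna(out.median(axis=0, skipna=True))
    return out
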