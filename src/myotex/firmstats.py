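"""Firmness grouping, group-level regression and ANOVA.

Fillet firmness is the breaking force (N) of a flat-cylinder puncture test.
Fish are binned into five texture classes over the calibrated 6.6-20.9 N
span; the headline analysis regresses group-mean pericellular fraction on
group-mean force with a quadratic ("curvilinear") ordinary-least-squares
model, and one-way ANOVA compares specimen-level morphometric features
across classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .containers import FIRMNESS_GROUPS, UNCLASSIFIED

__all__ = [
    "GROUP_BOUNDS_N",
    "assign_firmness_group",
    "group_summary",
    "QuadraticTextureRegression",
    "fit_firmness_vs_pericellular",
    "CurvilinearFit",
    "anova_feature",
]

#: Closed breaking-force intervals (N) of the five texture classes.
GROUP_BOUNDS_N = {
    "soft": (6.6, 7.5),
    "low": (8.6, 9.5),
    "medium": (9.7, 12.5),
    "high": (13.1, 16.7),
    "hard": (17.7, 20.9),
}


def assign_firmness_group(force_N: float) -> str:
    """Map a breaking force to its texture class.

    The five class intervals are closed.  Forces falling in a gap between
    two intervals go to the class with the nearest boundary, ties toward the
    softer class; forces outside the overall 6.6-20.9 N span are
    ``"unclassified"``.  The mapping is total on (0, inf).
    """
    if force_N <= 0:
        raise ValueError("breaking force must be positive")
    overall_lo = GROUP_BOUNDS_N["soft"][0]
    overall_hi = GROUP_BOUNDS_N["hard"][1]
    if force_N < overall_lo or force_N > overall_hi:
        return UNCLASSIFIED
    best, best_dist = None, np.inf
    for name in FIRMNESS_GROUPS:  # soft -> hard, so ties resolve softer
        lo, hi = GROUP_BOUNDS_N[name]
        if lo <= force_N <= hi:
            return name
        dist = min(abs(force_N - lo), abs(force_N - hi))
        if dist < best_dist:
            best, best_dist = name, dist
    return best


def group_summary(records: pd.DataFrame, summaries: pd.DataFrame) -> pd.DataFrame:
    """Per-texture-group means of specimen-level features.

    ``records`` needs columns ``fish_id``, ``breaking_force_N``, ``group``;
    ``summaries`` needs ``fish_id`` plus numeric feature columns.  Returns
    one row per non-empty group (soft -> hard order) with the group-mean of
    every numeric feature, the group-mean force, and ``n_fish``.
    """
    merged = records.merge(summaries, on="fish_id", how="inner", validate="1:1")
    if merged.empty:
        raise ValueError("no fish shared between records and summaries")
    rows = []
    for name in FIRMNESS_GROUPS:
        sub = merged[merged["group"] == name]
        if sub.empty:
            warnings.warn(f"empty firmness group {name!r} excluded")
            continue
        feat = sub.select_dtypes("number").mean()
        feat["n_fish"] = len(sub)
        feat["group"] = name
        rows.append(feat)
    out = pd.DataFrame(rows).reset_index(drop=True)
    out["n_fish"] = out["n_fish"].astype(int)
    return out


@dataclass
class CurvilinearFit:
    """Quadratic OLS fit y = b0 + b1*x + b2*x^2 with model F-test."""

    coefficients: tuple  # (b0, b1, b2)
    r_squared: float
    p_value: float
    n_points: int

    def predict(self, x):
        b0, b1, b2 = self.coefficients
        x = np.asarray(x, dtype=float)
        return b0 + b1 * x + b2 * x**2


class QuadraticTextureRegression(RegressorMixin, BaseEstimator):
    """Quadratic OLS of a tissue response on breaking force.

    Scikit-learn-style estimator: ``fit(X, y)`` with ``X`` of shape
    ``(n, 1)`` (breaking force, N) regresses ``y`` (e.g. group-mean
    pericellular fraction) on ``(1, F, F^2)``.  An optional log-linear
    alternative (``form="loglinear"``: y on ``(1, log F)``) is provided for
    sensitivity analysis.

    Attributes
    ----------
    coef_ : ndarray
        ``(b0, b1, b2)`` for the quadratic form, ``(b0, b1)`` for log-linear.
    r_squared_, f_pvalue_ : float
        Coefficient of determination and model F-test p-value.
    n_points_ : int
    """

    def __init__(self, form: str = "quadratic"):
        self.form = form

    def _design(self, x):
        if self.form == "quadratic":
            return np.column_stack([np.ones_like(x), x, x**2])
        if self.form == "loglinear":
            return np.column_stack([np.ones_like(x), np.log(x)])
        raise ValueError(f"unknown form {self.form!r}")

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] != 1:
            raise ValueError("expected a single predictor column (force, N)")
        y = np.asarray(y, dtype=float)
        x = X[:, 0]
        min_n = 4 if self.form == "quadratic" else 3
        if len(x) < min_n:
            raise ValueError(f"need at least {min_n} points for an F-test")
        design = self._design(x)
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("degenerate predictor: design matrix is rank deficient")
        res = sm.OLS(y, design).fit()
        self.coef_ = np.asarray(res.params)
        self.r_squared_ = float(res.rsquared)
        self.f_pvalue_ = float(res.f_pvalue) if np.isfinite(res.f_pvalue) else np.nan
        self.n_points_ = len(x)
        self._result_ = res
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self._design(X[:, 0]) @ self.coef_


def fit_firmness_vs_pericellular(force_N, pericellular_fraction) -> CurvilinearFit:
    """OLS of pericellular fraction on (1, force, force^2).

    Constant responses are handled explicitly: the fit is flat with
    R^2 = 0 and an undefined (NaN) F-test p-value.
    """
    y = np.asarray(pericellular_fraction, dtype=float)
    if np.ptp(y) == 0:
        return CurvilinearFit((float(y[0]), 0.0, 0.0), 0.0, np.nan, len(y))
    est = QuadraticTextureRegression().fit(np.asarray(force_N, dtype=float), y)
    b0, b1, b2 = est.coef_
    return CurvilinearFit((float(b0), float(b1), float(b2)),
                          est.r_squared_, est.f_pvalue_, est.n_points_)


def anova_feature(values: pd.DataFrame, feature: str,
                  group_col: str = "group") -> tuple:
    """One-way fixed-effects ANOVA of a specimen-level feature across groups.

    Returns ``(F, p)``.  Requires at least two groups with at least two
    observations each; when every within-group variance is zero the F
    statistic is undefined and ``(nan, nan)`` is returned with a warning.
    The analysis is run at the specimen level (one value per fish), not the
    cell level, to avoid pseudo-replication.
    """
    samples = [g[feature].to_numpy(dtype=float)
               for _, g in values.groupby(group_col, observed=True)]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if all(np.ptp(s) == 0 for s in samples):
        warnings.warn("all within-group variances are zero; F undefined")
        return np.nan, np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_stat, p = stats.f_oneway(*samples)
    return float(f_stat), float(p)
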