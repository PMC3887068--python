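"""FT-IR preprocessing and analysis of endomysial connective tissue.

The chain is: Savitzky-Golay second derivative (band sharpening and baseline
suppression), extended multiplicative signal correction (EMSC) against the
set-mean reference, restriction to the sulfated-glycosaminoglycan
fingerprint window (800-1000 cm^-1 by default), unstandardized PCA of the
corrected spectra, and detection of wavenumbers where the hard-texture group
mean exceeds the soft-texture one.

EMSC models each measured spectrum z on a wavenumber axis x (rescaled to
[-1, 1] for conditioning) as

    z = a + b * m + d1 * x + d2 * x**2 + e,

with m a reference spectrum; the chemical signal is recovered as
``(z - a - d1*x - d2*x**2) / b``.  The quadratic baseline term covers both
wavenumber-independent and wavenumber-dependent additive effects, and the
division removes multiplicative (path-length / scattering) scaling.

Transformers follow the scikit-learn estimator contract and operate on raw
``(n_spectra, n_wavenumbers)`` arrays so they compose in pipelines; the
module-level functions are thin wrappers working on :class:`SpectraSet`
containers and maintaining the processing log.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .containers import SpectraSet

__all__ = [
    "SavitzkyGolaySecondDerivative",
    "EMSCCorrection",
    "RegionSelector",
    "UnstandardizedPCA",
    "sg_second_derivative",
    "emsc_correct",
    "select_region",
    "pca_scores",
    "differential_peaks",
    "EMSCResult",
    "PcaScores",
]


def _check_grid(wavenumbers: np.ndarray) -> float:
    wn = np.asarray(wavenumbers, dtype=float)
    steps = np.diff(wn)
    if wn.size < 2 or not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise ValueError("wavenumber grid must be evenly spaced")
    return float(steps[0])


class SavitzkyGolaySecondDerivative(TransformerMixin, BaseEstimator):
    """Per-spectrum Savitzky-Golay second derivative.

    Output units are absorbance per (cm^-1)^2: the filter is scaled by the
    grid step.  Edges are handled by evaluating the local polynomial fitted
    within the first/last window, so a globally quadratic spectrum
    differentiates exactly everywhere.

    Parameters
    ----------
    window_points : odd int, default 11
    poly_order : int >= 2, default 3
    wavenumbers : array, optional
        Grid used to derive the step; a unit step is assumed when omitted.
    """

    def __init__(self, window_points: int = 11, poly_order: int = 3,
                 wavenumbers=None):
        self.window_points = window_points
        self.poly_order = poly_order
        self.wavenumbers = wavenumbers

    def _validate(self, n_cols: int) -> float:
        if self.window_points % 2 == 0:
            raise ValueError("window_points must be odd")
        if not 2 <= self.poly_order < self.window_points:
            raise ValueError("need window_points > poly_order >= 2")
        if self.window_points >= n_cols:
            raise ValueError("window_points must be smaller than the grid")
        if self.wavenumbers is None:
            return 1.0
        return _check_grid(self.wavenumbers)

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self.delta_ = self._validate(X.shape[1])
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "delta_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return savgol_filter(X, self.window_points, self.poly_order,
                             deriv=2, delta=self.delta_, axis=1, mode="interp")


@dataclass
class EMSCResult:
    corrected: SpectraSet
    parameters: pd.DataFrame  # columns a, b, d1, d2; one row per spectrum
    reference: np.ndarray


class EMSCCorrection(TransformerMixin, BaseEstimator):
    """Extended multiplicative signal correction with a quadratic baseline.

    ``fit`` stores the reference spectrum (given, or the column mean of the
    fitted data).  ``transform`` regresses every spectrum on
    ``(1, x, x**2, m)`` by least squares and returns
    ``(z - a - d1*x - d2*x**2) / b``.  Spectra whose multiplicative
    coefficient falls below ``b_tol`` in magnitude cannot be corrected
    stably; they are flagged and passed through unchanged with a warning.
    """

    def __init__(self, reference=None, b_tol: float = 1e-8, wavenumbers=None):
        self.reference = reference
        self.b_tol = b_tol
        self.wavenumbers = wavenumbers

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.reference is not None:
            ref = np.asarray(self.reference, dtype=float)
            if ref.size != X.shape[1]:
                raise ValueError("reference must live on the same grid")
        else:
            if X.shape[0] < 2:
                raise ValueError("need >= 2 spectra to use the set mean as "
                                 "reference")
            ref = X.mean(axis=0)
        self.reference_ = ref
        if self.wavenumbers is not None:
            wn = np.asarray(self.wavenumbers, dtype=float)
            x = 2.0 * (wn - wn[0]) / (wn[-1] - wn[0]) - 1.0
        else:
            x = np.linspace(-1.0, 1.0, X.shape[1])
        self.axis_ = x
        self.n_features_in_ = X.shape[1]
        return self

    def correct(self, X):
        """Correct spectra and return ``(corrected, params, flagged)``."""
        check_is_fitted(self, "reference_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        x = self.axis_
        design = np.column_stack([np.ones_like(x), x, x**2, self.reference_])
        coef, *_ = np.linalg.lstsq(design, X.T, rcond=None)
        a, d1, d2, b = coef
        flagged = np.abs(b) < self.b_tol
        if flagged.any():
            warnings.warn(f"{int(flagged.sum())} spectrum/spectra with |b| < "
                          f"{self.b_tol}: left uncorrected")
        baseline = (a[:, None] + np.outer(d1, x) + np.outer(d2, x**2))
        b_safe = np.where(flagged, 1.0, b)
        corrected = np.where(flagged[:, None], X, (X - baseline) / b_safe[:, None])
        params = pd.DataFrame({"a": a, "b": b, "d1": d1, "d2": d2,
                               "flagged": flagged})
        return corrected, params, flagged

    def transform(self, X):
        return self.correct(X)[0]


class RegionSelector(TransformerMixin, BaseEstimator):
    """Restrict spectra to an inclusive wavenumber window."""

    def __init__(self, lo_cm1: float, hi_cm1: float, wavenumbers=None):
        self.lo_cm1 = lo_cm1
        self.hi_cm1 = hi_cm1
        self.wavenumbers = wavenumbers

    def fit(self, X, y=None):
        if not self.lo_cm1 < self.hi_cm1:
            raise ValueError("need lo_cm1 < hi_cm1")
        wn = np.asarray(self.wavenumbers, dtype=float)
        mask = (wn >= self.lo_cm1) & (wn <= self.hi_cm1)
        if not mask.any():
            raise ValueError("empty region: no grid points in window")
        self.mask_ = mask
        self.selected_wavenumbers_ = wn[mask]
        return self

    def transform(self, X):
        check_is_fitted(self, "mask_")
        return np.atleast_2d(np.asarray(X, dtype=float))[:, self.mask_]


class UnstandardizedPCA(TransformerMixin, BaseEstimator):
    """PCA on mean-centred (never variance-scaled) spectra.

    Columns are centred but not standardized, so high-absorbance bands keep
    their weight — the convention for derivative FT-IR spectra.  Loadings
    follow a deterministic sign rule: the largest-magnitude element of each
    loading vector is positive.  If the data have lower rank than requested,
    the available components are returned with a warning.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n, p = X.shape
        if n < 2:
            raise ValueError("need at least 2 spectra")
        if self.n_components > min(n - 1, p):
            raise ValueError("n_components exceeds min(n_spectra - 1, "
                             "n_wavenumbers)")
        limit = min(n - 1, p)
        pca = PCA(n_components=limit, svd_solver="full")
        pca.fit(X)
        var = pca.explained_variance_
        rank = int(np.sum(var > max(var.max(), 1.0) * 1e-12)) if var.size else 0
        k = self.n_components
        if rank < k:
            warnings.warn(f"rank {rank} below requested {k} components; "
                          "returning fewer")
            k = rank
        comps = pca.components_[:k].copy()
        # sign convention: largest-|.| loading element positive
        flip = np.sign(comps[np.arange(k), np.argmax(np.abs(comps), axis=1)])
        comps *= flip[:, None]
        self.mean_ = pca.mean_
        self.components_ = comps
        self.explained_variance_ = var[:k]
        self.total_variance_ = float(var.sum())
        self.n_components_ = k
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.mean_) @ self.components_.T

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


@dataclass
class PcaScores:
    scores: np.ndarray              # (n_spectra, k)
    loadings: np.ndarray            # (k, n_wavenumbers)
    explained_variance: np.ndarray  # length k
    total_variance: float


# ---------------------------------------------------------------------------
# SpectraSet-level wrappers


def sg_second_derivative(spectra: SpectraSet, window_points: int = 11,
                         poly_order: int = 3) -> SpectraSet:
    est = SavitzkyGolaySecondDerivative(window_points, poly_order,
                                        wavenumbers=spectra.wavenumbers)
    out = est.fit(spectra.absorbance).transform(spectra.absorbance)
    return spectra.copy_with(
        absorbance=out,
        log_entry={"step": "sg_second_derivative",
                   "window_points": window_points, "poly_order": poly_order},
    )


def emsc_correct(spectra: SpectraSet, reference=None) -> EMSCResult:
    est = EMSCCorrection(reference=reference, wavenumbers=spectra.wavenumbers)
    est.fit(spectra.absorbance)
    corrected, params, _flagged = est.correct(spectra.absorbance)
    out = spectra.copy_with(
        absorbance=corrected,
        log_entry={"step": "emsc_correct",
                   "reference": "given" if reference is not None else "set_mean"},
    )
    return EMSCResult(corrected=out, parameters=params,
                      reference=est.reference_)


def select_region(spectra: SpectraSet, lo_cm1: float, hi_cm1: float) -> SpectraSet:
    sel = RegionSelector(lo_cm1, hi_cm1, wavenumbers=spectra.wavenumbers)
    sel.fit(spectra.absorbance)
    return spectra.copy_with(
        absorbance=sel.transform(spectra.absorbance),
        wavenumbers=sel.selected_wavenumbers_,
        log_entry={"step": "select_region", "lo_cm1": lo_cm1, "hi_cm1": hi_cm1},
    )


def pca_scores(spectra: SpectraSet, n_components: int = 2) -> PcaScores:
    est = UnstandardizedPCA(n_components).fit(spectra.absorbance)
    return PcaScores(
        scores=est.transform(spectra.absorbance),
        loadings=est.components_,
        explained_variance=est.explained_variance_,
        total_variance=est.total_variance_,
    )


def differential_peaks(mean_hard, mean_soft, wavenumbers,
                       prominence: float = None,
                       n_peaks: int = None) -> np.ndarray:
    """Wavenumbers where the hard-group mean exceeds the soft-group mean.

    Works on second-derivative (EMSC-corrected) group means: absolute values
    are compared because differentiation inverts band signs, and local
    maxima of ``|mean_hard| - |mean_soft|`` above the prominence threshold
    are returned in ascending wavenumber order.  The default prominence is
    three times the median absolute deviation of the difference trace.
    ``n_peaks`` keeps only the that many most prominent maxima (derivative
    band shapes produce side lobes flanking each true band centre).
    """
    mean_hard = np.asarray(mean_hard, dtype=float)
    mean_soft = np.asarray(mean_soft, dtype=float)
    wn = np.asarray(wavenumbers, dtype=float)
    if mean_hard.shape != mean_soft.shape or mean_hard.shape != wn.shape:
        raise ValueError("means and grid must share one shape")
    diff = np.abs(mean_hard) - np.abs(mean_soft)
    if prominence is None:
        mad = np.median(np.abs(diff - np.median(diff)))
        prominence = 3.0 * mad
        if prominence == 0:
            # sparse difference traces (zero almost everywhere) have zero
            # MAD; fall back to a fraction of the largest excursion
            prominence = 0.05 * np.abs(diff).max()
    if prominence <= 0:
        return np.array([], dtype=float)
    idx, props = find_peaks(diff, prominence=prominence)
    if n_peaks is not None and len(idx) > n_peaks:
        keep = np.argsort(props["prominences"])[-n_peaks:]
        idx = idx[keep]
    return np.sort(wn[idx])


def group_mean_spectra(spectra: SpectraSet) -> dict:
    """Mean spectrum per group label."""
    if spectra.groups is None:
        raise ValueError("spectra set carries no group labels")
    return {g: spectra.absorbance[spectra.groups == g].mean(axis=0)
            for g in np.unique(spectra.groups)}
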