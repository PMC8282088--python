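"""Detrended fluctuation analysis (DFA).

DFA quantifies long-range temporal correlation in the time domain, which
complements spectral power-law fitting and remains valid for nonstationary
records.  The procedure: (1) remove the global mean and cumulatively sum the
series (the "profile"); (2) split the profile into non-overlapping windows of
n samples; (3) subtract a polynomial trend (order 2 by default, which removes
the integrated image of linear trends in the raw data) within each window;
(4) take the root mean square of the residuals over all windowed samples as
F(n).  For scale-free signals F(n) ~ n^alpha: alpha = 0.5 for uncorrelated
noise, alpha > 0.5 for persistent correlations, alpha = H for fractional
Gaussian noise, and alpha ~ (beta + 1) / 2 relative to the spectral exponent.

Two implementations are provided: a vectorized one (`dfa`) and a deliberately
literal loop-per-window one (`dfa_oracle`) used to cross-check it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .trace import SignalTrace

__all__ = ["DFAResult", "DFAEstimator", "dfa", "dfa_oracle", "auto_scales"]


@dataclass(frozen=True)
class DFAResult:
    scales: np.ndarray       # window sizes n, strictly increasing
    fluct: np.ndarray        # F(n), same units as the input
    alpha: float             # scaling exponent from OLS of log F on log n
    r2: float
    detrend_order: int


def auto_scales(n_samples: int, n_scales: int = 16, min_scale: int = 10,
                ) -> np.ndarray:
    """Default grid: log-spaced window sizes from ``min_scale`` to N/4."""
    max_scale = n_samples // 4
    if max_scale <= min_scale:
        raise ValueError(f"series too short for DFA: n={n_samples}")
    scales = np.unique(np.round(np.geomspace(min_scale, max_scale,
                                             n_scales)).astype(int))
    return scales


def _profile(x: np.ndarray) -> np.ndarray:
    return np.cumsum(x - x.mean())


def _check_input(x, scales, order):
    values = np.asarray(getattr(x, "values", x), dtype=float)
    if order < 1:
        raise ValueError("detrend order must be >= 1")
    if np.ptp(values) == 0:
        raise ValueError("constant input: F(n) = 0, scaling exponent undefined")
    if scales is None:
        scales = auto_scales(values.size)
    scales = np.asarray(scales, dtype=int)
    if np.any(np.diff(scales) <= 0):
        raise ValueError("scales must be strictly increasing")
    if values.size < 4 * scales.max():
        raise ValueError("need series length >= 4 * max(scales)")
    return values, scales


def _fit_loglog(scales, fluct):
    if np.size(scales) < 2:
        return float("nan"), float("nan")  # single scale: no slope to fit
    lx, ly = np.log10(scales), np.log10(fluct)
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), r2


class DFAEstimator(BaseEstimator):
    """Sklearn-style wrapper around :func:`dfa`.

    Attributes (after ``fit``): ``scales_``, ``fluct_``, ``alpha_``, ``r2_``.
    """

    def __init__(self, scales=None, order: int = 2):
        self.scales = scales
        self.order = order

    def fit(self, x, y=None) -> "DFAEstimator":
        res = dfa(x, scales=self.scales, order=self.order)
        self.scales_ = res.scales
        self.fluct_ = res.fluct
        self.alpha_ = res.alpha
        self.r2_ = res.r2
        return self

    @property
    def result_(self) -> DFAResult:
        return DFAResult(self.scales_, self.fluct_, self.alpha_, self.r2_,
                         self.order)


def dfa(x: SignalTrace | np.ndarray, scales=None, order: int = 2) -> DFAResult:
    """Vectorized DFA.

    Windows are taken from the start of the profile; a trailing partial
    window is discarded.  F(n) is the RMS of residuals over all samples that
    fall in complete windows.  alpha and r2 come from unweighted OLS of
    log10 F on log10 n.
    """
    values, scales = _check_input(x, scales, order)
    prof = _profile(values)
    fluct = np.empty(scales.size)
    for i, n in enumerate(scales):
        n_win = prof.size // n
        seg = prof[:n_win * n].reshape(n_win, n)
        # shared detrending basis: orthonormal columns of the Vandermonde QR
        t = np.arange(n, dtype=float)
        v = np.vander(t, order + 1, increasing=True)
        q, _ = np.linalg.qr(v)
        resid = seg - (seg @ q) @ q.T
        fluct[i] = np.sqrt(np.mean(resid ** 2))
    slope, r2 = _fit_loglog(scales, fluct)
    return DFAResult(scales, fluct, slope, r2, order)


def dfa_oracle(x: SignalTrace | np.ndarray, scales=None,
               order: int = 2) -> DFAResult:
    """Literal loop-per-window DFA, kept naive on purpose as a cross-check.

    Each of the four steps (demean+integrate, window, polynomial detrend,
    RMS over all windowed samples) is performed with explicit loops and
    per-window `polyfit`; intended for short inputs (n <= 1e4).
    """
    values, scales = _check_input(x, scales, order)
    prof = _profile(values)
    fluct = np.empty(scales.size)
    for i, n in enumerate(scales):
        n_win = prof.size // n
        sq_sum = 0.0
        count = 0
        for w in range(n_win):
            seg = prof[w * n:(w + 1) * n]
            t = np.arange(n, dtype=float)
            coef = np.polyfit(t, seg, order)
            trend = np.polyval(coef, t)
            res = seg - trend
            sq_sum += float(np.sum(res ** 2))
            count += n
        fluct[i] = np.sqrt(sq_sum / count)
    slope, r2 = _fit_loglog(scales, fluct)
    return DFAResult(scales, fluct, slope, r2, order)
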