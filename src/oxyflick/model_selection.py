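"""Corrected-AIC comparison of spectral shape models.

Is a spectrum genuinely power-law, or would an exponential or log-normal
decay describe it as well?  Each candidate is a two-parameter linear
regression on transformed coordinates of the log-resampled spectrum:

* power_law:    ln P ~ a + b * ln f            (straight line in log-log)
* exponential:  ln P ~ a + b * f               (straight line in semilog)
* log_normal:   ln P ~ a + b * (ln f)^2        (Gaussian-in-log-f shape)

Each model therefore has exactly K = 3 estimated parameters (slope,
intercept, residual variance).  With Gaussian residuals,
``AIC = n ln(sigma2) + 2K`` where ``sigma2 = SSE/n`` is the maximum-
likelihood residual variance, and the small-sample correction is
``AICc = AIC + 2K(K+1)/(n-K-1)``.  Pairs of models whose AICc differ by less
than 2 are treated as indistinguishable; otherwise the lower AICc wins.

The log-normal shape admits a second reading — a full quadratic in ln f —
which carries one extra parameter; it is available via
``log_normal_form="quadratic"`` for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .spectral import DEFAULT_BAND, PowerSpectrum, log_resample

__all__ = ["ModelFit", "ComparisonVerdict", "SpectrumModelSelector",
           "fit_spectrum_model", "compare_models", "aicc_from_sigma2"]

MODELS = ("power_law", "exponential", "log_normal")
DELTA_THRESHOLD = 2.0


@dataclass(frozen=True)
class ModelFit:
    model: str
    params: tuple[float, float]     # (slope, intercept) on transformed axes
    sigma2: float                   # ML residual variance, SSE/n
    K: int                          # parameter count incl. sigma2
    n: int
    aicc: float


@dataclass(frozen=True)
class ComparisonVerdict:
    delta_aicc: dict[str, float]    # alternative -> AICc(alt) - AICc(power law)
    verdict: str                    # {power_law, alternative, inconclusive}
    best_model: str


def aicc_from_sigma2(sigma2: float, n: int, K: int = 3) -> float:
    """AICc = n ln(sigma2) + 2K + 2K(K+1)/(n-K-1)."""
    if n <= K + 1:
        raise ValueError(f"need n > K+1 = {K + 1} points, got {n}")
    aic = n * np.log(sigma2) + 2 * K
    return float(aic + 2 * K * (K + 1) / (n - K - 1))


def _design(model: str, f: np.ndarray, log_normal_form: str) -> np.ndarray:
    if model == "power_law":
        cols = [np.log(f)]
    elif model == "exponential":
        cols = [f]
    elif model == "log_normal":
        if log_normal_form == "quadratic":
            cols = [np.log(f), np.log(f) ** 2]
        else:
            cols = [np.log(f) ** 2]
    else:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    return np.column_stack([np.ones_like(f)] + cols)


def fit_spectrum_model(ps: PowerSpectrum, model: str,
                       band: tuple[float, float] = DEFAULT_BAND,
                       log_normal_form: str = "squared_log") -> ModelFit:
    """OLS fit of one candidate shape to ln P over the band.

    The spectrum is log-resampled first (if not already) so that every model
    sees the identical, log-uniform point set — a prerequisite for AICc
    comparability.
    """
    if "log_resampled" not in ps.taper_meta:
        ps = log_resample(ps, band=band)
    m = (ps.freqs >= band[0]) & (ps.freqs <= band[1]) & (ps.power > 0)
    f, p = ps.freqs[m], ps.power[m]
    if f.size < 10:
        raise ValueError(f"need >= 10 points in band, got {f.size}")
    X = _design(model, f, log_normal_form)
    y = np.log(p)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    sse = float(np.sum((y - X @ coef) ** 2))
    n = f.size
    sigma2 = max(sse / n, np.finfo(float).tiny)  # guard exact fits from log(0)
    K = X.shape[1] + 1                            # regression coefs + sigma2
    slope = float(coef[1]) if coef.size > 1 else 0.0
    return ModelFit(model, (slope, float(coef[0])), sigma2, K, n,
                    aicc_from_sigma2(sigma2, n, K))


def compare_models(fits: list[ModelFit]) -> ComparisonVerdict:
    """Pairwise AICc comparison of alternatives against the power-law fit."""
    by_name = {f.model: f for f in fits}
    if "power_law" not in by_name:
        raise ValueError("comparison requires a power_law fit")
    ns = {f.n for f in fits}
    if len(ns) != 1:
        raise ValueError(f"fits were made on different point sets: n = {ns}")
    pl = by_name["power_law"]
    delta = {name: f.aicc - pl.aicc for name, f in by_name.items()
             if name != "power_law"}
    best = min(fits, key=lambda f: f.aicc)
    if all(abs(d) < DELTA_THRESHOLD for d in delta.values()):
        verdict = "inconclusive"
    elif best.model == "power_law":
        verdict = "power_law"
    elif abs(best.aicc - pl.aicc) >= DELTA_THRESHOLD:
        verdict = "alternative"
    else:
        verdict = "inconclusive"
    return ComparisonVerdict(delta, verdict, best.model)


class SpectrumModelSelector(BaseEstimator):
    """Fit all three spectral shapes and keep the AICc comparison.

    Attributes (after ``fit``): ``fits_`` (dict model -> ModelFit),
    ``verdict_`` (ComparisonVerdict), ``best_model_``.
    """

    def __init__(self, band: tuple[float, float] = DEFAULT_BAND,
                 log_normal_form: str = "squared_log"):
        self.band = band
        self.log_normal_form = log_normal_form

    def fit(self, ps: PowerSpectrum, y=None) -> "SpectrumModelSelector":
        if "log_resampled" not in ps.taper_meta:
            ps = log_resample(ps, band=self.band)
        self.fits_ = {m: fit_spectrum_model(ps, m, band=self.band,
                                            log_normal_form=self.log_normal_form)
                      for m in MODELS}
        self.verdict_ = compare_models(list(self.fits_.values()))
        self.best_model_ = self.verdict_.best_model
        return self
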