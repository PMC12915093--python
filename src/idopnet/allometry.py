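"""Allometric scaling power fits: y_j(E) = alpha_j * E^beta_j.

Each gene's expression forms a part-whole relationship with its compartment
(or ecosystem/niche) index across samples; allometric scaling theory says the
relationship follows a power law.  ``alpha`` is a positive scale constant and
``beta`` the scaling exponent.  Fitting is raw-scale least squares so the
residuals match the additive-noise model used by the clustering and network
likelihoods; log-scale fitting is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from idopnet.errors import FitError
from idopnet.io_indices import IndexSeries

_TOL = 1e-8


@dataclass
class PowerFit:
    """Fitted power-equation parameters for one gene against one index."""

    alpha: float
    beta: float
    sigma2: float
    n_used: int

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise FitError(f"alpha must be positive, got {self.alpha}")
        if self.sigma2 < 0:
            raise FitError("sigma2 must be nonnegative")
        if self.n_used < 2:
            raise FitError("need at least 2 samples")


def _as_values(E) -> np.ndarray:
    if isinstance(E, IndexSeries):
        return np.asarray(E.values, dtype=float)
    return np.asarray(E, dtype=float)


def _profiled_alpha(beta: float, y: np.ndarray, E: np.ndarray) -> float:
    """Least-squares alpha for fixed beta (closed form)."""
    p = E**beta
    denom = float(p @ p)
    if denom <= 0.0:
        return 0.0
    return float(p @ y) / denom


def _rss(beta: float, y: np.ndarray, E: np.ndarray) -> float:
    a = _profiled_alpha(beta, y, E)
    r = y - a * E**beta
    return float(r @ r)


def fit_power(y, E, log_scale: bool = False) -> PowerFit:
    """Fit y = alpha * E^beta by least squares.

    Initialized from ordinary log-log regression on strictly positive pairs,
    then refined on the raw scale with beta profiled against its closed-form
    alpha.  Zeros in ``y`` are excluded from the initialization but kept in
    the raw-scale refinement.

    Parameters
    ----------
    y : array-like
        Nonnegative expression values, one per sample.
    E : IndexSeries or array-like
        Driving index values, same length.
    log_scale : bool
        If True, return the log-log OLS fit (multiplicative error model)
        instead of refining on the raw scale.
    """
    y = np.asarray(y, dtype=float)
    Ev = _as_values(E)
    if y.shape != Ev.shape:
        raise FitError("y and E must have the same length")
    pos = (y > 0) & (Ev > 0)
    if pos.sum() < 2:
        raise FitError("need at least 2 samples with positive y and E")
    if np.ptp(Ev[pos]) == 0.0 and np.ptp(Ev) == 0.0:
        raise FitError("all index values equal: exponent unidentifiable")

    # log-log OLS initialization
    lx, ly = np.log(Ev[pos]), np.log(y[pos])
    if np.ptp(lx) == 0.0:
        beta0 = 0.0
        alpha0 = float(np.exp(ly.mean() - beta0 * lx.mean()))
    else:
        beta0, la0 = np.polyfit(lx, ly, 1)
        alpha0 = float(np.exp(la0))
    if log_scale:
        resid = ly - (np.log(alpha0) + beta0 * lx)
        return PowerFit(alpha0, float(beta0), float(resid @ resid / pos.sum()),
                        int(pos.sum()))

    # raw-scale refinement: 1-D profiled search around the initializer
    keep = Ev > 0
    yr, Er = y[keep], Ev[keep]
    half = max(2.0, 4.0 * abs(beta0))
    res = minimize_scalar(
        _rss, args=(yr, Er), method="bounded",
        bounds=(beta0 - half, beta0 + half),
        options={"xatol": _TOL},
    )
    beta = float(res.x)
    # keep whichever of {initializer, refined} has the smaller raw-scale RSS
    if _rss(beta0, yr, Er) < _rss(beta, yr, Er):
        beta = float(beta0)
    alpha = _profiled_alpha(beta, yr, Er)
    if alpha <= 0:
        alpha = np.finfo(float).tiny
    r = yr - alpha * Er**beta
    return PowerFit(float(alpha), beta, float(r @ r / yr.size), int(yr.size))


def predict_power(fit: PowerFit, E) -> np.ndarray:
    """Evaluate alpha * E^beta elementwise; 0^beta = 0 for beta > 0."""
    Ev = _as_values(E)
    if np.any(Ev < 0):
        raise FitError("index values must be nonnegative")
    if fit.beta < 0 and np.any(Ev == 0):
        raise FitError("alpha*E^beta undefined at E=0 for beta<0")
    with np.errstate(divide="ignore"):
        out = fit.alpha * np.power(Ev, fit.beta)
    return out


def fit_power_batch(Y: np.ndarray, E, log_scale: bool = False) -> list[PowerFit]:
    """Row-wise :func:`fit_power` over a genes x samples matrix."""
    return [fit_power(Y[j], E, log_scale=log_scale) for j in range(Y.shape[0])]
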