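"""Legendre orthogonal polynomial (LOP) curve algebra.

Independent and dependent ODE kernels are represented nonparametrically as
finite Legendre series on a normalized domain: the driving variable (an index
or a smoothed expression level) is mapped linearly from [lo, hi] onto [-1, 1]
where the Legendre polynomials P_0..P_r are orthogonal.  Differentiation and
integration are exact linear maps on the coefficients (with the chain-rule
factor 2/(hi-lo)), which is what justifies fitting the ODE system in integral
space: the integral of a Legendre series has the same basis parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre as L

from idopnet.errors import FitError


@dataclass
class LOPCurve:
    """A Legendre series: coeffs[k] multiplies P_k(t(x)), t linear [lo,hi]->[-1,1]."""

    coeffs: np.ndarray
    domain: tuple[float, float]
    extrapolate: str = "error"  # or "clamp"

    def __post_init__(self) -> None:
        self.coeffs = np.atleast_1d(np.asarray(self.coeffs, dtype=float))
        if not np.all(np.isfinite(self.coeffs)):
            raise FitError("non-finite LOP coefficients")
        lo, hi = self.domain
        if not lo < hi:
            raise FitError(f"degenerate domain [{lo}, {hi}]")

    @property
    def order(self) -> int:
        return self.coeffs.size - 1

    def _normalize(self, x: np.ndarray) -> np.ndarray:
        lo, hi = self.domain
        t = (2.0 * (np.asarray(x, dtype=float) - lo) / (hi - lo)) - 1.0
        if self.extrapolate == "clamp":
            return np.clip(t, -1.0, 1.0)
        if np.any(t < -1.0 - 1e-12) or np.any(t > 1.0 + 1e-12):
            raise FitError(
                f"value outside curve domain {self.domain}; "
                "pass extrapolate='clamp' to clamp"
            )
        return np.clip(t, -1.0, 1.0)

    def __call__(self, x) -> np.ndarray:
        return L.legval(self._normalize(x), self.coeffs)

    def to_dict(self) -> dict:
        return {
            "order": self.order,
            "domain": [float(self.domain[0]), float(self.domain[1])],
            "coeffs": [float(c) for c in self.coeffs],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LOPCurve":
        return cls(np.asarray(d["coeffs"], dtype=float), tuple(d["domain"]))


def _to_unit(x: np.ndarray, domain: tuple[float, float],
             extrapolate: str = "error") -> np.ndarray:
    lo, hi = domain
    if not lo < hi:
        raise FitError(f"degenerate domain [{lo}, {hi}]")
    t = (2.0 * (np.asarray(x, dtype=float) - lo) / (hi - lo)) - 1.0
    if extrapolate == "clamp":
        return np.clip(t, -1.0, 1.0)
    if np.any(np.abs(t) > 1.0 + 1e-12):
        raise FitError(f"value outside domain [{lo}, {hi}]")
    return np.clip(t, -1.0, 1.0)


def lop_design(x, domain: tuple[float, float], order: int,
               extrapolate: str = "error") -> np.ndarray:
    """Design matrix with column k = P_k(t(x)), shape (n, order+1)."""
    t = _to_unit(np.asarray(x, dtype=float), domain, extrapolate)
    return L.legvander(t, order)


def fit_lop(x, y, order: int, domain: tuple[float, float] | None = None) -> LOPCurve:
    """Least-squares Legendre series through (x, y).

    Exactly reproduces any polynomial of degree <= order in the normalized
    variable.  Domain defaults to the min-max range of x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if domain is None:
        domain = (float(x.min()), float(x.max()))
    if np.unique(x).size < order + 1:
        raise FitError(f"need at least {order + 1} distinct x values")
    X = lop_design(x, domain, order)
    coeffs, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < order + 1:
        raise FitError("rank-deficient LOP design")
    return LOPCurve(coeffs, domain)


def differentiate(c: LOPCurve) -> LOPCurve:
    """Exact derivative with respect to the original (unnormalized) variable."""
    if c.order < 1:
        raise FitError("cannot differentiate an order-0 curve")
    lo, hi = c.domain
    dcoef = L.legder(c.coeffs) * (2.0 / (hi - lo))
    return LOPCurve(dcoef, c.domain, c.extrapolate)


def integrate(c: LOPCurve, at0: float = 0.0) -> LOPCurve:
    """Exact antiderivative, pinned so the result equals ``at0`` at x = lo."""
    lo, hi = c.domain
    icoef = L.legint(c.coeffs) * ((hi - lo) / 2.0)
    shift = at0 - L.legval(-1.0, icoef)
    icoef = icoef.copy()
    icoef[0] += shift
    return LOPCurve(icoef, c.domain, c.extrapolate)
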