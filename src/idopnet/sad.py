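"""First-order structured antedependence (SAD(1)) residual covariance.

Residuals along the ordered index grid follow the nonstationary
innovation-driven recursion e_1 = eps_1, e_i = phi * e_{i-1} + eps_i with
iid N(0, nu2) innovations.  This gives the closed forms

    Cov(e_s, e_t) = nu2 * phi^|t-s| * (1 - phi^(2 min(s,t))) / (1 - phi^2)
    det(Sigma)    = nu2^n
    log-density   = -n/2 log(2 pi nu2) - sum_i eps_i^2 / (2 nu2)

used by both the network likelihood and functional clustering.  The
two-compartment version couples a scion block and a rootstock block through a
single same-grid-position correlation rho_c.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from idopnet.errors import FitError, NotPositiveDefiniteError

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class SADParams:
    """SAD(1) parameters on a length-n grid: |phi| < 1, nu2 > 0."""

    phi: float
    nu2: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.phi) >= 1.0:
            raise FitError(f"|phi| must be < 1, got {self.phi}")
        if self.nu2 <= 0.0:
            raise FitError(f"nu2 must be positive, got {self.nu2}")
        if self.n < 1:
            raise FitError("grid length must be >= 1")


@dataclass
class BlockCov:
    """Scion/rootstock residual covariance for one grafting combination.

    Diagonal blocks are SAD(1); the cross block correlates the two segments
    only at matching grid positions, with a single coefficient rho_c.
    """

    scion: SADParams
    rootstock: SADParams
    rho_c: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.rho_c) >= 1.0:
            raise FitError(f"|rho_c| must be < 1, got {self.rho_c}")
        if self.scion.n != self.rootstock.n:
            raise FitError("scion and rootstock grids differ in length")


def sad_matrix(p: SADParams) -> np.ndarray:
    """Dense n x n SAD(1) covariance matrix (det = nu2^n)."""
    n, phi, nu2 = p.n, p.phi, p.nu2
    if phi == 0.0:
        return nu2 * np.eye(n)
    i = np.arange(1, n + 1)
    mn = np.minimum.outer(i, i)
    lag = np.abs(np.subtract.outer(i, i))
    return nu2 * phi**lag * (1.0 - phi ** (2 * mn)) / (1.0 - phi**2)


def sad_whiten(resid: np.ndarray, phi: float) -> np.ndarray:
    """Map residuals to their innovations: eps_i = e_i - phi*e_{i-1}."""
    resid = np.asarray(resid, dtype=float)
    eps = resid.copy()
    eps[..., 1:] -= phi * resid[..., :-1]
    return eps


def sad_loglik(resid: np.ndarray, p: SADParams) -> float:
    """Gaussian log-density of a residual vector under SAD(1).

    Uses the innovation transform (tridiagonal inverse) and the closed-form
    log-determinant n*log(nu2); identical to dense-matrix evaluation.
    """
    resid = np.asarray(resid, dtype=float)
    if resid.shape[-1] != p.n:
        raise FitError(f"residual length {resid.shape[-1]} != grid length {p.n}")
    eps = sad_whiten(resid, p.phi)
    quad = np.sum(eps * eps, axis=-1) / p.nu2
    return -0.5 * (p.n * (_LOG2PI + np.log(p.nu2)) + quad)


def sad_mle(resid: np.ndarray, max_abs_phi: float = 0.99) -> SADParams:
    """Closed-form SAD(1) MLE-style estimates from rows of residuals.

    phi from the lag-1 regression of pooled residuals, nu2 from the mean
    squared innovation.  ``resid`` may be (n,) or (m, n).
    """
    R = np.atleast_2d(np.asarray(resid, dtype=float))
    num = float(np.sum(R[:, 1:] * R[:, :-1]))
    den = float(np.sum(R[:, :-1] ** 2))
    phi = 0.0 if den <= 0.0 else float(np.clip(num / den, -max_abs_phi, max_abs_phi))
    eps = sad_whiten(R, phi)
    nu2 = float(np.mean(eps * eps))
    return SADParams(phi, max(nu2, 1e-12), R.shape[1])


def block_cov(b: BlockCov) -> np.ndarray:
    """Assemble the 2n x 2n scion/rootstock covariance; error if not PD."""
    S = sad_matrix(b.scion)
    R = sad_matrix(b.rootstock)
    n = b.scion.n
    cross = np.zeros((n, n))
    np.fill_diagonal(cross, b.rho_c * np.sqrt(np.diag(S) * np.diag(R)))
    full = np.block([[S, cross], [cross.T, R]])
    try:
        np.linalg.cholesky(full)
    except np.linalg.LinAlgError as exc:
        raise NotPositiveDefiniteError(
            f"assembled block covariance is not positive definite "
            f"(rho_c={b.rho_c}); use a smaller |rho_c|"
        ) from exc
    return full


def mvn_loglik(resid: np.ndarray, cov: np.ndarray | None = None,
               chol: np.ndarray | None = None) -> float:
    """Dense multivariate-normal log-density at ``resid`` (mean zero)."""
    from scipy.linalg import solve_triangular

    if chol is None:
        chol = np.linalg.cholesky(cov)
    y = solve_triangular(chol, np.atleast_1d(resid), lower=True)
    n = chol.shape[0]
    logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
    return -0.5 * (n * _LOG2PI + logdet + float(y @ y))
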