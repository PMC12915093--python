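"""Regulator selection by weighted group Lasso.

Integrating each gene's quasi-dynamic ODE turns the system into an additive
regression: observed expression of gene j over the ordered index grid equals
its own (unpenalized) self curve plus one Legendre-basis group per candidate
regulator, evaluated in the regulator's normalized smoothed expression.  A
group Lasso penalty over the regulator groups picks the small set d_j of most
influential regulators; a quadratic-bump weight function that vanishes at the
two boundary samples downweights the ends of the grid.

The solver is block-coordinate proximal descent (majorize-minimize per
group), which is monotone in the objective and keeps groups exactly zero at
and above the critical penalty lambda_max.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from idopnet.errors import FitError
from idopnet.lop import lop_design


@dataclass
class RegressionProblem:
    """One gene's additive-regression problem over the ordered index grid."""

    target: str
    y: np.ndarray                    # response, ordered by index
    grid: np.ndarray                 # ordered index values E_1 <= ... <= E_n
    self_design: np.ndarray          # unpenalized group (own smoothed curve)
    groups: dict[str, np.ndarray]    # regulator id -> n x (r+1) design
    weights: np.ndarray              # Z, zero at both boundary samples

    @property
    def order(self) -> int:
        if self.groups:
            return next(iter(self.groups.values())).shape[1] - 1
        return self.self_design.shape[1] - 2


@dataclass
class SelectionResult:
    """Group-Lasso solution at one penalty value."""

    target: str
    lambda_: float
    self_coef: np.ndarray
    coef: dict[str, np.ndarray]
    weighted_rss: float
    n_samples: int = 0
    criterion: float = np.nan

    @property
    def selected(self) -> list[str]:
        return [g for g, b in self.coef.items() if np.linalg.norm(b) > 1e-10]


def boundary_weight(grid: np.ndarray) -> np.ndarray:
    """Quadratic bump Z_i = (E_i-E_1)(E_n-E_i) / ((E_n-E_1)/2)^2.

    Nonnegative, zero at both boundary samples, maximal (=1) mid-range.
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = grid[0], grid[-1]
    if hi <= lo:
        raise FitError("index grid must span a positive range")
    return (grid - lo) * (hi - grid) / ((hi - lo) / 2.0) ** 2


def _curve_design(curve: np.ndarray, order: int,
                  grid: np.ndarray | None = None) -> np.ndarray | None:
    """Legendre design in a curve's normalized values; integrated along the
    grid when one is given.

    The additive regression is the *integral* of the ODE system, so each
    kernel's regression group is the running integral of its basis functions
    evaluated along the driving curve:
        Xtilde[i, k] = int_{E_1}^{E_i} P_k(t(curve(s))) ds
    (cumulative trapezoid).  Pointwise designs would make the target's own
    group span the identity map of its trajectory and the regression
    self-explaining.
    """
    lo, hi = float(np.min(curve)), float(np.max(curve))
    if hi - lo <= 1e-12 * max(1.0, abs(hi)):
        return None
    X = lop_design(curve, (lo, hi), order)
    if grid is None:
        return X
    h = np.diff(grid)
    Xi = np.zeros_like(X)
    Xi[1:] = np.cumsum(0.5 * h[:, None] * (X[:-1] + X[1:]), axis=0)
    return Xi


def build_problem(
    target: str,
    curves: dict[str, np.ndarray],
    grid: np.ndarray,
    y: np.ndarray | None = None,
    order: int = 4,
) -> RegressionProblem:
    """Assemble the design for gene ``target``.

    ``curves`` maps every module gene to its smoothed trajectory on the
    ordered grid; the response defaults to the target's own (raw or smoothed)
    trajectory.  Constant regulator curves cannot carry a Legendre group and
    are dropped with a warning.
    """
    grid = np.asarray(grid, dtype=float)
    if target not in curves:
        raise FitError(f"target {target!r} missing from curves")
    y = np.asarray(curves[target] if y is None else y, dtype=float)
    own = _curve_design(np.asarray(curves[target], dtype=float), order, grid)
    if own is None:
        raise FitError(f"target curve {target!r} is constant")
    # the self group is the integrated own-kernel family plus the intercept
    # carrying the initial value y(E_1)
    self_design = np.column_stack([np.ones(grid.size), own])
    groups: dict[str, np.ndarray] = {}
    for g, c in curves.items():
        if g == target:
            continue
        X = _curve_design(np.asarray(c, dtype=float), order, grid)
        if X is None:
            warnings.warn(f"degenerate (constant) regulator curve {g!r} dropped")
            continue
        groups[g] = X
    return RegressionProblem(target, y, grid, self_design, groups,
                             boundary_weight(grid))


def _objective(p: RegressionProblem, a: np.ndarray,
               B: dict[str, np.ndarray], lam: float) -> float:
    r = p.y - p.self_design @ a
    for g, b in B.items():
        r = r - p.groups[g] @ b
    return float(r @ (p.weights * r)) + lam * sum(
        float(np.linalg.norm(b)) for b in B.values()
    )


def lambda_max(p: RegressionProblem) -> float:
    """Smallest penalty at which every regulator group is exactly zero."""
    a = _self_ls(p, p.y)
    r0 = p.weights * (p.y - p.self_design @ a)
    return max(2.0 * float(np.linalg.norm(X.T @ r0)) for X in p.groups.values())


def _self_ls(p: RegressionProblem, target_vec: np.ndarray) -> np.ndarray:
    Xw = p.self_design * p.weights[:, None]
    A = Xw.T @ p.self_design
    return np.linalg.lstsq(A, Xw.T @ target_vec, rcond=None)[0]


def _bcd_core(y, w, Xs, As, Xg, lips, r1, lam_seq, max_sweeps):
    """Proximal block-coordinate descent over a decreasing penalty sequence.

    Xg stacks the penalized groups column-wise (n, G*r1); As is the
    precomputed weighted least-squares operator for the unpenalized self
    group.  Warm starts along the path.  Returns (self coefs, group coefs,
    converged flags) per penalty value.
    """
    n = y.shape[0]
    G = Xg.shape[1] // r1
    nlam = lam_seq.shape[0]
    A_out = np.zeros((nlam, Xs.shape[1]))
    B_out = np.zeros((nlam, G * r1))
    conv = np.zeros(nlam, dtype=np.bool_)
    beta = np.zeros(G * r1)
    fit_pen = np.zeros(n)
    for li in range(nlam):
        lam = lam_seq[li]
        prev_obj = np.inf
        for sweep in range(max_sweeps):
            a = As @ (y - fit_pen)
            fit_self = Xs @ a
            moved = 0.0
            for g in range(G):
                sl = slice(g * r1, (g + 1) * r1)
                resid = y - fit_self - fit_pen
                grad = Xg[:, sl].T @ (w * resid)
                z = beta[sl] + 2.0 * grad / lips[g]
                nz = np.sqrt(np.sum(z * z))
                thr = lam / lips[g]
                if nz <= thr:
                    new = np.zeros(r1)
                else:
                    new = (1.0 - thr / nz) * z
                delta = new - beta[sl]
                md = np.max(np.abs(delta))
                if md > 0.0:
                    fit_pen = fit_pen + Xg[:, sl] @ delta
                    beta[sl] = new
                    if md > moved:
                        moved = md
            resid = y - fit_self - fit_pen
            pen = 0.0
            for g in range(G):
                sl = slice(g * r1, (g + 1) * r1)
                pen += np.sqrt(np.sum(beta[sl] ** 2))
            obj = np.sum(w * resid * resid) + lam * pen
            if prev_obj - obj < 1e-9 * (1.0 + np.abs(obj)):
                conv[li] = True
                break
            prev_obj = obj
        A_out[li] = As @ (y - fit_pen)
        B_out[li] = beta
    return A_out, B_out, conv


try:  # pragma: no cover
    import numba as _numba

    _bcd_core = _numba.njit(cache=True)(_bcd_core)
except ImportError:  # pragma: no cover
    pass


def group_lasso_path(
    p: RegressionProblem,
    lambdas: np.ndarray | None = None,
    n_lambda: int = 50,
    lambda_min_ratio: float = 1e-3,
    max_sweeps: int = 1000,
) -> list[SelectionResult]:
    """Solve the penalized weighted least-squares problem along a path.

    Default path: ``n_lambda`` log-spaced values from lambda_max down to
    ``lambda_min_ratio * lambda_max``.  The self group is never penalized.
    """
    if not p.groups:
        raise FitError("no candidate regulator groups")
    lmax = lambda_max(p)
    if lambdas is None:
        lambdas = np.geomspace(lmax, lambda_min_ratio * lmax, n_lambda)
    lambdas = np.asarray(lambdas, dtype=float)
    if np.any(lambdas < 0) or np.any(np.diff(lambdas) > 0):
        raise FitError("lambdas must be nonnegative and decreasing")

    names = list(p.groups)
    W = p.weights
    r1 = p.groups[names[0]].shape[1]       # columns per penalized group
    Xg = np.concatenate([p.groups[g] for g in names], axis=1)
    # majorization constants: 2 * lambda_max(X_g' W X_g)
    lips = np.array([
        2.0 * float(np.linalg.eigvalsh(
            p.groups[g].T @ (W[:, None] * p.groups[g])).max())
        for g in names
    ])
    Xsw = p.self_design * W[:, None]
    As = np.linalg.pinv(Xsw.T @ p.self_design) @ Xsw.T
    A_out, B_out, conv = _bcd_core(
        p.y.astype(float), W.astype(float), p.self_design, As, Xg, lips,
        r1, lambdas, max_sweeps,
    )
    results = []
    for li, lam in enumerate(lambdas):
        if lam == 0.0:
            # unpenalized: the exact weighted least-squares solution
            X = np.hstack([p.self_design, Xg])
            sw = np.sqrt(W)
            beta = np.linalg.lstsq(sw[:, None] * X, sw * p.y, rcond=None)[0]
            A_out[li] = beta[: p.self_design.shape[1]]
            B_out[li] = beta[p.self_design.shape[1]:]
            conv[li] = True
        if not conv[li]:
            warnings.warn(f"group Lasso did not converge at lambda={lam:g}")
        coef = {g: B_out[li, i * r1:(i + 1) * r1].copy()
                for i, g in enumerate(names)}
        resid = p.y - p.self_design @ A_out[li] - Xg @ B_out[li]
        results.append(
            SelectionResult(
                p.target, float(lam), A_out[li].copy(), coef,
                float(resid @ (W * resid)),
                n_samples=p.y.size,
            )
        )
    return results


def sweep_objectives(p: RegressionProblem, lam: float,
                     n_sweeps: int = 50) -> list[float]:
    """Objective value after each block-coordinate sweep at one penalty.

    Introspection helper (pure Python mirror of the solver's updates); the
    proximal majorize-minimize steps make the sequence nonincreasing.
    """
    names = list(p.groups)
    W = p.weights
    designs = [p.groups[g] for g in names]
    lips = [2.0 * float(np.linalg.eigvalsh(X.T @ (W[:, None] * X)).max())
            for X in designs]
    B = [np.zeros(X.shape[1]) for X in designs]
    out = []
    for _ in range(n_sweeps):
        partial = p.y - sum(X @ b for X, b in zip(designs, B))
        a = _self_ls(p, partial)
        fit = p.self_design @ a + (p.y - partial)
        for gi, X in enumerate(designs):
            grad_at = (X * W[:, None]).T @ (p.y - fit)
            z = B[gi] + 2.0 * grad_at / lips[gi]
            nz = np.linalg.norm(z)
            thr = lam / lips[gi]
            new = np.zeros_like(z) if nz <= thr else (1.0 - thr / nz) * z
            fit = fit + X @ (new - B[gi])
            B[gi] = new
        out.append(_objective(p, a, dict(zip(names, B)), lam))
    return out


def choose_lambda(
    path: list[SelectionResult],
    criterion: str = "extendedBIC",
    gamma: float = 0.5,
    n_candidates: int | None = None,
) -> SelectionResult:
    """Pick the path entry minimizing BIC or the extended BIC.

    BIC = n log(weighted RSS / n) + df log n with df counting all active
    coefficients (self block plus each selected group).  The extended BIC
    adds 2 gamma log C(n_candidates, k) for k selected groups.  Ties go to
    the sparser model.
    """
    if not path:
        raise FitError("empty path")
    if criterion not in ("BIC", "extendedBIC"):
        raise FitError(f"unknown criterion {criterion!r}")
    if n_candidates is None:
        n_candidates = len(path[0].coef)
    group_size = (len(next(iter(path[0].coef.values())))
                  if path[0].coef else path[0].self_coef.size)
    best: SelectionResult | None = None
    best_key: tuple[float, int, float] | None = None
    for res in path:
        n = res.n_samples
        k = len(res.selected)
        df = k * group_size + res.self_coef.size
        if df >= n - 1:
            # (near-)saturated fits leave no residual degrees of freedom;
            # their log-RSS term is meaningless and would always win
            res.criterion = np.inf
            continue
        rss = max(res.weighted_rss, 1e-300)
        score = n * np.log(rss / n) + df * np.log(n)
        if criterion == "extendedBIC":
            score += 2.0 * gamma * (
                gammaln(n_candidates + 1)
                - gammaln(k + 1)
                - gammaln(n_candidates - k + 1)
            )
        res.criterion = float(score)
        key = (round(float(score), 10), k, -res.lambda_)
        if best_key is None or key < best_key:
            best, best_key = res, key
    if best is None:
        # every entry saturated: fall back to the sparsest (largest penalty)
        return path[0]
    return best
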