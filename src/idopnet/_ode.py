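"""Fixed-grid fourth-order Runge-Kutta cores for the quasi-dynamic ODEs.

The independent kernel of a gene is a polynomial in its own normalized state;
dependent drives are either precomputed functions of the index (regulators
frozen at their smoothed trajectories, the conditional-fitting case) or
polynomials in the co-integrated counterpart state (the coupled crosstalk
case).  Component integrals (independent vs dependent) are accumulated with
the same RK4 stage weights as the state itself, so

    y(E_k) = y(E_1) + indep_cum[k] + dep_cum[k]

holds to machine precision at every knot.

Kernels arrive as monomial coefficients (ascending powers) in the normalized
variable t = 2 (y - lo) / (hi - lo) - 1, clamped to [-1, 1]; the clamp is what
keeps integration defined when the state drifts outside the fitted domain.

All cores are jitted with numba when it is importable; pure-Python versions
are kept as the reference implementation and fallback.
"""

from __future__ import annotations

import numpy as np


def _poly_eval(c, t):
    """Horner evaluation of ascending-power coefficients at scalar t."""
    acc = 0.0
    for i in range(len(c) - 1, -1, -1):
        acc = acc * t + c[i]
    return acc


def _norm_clamp(y, lo, hi):
    t = 2.0 * (y - lo) / (hi - lo) - 1.0
    if t < -1.0:
        return -1.0
    if t > 1.0:
        return 1.0
    return t


def _rk4_conditional(poly_self, lo, hi, y0, grid, dep_knot, dep_mid):
    """Single-state RK4 with an index-dependent (frozen-regulator) drive.

    dep_knot[k] is the total dependent drive at grid[k]; dep_mid[k] the drive
    at the midpoint of interval k.  Returns (trajectory, indep_cum, dep_cum).
    """
    n = grid.shape[0]
    traj = np.empty(n)
    indep = np.zeros(n)
    dep = np.zeros(n)
    y = y0
    traj[0] = y
    for k in range(n - 1):
        h = grid[k + 1] - grid[k]
        d0 = dep_knot[k]
        dm = dep_mid[k]
        d1 = dep_knot[k + 1]
        f1 = _poly_eval(poly_self, _norm_clamp(y, lo, hi))
        k1 = f1 + d0
        f2 = _poly_eval(poly_self, _norm_clamp(y + 0.5 * h * k1, lo, hi))
        k2 = f2 + dm
        f3 = _poly_eval(poly_self, _norm_clamp(y + 0.5 * h * k2, lo, hi))
        k3 = f3 + dm
        f4 = _poly_eval(poly_self, _norm_clamp(y + h * k3, lo, hi))
        k4 = f4 + d1
        y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        indep[k + 1] = indep[k] + (h / 6.0) * (f1 + 2.0 * f2 + 2.0 * f3 + f4)
        dep[k + 1] = dep[k] + (h / 6.0) * (d0 + 4.0 * dm + d1)
        traj[k + 1] = y
    return traj, indep, dep


def _rk4_coupled(poly1, lo1, hi1, poly2, lo2, hi2,
                 poly12, poly21, y10, y20, grid):
    """Two-state coupled RK4 over the niche index.

    State 1 is the rootstock, state 2 the scion.  Cross kernels are
    polynomials in the *other* state's normalized value:
        dy1/dN = f1(y1) + f12(y2),  dy2/dN = f2(y2) + f21(y1).
    Returns (traj1, traj2, indep1, dep1, indep2, dep2).
    """
    n = grid.shape[0]
    traj1 = np.empty(n)
    traj2 = np.empty(n)
    ind1 = np.zeros(n)
    dep1 = np.zeros(n)
    ind2 = np.zeros(n)
    dep2 = np.zeros(n)
    y1 = y10
    y2 = y20
    traj1[0] = y1
    traj2[0] = y2
    for k in range(n - 1):
        h = grid[k + 1] - grid[k]
        a1 = 0.0
        b1 = 0.0
        a2 = 0.0
        b2 = 0.0
        u1 = y1
        u2 = y2
        s1i = 0.0
        s1d = 0.0
        s2i = 0.0
        s2d = 0.0
        for stage in range(4):
            fi1 = _poly_eval(poly1, _norm_clamp(u1, lo1, hi1))
            fd1 = _poly_eval(poly12, _norm_clamp(u2, lo2, hi2))
            fi2 = _poly_eval(poly2, _norm_clamp(u2, lo2, hi2))
            fd2 = _poly_eval(poly21, _norm_clamp(u1, lo1, hi1))
            w = 2.0 if stage == 1 or stage == 2 else 1.0
            s1i += w * fi1
            s1d += w * fd1
            s2i += w * fi2
            s2d += w * fd2
            g1 = fi1 + fd1
            g2 = fi2 + fd2
            if stage == 0:
                a1, a2 = g1, g2
                u1 = y1 + 0.5 * h * g1
                u2 = y2 + 0.5 * h * g2
            elif stage == 1:
                u1 = y1 + 0.5 * h * g1
                u2 = y2 + 0.5 * h * g2
            elif stage == 2:
                u1 = y1 + h * g1
                u2 = y2 + h * g2
        y1 = y1 + (h / 6.0) * (s1i + s1d)
        y2 = y2 + (h / 6.0) * (s2i + s2d)
        ind1[k + 1] = ind1[k] + (h / 6.0) * s1i
        dep1[k + 1] = dep1[k] + (h / 6.0) * s1d
        ind2[k + 1] = ind2[k] + (h / 6.0) * s2i
        dep2[k + 1] = dep2[k] + (h / 6.0) * s2d
        traj1[k + 1] = y1
        traj2[k + 1] = y2
    return traj1, traj2, ind1, dep1, ind2, dep2


def _rk4_system(polys, los, his, edge_src, edge_dst, edge_poly,
                y0, grid):
    """m-state joint RK4: dy_j/dE = f_j(y_j) + sum_{j' -> j} f_{j<-j'}(y_{j'}).

    ``polys`` is (m, p) monomial coefficients for the independent kernels,
    ``edge_poly`` (n_edges, p) for the edge kernels in the source's value.
    Returns (trajectories (n, m), indep_cum (n, m), dep_cum (n, m)).
    """
    n = grid.shape[0]
    m = y0.shape[0]
    ne = edge_src.shape[0]
    traj = np.empty((n, m))
    indc = np.zeros((n, m))
    depc = np.zeros((n, m))
    y = y0.copy()
    traj[0] = y
    fi = np.empty(m)
    fd = np.empty(m)
    si = np.zeros(m)
    sd = np.zeros(m)
    u = np.empty(m)
    for k in range(n - 1):
        h = grid[k + 1] - grid[k]
        for j in range(m):
            si[j] = 0.0
            sd[j] = 0.0
            u[j] = y[j]
        g = np.zeros(m)
        for stage in range(4):
            for j in range(m):
                fi[j] = _poly_eval(polys[j], _norm_clamp(u[j], los[j], his[j]))
                fd[j] = 0.0
            for e in range(ne):
                s = edge_src[e]
                fd[edge_dst[e]] += _poly_eval(
                    edge_poly[e], _norm_clamp(u[s], los[s], his[s])
                )
            w = 2.0 if stage == 1 or stage == 2 else 1.0
            for j in range(m):
                si[j] += w * fi[j]
                sd[j] += w * fd[j]
                g[j] = fi[j] + fd[j]
            if stage == 0 or stage == 1:
                for j in range(m):
                    u[j] = y[j] + 0.5 * h * g[j]
            elif stage == 2:
                for j in range(m):
                    u[j] = y[j] + h * g[j]
        for j in range(m):
            y[j] = y[j] + (h / 6.0) * (si[j] + sd[j])
            indc[k + 1, j] = indc[k, j] + (h / 6.0) * si[j]
            depc[k + 1, j] = depc[k, j] + (h / 6.0) * sd[j]
            traj[k + 1, j] = y[j]
    return traj, indc, depc


rk4_conditional = _rk4_conditional
rk4_coupled = _rk4_coupled
rk4_system = _rk4_system

try:  # pragma: no cover - exercised implicitly wherever numba is present
    import numba

    _poly_eval = numba.njit(cache=True)(_poly_eval)
    _norm_clamp = numba.njit(cache=True)(_norm_clamp)
    rk4_conditional = numba.njit(cache=True)(_rk4_conditional)
    rk4_coupled = numba.njit(cache=True)(_rk4_coupled)
    rk4_system = numba.njit(cache=True)(_rk4_system)
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False
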