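"""Sparse quasi-dynamic ODE network fitting, testing, and graph analysis.

Each gene's trajectory over the ordered index grid is decomposed into an
independent component (a Legendre kernel in the gene's own normalized state)
and dependent components (Legendre kernels in each selected regulator's
normalized smoothed expression):

    dy_j/dE = f_j(y_j) + sum_{j' in d_j} f_{j<-j'}( yhat_{j'}(E) )

Fitting is gene-by-gene conditional maximum likelihood: regulator inputs are
frozen at their power-smoothed trajectories, so the dependent drive is a
known function of E and only a single state is integrated (fixed-grid RK4).
Residuals follow SAD(1) with the innovation variance and antedependence
coefficient profiled out in closed form; the kernel coefficients are
optimized by Nelder-Mead.  Interactions are tested by a permutation
likelihood ratio: regulator trajectories are reshuffled across samples and
the model refit, the observed LR being compared with the permutation
distribution's upper quantile.

The fitted independent components become network nodes and the dependent
components signed, weighted, directed edges; graph statistics, eigenvector
centrality hubness, and six-degree information-flow path tracing operate on
the assembled graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from numpy.polynomial import legendre as L
from scipy.optimize import minimize

from idopnet._ode import rk4_conditional, rk4_system
from idopnet.allometry import fit_power, predict_power
from idopnet.errors import FitError
from idopnet.io_indices import IndexSeries
from idopnet.lop import LOPCurve, fit_lop
from idopnet.sad import SADParams, sad_loglik, sad_mle
from idopnet.selection import SelectionResult

_BIG = 1e12


# ---------------------------------------------------------------------------
# containers


@dataclass
class GeneNode:
    gene: str
    kernel: LOPCurve                 # independent kernel over own normalized state
    independent_trajectory: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.independent_trajectory)):
            raise FitError(f"non-finite independent trajectory for {self.gene}")


@dataclass
class GeneEdge:
    source: str
    target: str
    kernel: LOPCurve                 # dependent kernel over source's normalized state
    dependent_trajectory: np.ndarray
    weight: float                    # mean dependent-component derivative, signed
    lr: float = np.nan
    threshold: float = np.nan
    significant: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.weight):
            raise FitError(f"non-finite weight on {self.source}->{self.target}")

    @property
    def sign(self) -> str:
        return "promote" if self.weight >= 0 else "inhibit"


@dataclass
class GeneFit:
    """Everything needed to evaluate / refit one gene's conditional model."""

    gene: str
    knots: np.ndarray                # unique ascending index values
    sample_map: np.ndarray           # sample position -> knot position
    y_obs: np.ndarray                # observed values, ordered by index
    y0: float
    domain: tuple[float, float]      # own smoothed-state domain
    parents: list[str]
    parent_designs: dict[str, np.ndarray]   # knot-level Legendre designs
    parent_values: dict[str, np.ndarray]    # smoothed parent values at knots
    parent_domains: dict[str, tuple[float, float]]
    order: int
    theta_self: np.ndarray = field(default_factory=lambda: np.zeros(0))
    theta_dep: dict[str, np.ndarray] = field(default_factory=dict)
    theta_self_null: np.ndarray = field(default_factory=lambda: np.zeros(0))
    loglik_full: float = -np.inf
    loglik_null: float = -np.inf
    sad: SADParams | None = None
    trajectory: np.ndarray | None = None      # fitted, at sample positions
    indep_cum: np.ndarray | None = None
    dep_cum: np.ndarray | None = None
    converged: bool = True


@dataclass
class GeneNetwork:
    nodes: list[GeneNode]
    edges: list[GeneEdge]
    layer: str = "gene"
    context: tuple[str, str] | None = None
    grid: np.ndarray | None = None
    fits: dict[str, GeneFit] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        names = {n.gene for n in self.nodes}
        for e in self.edges:
            if e.source not in names or e.target not in names:
                raise FitError(f"edge {e.source}->{e.target} endpoint missing")
            if e.source == e.target:
                raise FitError(f"self-edge on {e.source}")

    def edge(self, source: str, target: str) -> GeneEdge:
        for e in self.edges:
            if e.source == source and e.target == target:
                return e
        raise KeyError(f"{source}->{target}")

    def to_graph(self, significant_only: bool = False) -> nx.DiGraph:
        G = nx.DiGraph()
        for node in self.nodes:
            G.add_node(node.gene)
        for e in self.edges:
            if significant_only and not e.significant:
                continue
            G.add_edge(e.source, e.target, weight=e.weight, sign=e.sign,
                       lr=e.lr, significant=e.significant)
        return G


# ---------------------------------------------------------------------------
# joint ODE integration (simulation / forward runs)


def _leg_to_poly(coeffs: np.ndarray, width: int) -> np.ndarray:
    p = L.leg2poly(coeffs)
    out = np.zeros(width)
    out[: p.size] = p
    return out


def integrate_system(
    node_kernels: Mapping[str, LOPCurve],
    edge_kernels: Mapping[tuple[str, str], LOPCurve],
    y0: Mapping[str, float],
    grid,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """RK4 solution of the joint sparse qdMODE system on a strictly
    increasing grid.

    Returns (trajectories, independent_cum, dependent_cum, gene_order), each
    array (n_grid, m).  Component integrals use the same RK4 stage weights as
    the state, so y(E_k) = y(E_1) + indep[k] + dep[k] exactly.
    """
    grid = np.asarray(
        grid.sorted_values if isinstance(grid, IndexSeries) else grid, float
    )
    if np.any(np.diff(grid) <= 0):
        raise FitError("grid must be strictly increasing (collapse ties first)")
    genes = list(node_kernels)
    gi = {g: j for j, g in enumerate(genes)}
    width = max(
        [c.coeffs.size for c in node_kernels.values()]
        + [c.coeffs.size for c in edge_kernels.values()]
    )
    polys = np.stack([_leg_to_poly(node_kernels[g].coeffs, width) for g in genes])
    los = np.array([node_kernels[g].domain[0] for g in genes])
    his = np.array([node_kernels[g].domain[1] for g in genes])
    if edge_kernels:
        src = np.array([gi[s] for (s, _t) in edge_kernels], dtype=np.int64)
        dst = np.array([gi[t] for (_s, t) in edge_kernels], dtype=np.int64)
        epoly = np.stack([_leg_to_poly(c.coeffs, width)
                          for c in edge_kernels.values()])
    else:
        src = np.zeros(0, dtype=np.int64)
        dst = np.zeros(0, dtype=np.int64)
        epoly = np.zeros((0, width))
    y0v = np.array([float(y0[g]) for g in genes])
    traj, ind, dep = rk4_system(polys, los, his, src, dst, epoly, y0v, grid)
    if not np.all(np.isfinite(traj)):
        raise FitError("non-finite state during system integration")
    return traj, ind, dep, genes


# ---------------------------------------------------------------------------
# conditional gene fitting


def _collapse_ties(E_sorted: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    knots, inverse = np.unique(E_sorted, return_inverse=True)
    return knots, inverse


def smooth_trajectories(Y_ordered: np.ndarray, E_sorted: np.ndarray,
                        method: str = "lop", order: int = 4) -> np.ndarray:
    """Smooth each row's trajectory over the ordered index.

    ``method='lop'`` (default) fits a Legendre series in the index, which
    preserves non-monotone trajectory shapes - the feature that makes
    regulators statistically distinguishable from a gene's own smooth trend.
    ``method='power'`` uses the power equation instead; its curves are
    always monotone in the index, which collapses all candidate regressors
    onto near-identical smooth shapes.
    """
    out = np.empty_like(Y_ordered, dtype=float)
    knots = np.unique(E_sorted)
    r = min(order, knots.size - 1)
    for j in range(Y_ordered.shape[0]):
        try:
            if method == "power":
                fit = fit_power(Y_ordered[j], E_sorted)
                out[j] = predict_power(fit, E_sorted)
            else:
                curve = fit_lop(E_sorted, Y_ordered[j], r)
                out[j] = curve(E_sorted)
        except FitError:
            out[j] = np.full(E_sorted.size, max(Y_ordered[j].mean(), 1e-12))
    return out


def _objective(params: np.ndarray, fit: GeneFit) -> float:
    r1 = fit.order + 1
    theta_self = params[:r1]
    dep_knot = np.zeros(fit.knots.size)
    for i, p in enumerate(fit.parents):
        dep_knot += fit.parent_designs[p] @ params[r1 * (i + 1): r1 * (i + 2)]
    dep_mid = 0.5 * (dep_knot[:-1] + dep_knot[1:])
    poly = _leg_to_poly(theta_self, r1)
    traj, _ind, _dep = rk4_conditional(
        poly, fit.domain[0], fit.domain[1], fit.y0, fit.knots, dep_knot, dep_mid
    )
    if not np.all(np.isfinite(traj)) or np.max(np.abs(traj)) > 1e8:
        return _BIG
    resid = fit.y_obs - traj[fit.sample_map]
    sad = sad_mle(resid)
    return -float(sad_loglik(resid, sad))


def _run_nm(fun, x0, maxfev):
    res = minimize(fun, x0, method="Nelder-Mead",
                   options={"maxfev": maxfev, "xatol": 1e-6, "fatol": 1e-9,
                            "adaptive": x0.size > 8})
    f0 = fun(x0)
    if res.fun <= f0:
        return res.x, float(res.fun), bool(res.success)
    return x0, float(f0), False


def _init_kernel_from_curve(values: np.ndarray, deriv: np.ndarray,
                            order: int) -> np.ndarray:
    """Legendre coefficients of a derivative curve against a state variable."""
    lo, hi = float(values.min()), float(values.max())
    if hi - lo <= 1e-12:
        return np.zeros(order + 1)
    try:
        return fit_lop(values, deriv, order, domain=(lo, hi)).coeffs
    except FitError:
        c = np.zeros(order + 1)
        c[0] = float(np.mean(deriv))
        return c


def _fit_gene(fit: GeneFit, maxfev: int, init_dep: dict[str, np.ndarray]) -> None:
    """Null fit (independent only) then full fit; enforces LR >= 0 nesting."""
    r1 = fit.order + 1
    # independent-kernel initializer: finite-difference slope of the data
    knot_y = np.array([fit.y_obs[fit.sample_map == k].mean()
                       for k in range(fit.knots.size)])
    slope = np.gradient(knot_y, fit.knots)
    x0 = _init_kernel_from_curve(
        np.clip(knot_y, fit.domain[0], fit.domain[1]), slope, fit.order
    )

    def null_obj(p):
        return _objective(np.concatenate([p, np.zeros(r1 * len(fit.parents))]),
                          fit) if fit.parents else _objective(p, fit)

    theta_null, nll_null, _ = _run_nm(null_obj, x0, maxfev)
    fit.theta_self_null = theta_null
    fit.loglik_null = -nll_null

    if not fit.parents:
        fit.theta_self = theta_null
        fit.theta_dep = {}
        fit.loglik_full = fit.loglik_null
        fit.converged = True
    else:
        starts = []
        full0 = np.concatenate(
            [theta_null] + [init_dep.get(p, np.zeros(r1)) for p in fit.parents]
        )
        starts.append(full0)
        starts.append(np.concatenate([theta_null, np.zeros(r1 * len(fit.parents))]))
        best_x, best_f, ok = None, np.inf, False
        for s in starts:
            x, f, conv = _run_nm(lambda p: _objective(p, fit), s, maxfev)
            if f < best_f:
                best_x, best_f, ok = x, f, conv
        fit.converged = ok
        if best_f > nll_null:          # nesting guard: null embeds in full
            best_x = np.concatenate(
                [theta_null, np.zeros(r1 * len(fit.parents))]
            )
            best_f = nll_null
        fit.theta_self = best_x[:r1]
        fit.theta_dep = {
            p: best_x[r1 * (i + 1): r1 * (i + 2)]
            for i, p in enumerate(fit.parents)
        }
        fit.loglik_full = -best_f

    # final decomposition at the optimum
    dep_knot = np.zeros(fit.knots.size)
    for p in fit.parents:
        dep_knot += fit.parent_designs[p] @ fit.theta_dep.get(
            p, np.zeros(r1)
        )
    dep_mid = 0.5 * (dep_knot[:-1] + dep_knot[1:])
    traj, ind, dep = rk4_conditional(
        _leg_to_poly(fit.theta_self, r1), fit.domain[0], fit.domain[1],
        fit.y0, fit.knots, dep_knot, dep_mid,
    )
    fit.trajectory = traj[fit.sample_map]
    fit.indep_cum = ind[fit.sample_map]
    fit.dep_cum = dep[fit.sample_map]
    resid = fit.y_obs - fit.trajectory
    fit.sad = sad_mle(resid)


def _normalize_selection(selection, gene_ids) -> dict[str, list[str]]:
    if isinstance(selection, Mapping):
        out = {}
        for g, v in selection.items():
            out[g] = list(v.selected) if isinstance(v, SelectionResult) else list(v)
        missing = [g for g in gene_ids if g not in out]
        if missing:
            raise FitError(f"selection missing genes: {missing[:5]}")
        return out
    out = {}
    for res in selection:
        out[res.target] = list(res.selected)
    missing = [g for g in gene_ids if g not in out]
    if missing:
        raise FitError(f"selection missing genes: {missing[:5]}")
    return out


def fit_network(
    Y: np.ndarray,
    gene_ids: Sequence[str],
    E: IndexSeries,
    selection,
    order: int = 4,
    seed: int = 0,
    maxfev: int = 2000,
    layer: str = "gene",
    context: tuple[str, str] | None = None,
) -> GeneNetwork:
    """Fit the sparse qdMODE system for a module of genes.

    Y is the raw (m, n) matrix in original sample order, E the index series
    driving the quasi-dynamic axis, and ``selection`` the per-gene regulator
    sets (gene id -> regulator ids, or a list of SelectionResult).

    The per-gene decomposition satisfies the conservation identity
    y(E_1) + indep + dep = fitted trajectory at every grid point.
    """
    Y = np.asarray(Y, dtype=float)
    gene_ids = list(gene_ids)
    parents_of = _normalize_selection(selection, gene_ids)
    if isinstance(selection, Mapping):
        sel_objs = {g: v for g, v in selection.items()
                    if isinstance(v, SelectionResult)}
    else:
        sel_objs = {r.target: r for r in selection}
    pos = {g: j for j, g in enumerate(gene_ids)}
    order_idx = E.order
    E_sorted = E.values[order_idx]
    Yo = Y[:, order_idx]
    knots, sample_map = _collapse_ties(E_sorted)
    if knots.size < 2:
        raise FitError("need at least 2 distinct index values")
    smooth = smooth_trajectories(Yo, E_sorted)
    smooth_knots = np.stack(
        [np.array([smooth[j, sample_map == k].mean() for k in range(knots.size)])
         for j in range(len(gene_ids))]
    )

    nodes, edges, fits = [], [], {}
    for g in gene_ids:
        j = pos[g]
        parents = [p for p in parents_of[g] if p != g]
        own = smooth_knots[j]
        lo, hi = float(own.min()), float(own.max())
        if hi - lo <= 1e-9 * max(1.0, abs(hi)):
            lo, hi = lo - 0.5, hi + 0.5
        designs, values, domains, init_dep = {}, {}, {}, {}
        for p in parents:
            pv = smooth_knots[pos[p]]
            plo, phi_ = float(pv.min()), float(pv.max())
            if phi_ - plo <= 1e-12:
                continue
            t = np.clip(2.0 * (pv - plo) / (phi_ - plo) - 1.0, -1.0, 1.0)
            designs[p] = L.legvander(t, order)
            values[p] = pv
            domains[p] = (plo, phi_)
            # warm start from the group-Lasso coefficients when available:
            # the selected group models the integral g(E); its finite
            # difference against the parent state initializes the kernel
            sel = sel_objs.get(g)
            if sel is not None and p in sel.coef and sel.coef[p].size == order + 1:
                pv_s = smooth[pos[p]]
                ts = np.clip(2.0 * (pv_s - plo) / (phi_ - plo) - 1.0, -1.0, 1.0)
                g_curve = L.legvander(ts, order) @ sel.coef[p]
                f_vals = np.gradient(g_curve, E_sorted + np.arange(E_sorted.size) * 1e-12)
                init_dep[p] = _init_kernel_from_curve(
                    np.clip(pv_s, plo, phi_), f_vals, order
                )
        parents = [p for p in parents if p in designs]
        gf = GeneFit(
            gene=g, knots=knots, sample_map=sample_map, y_obs=Yo[j],
            y0=float(Yo[j, sample_map == 0].mean()), domain=(lo, hi),
            parents=parents, parent_designs=designs, parent_values=values,
            parent_domains=domains, order=order,
        )
        _fit_gene(gf, maxfev, init_dep)
        fits[g] = gf
        nodes.append(GeneNode(
            gene=g,
            kernel=LOPCurve(gf.theta_self, gf.domain, extrapolate="clamp"),
            independent_trajectory=gf.indep_cum,
        ))
    for g in gene_ids:
        gf = fits[g]
        for p in gf.parents:
            theta = gf.theta_dep[p]
            drive = gf.parent_designs[p] @ theta
            cum = np.concatenate(
                [[0.0], np.cumsum(0.5 * np.diff(knots) * (drive[:-1] + drive[1:]))]
            )
            edges.append(GeneEdge(
                source=p, target=g,
                kernel=LOPCurve(theta, gf.parent_domains[p], extrapolate="clamp"),
                dependent_trajectory=cum[sample_map],
                weight=float(np.mean(drive)),
            ))
    return GeneNetwork(nodes=nodes, edges=edges, layer=layer, context=context,
                       grid=knots, fits=fits, seed=seed)


# ---------------------------------------------------------------------------
# permutation likelihood-ratio test


@dataclass
class LRTestResult:
    gene: str
    lr: float
    threshold: float
    significant: bool
    perm_lrs: np.ndarray


def _cyclic_perms(k: int, rng: np.random.Generator,
                  n_max: int) -> list[np.ndarray]:
    """Rotation/reflection reorderings of k grid positions.

    Unlike full reshuffling, rotations preserve the smoothness of the
    regulator curves, so the null distribution is comparable to the observed
    statistic; full permutations make every null design rough and are badly
    anticonservative whenever the independent-only fit leaves smooth misfit.
    """
    base = np.arange(k)
    perms = [np.roll(base, s) for s in range(1, k)]
    perms += [np.roll(base[::-1], s) for s in range(k)]
    if len(perms) > n_max:
        idx = rng.choice(len(perms), size=n_max, replace=False)
        perms = [perms[i] for i in idx]
    return perms


def lr_test(
    net: GeneNetwork,
    gene: str,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    perm_maxfev: int = 300,
) -> LRTestResult:
    """Permutation LR test of whether a gene interacts with its regulators.

    H0: dy/dE = f(y) (independent only); H1 adds the selected regulators.
    The statistic is a conditional LR computed by one fixed protocol: the
    dependent kernels are seeded in closed form by regressing the null
    residual on the running integral of the regulator designs, then the
    full model is polished by a short Nelder-Mead from the null solution.
    The null distribution applies the identical protocol to rotated
    (cyclically shifted, optionally reflected) regulator trajectories -
    identical treatment is what makes the comparison exchangeable, and
    rotations keep the null designs as smooth as the observed one.
    ``n_perm`` caps how many of the 2(k-1)+1 distinct rotations are used.
    """
    if n_perm < 50:
        raise FitError("need at least 50 permutations")
    gf = net.fits[gene]
    if not gf.parents:
        return LRTestResult(gene, 0.0, np.inf, False, np.zeros(0))
    r1 = gf.order + 1
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF,
                                                        abs(hash(gene)) % 2**31]))
    k = gf.knots.size
    h = np.diff(gf.knots)

    # null residual under the independent-only solution
    zero = np.zeros(k)
    traj0, _i, _d = rk4_conditional(
        _leg_to_poly(gf.theta_self_null, r1), gf.domain[0], gf.domain[1],
        gf.y0, gf.knots, zero, zero[:-1],
    )
    null_resid = gf.y_obs - traj0[gf.sample_map]

    saved = {p: gf.parent_designs[p] for p in gf.parents}

    def cond_lr(perm: np.ndarray | None) -> float:
        designs = (saved if perm is None
                   else {p: saved[p][perm] for p in gf.parents})
        Dk = np.concatenate([designs[p] for p in gf.parents], axis=1)
        Dint = np.zeros_like(Dk)
        Dint[1:] = np.cumsum(0.5 * h[:, None] * (Dk[:-1] + Dk[1:]), axis=0)
        theta_seed = np.linalg.lstsq(Dint[gf.sample_map], null_resid,
                                     rcond=None)[0]
        gf.parent_designs = designs
        try:
            x0 = np.concatenate([gf.theta_self_null, theta_seed])
            _x, f, _ = _run_nm(lambda q: _objective(q, gf), x0, perm_maxfev)
        finally:
            gf.parent_designs = saved
        return max(0.0, 2.0 * (-f - gf.loglik_null))

    lr = cond_lr(None)
    perms = _cyclic_perms(k, rng, n_perm)
    perm_lrs = np.array([cond_lr(p) for p in perms])
    threshold = float(np.quantile(perm_lrs, 1.0 - alpha))
    return LRTestResult(gene, float(lr), threshold, bool(lr > threshold),
                        perm_lrs)


def apply_significance(net: GeneNetwork, n_perm: int = 200, seed: int = 0,
                       alpha: float = 0.05) -> dict[str, LRTestResult]:
    """Run the gene-level LR test for every gene and flag its incoming edges."""
    results = {}
    for node in net.nodes:
        g = node.gene
        if not net.fits[g].parents:
            continue
        res = lr_test(net, g, n_perm=n_perm, seed=seed, alpha=alpha)
        results[g] = res
        for e in net.edges:
            if e.target == g:
                e.lr = res.lr
                e.threshold = res.threshold
                e.significant = res.significant
    return results


# ---------------------------------------------------------------------------
# graph analytics


def network_metrics(G: GeneNetwork | nx.Graph) -> dict[str, float]:
    """Mean distance, clustering coefficient, vertex connectivity, diameter.

    Computed on the undirected unweighted skeleton: mean distance averages
    shortest-path lengths over connected pairs; vertex connectivity and
    diameter refer to the largest connected component.
    """
    U = (G.to_graph() if isinstance(G, GeneNetwork) else G).to_undirected()
    U = nx.Graph(U)
    U.remove_edges_from(nx.selfloop_edges(U))
    if U.number_of_nodes() == 0:
        raise FitError("empty graph")
    if U.number_of_nodes() == 1:
        warnings.warn("single-node graph: metrics defined as 0")
        return {"mean_distance": 0.0, "clustering_coefficient": 0.0,
                "vertex_connectivity": 0.0, "diameter": 0.0}
    total, pairs = 0.0, 0
    for comp in nx.connected_components(U):
        sub = U.subgraph(comp)
        k = sub.number_of_nodes()
        if k < 2:
            continue
        for _s, lengths in nx.all_pairs_shortest_path_length(sub):
            total += sum(lengths.values())
        pairs += k * (k - 1)
    mean_distance = total / pairs if pairs else 0.0
    giant = U.subgraph(max(nx.connected_components(U), key=len))
    return {
        "mean_distance": float(mean_distance),
        "clustering_coefficient": float(nx.average_clustering(U)),
        "vertex_connectivity": float(
            nx.node_connectivity(giant) if giant.number_of_nodes() > 1 else 0.0
        ),
        "diameter": float(nx.diameter(giant) if giant.number_of_nodes() > 1 else 0.0),
    }


def hubness(G: GeneNetwork | nx.Graph, tol: float = 1e-10,
            max_iter: int = 100_000) -> dict[str, float]:
    """Eigenvector-centrality hubness on the |weight| undirected adjacency.

    Power iteration per connected component; each component's principal
    eigenvector is normalized to max 1.  Isolated nodes get 0.
    """
    H = G.to_graph() if isinstance(G, GeneNetwork) else G
    U = nx.Graph()
    U.add_nodes_from(H.nodes)
    for u, v, d in H.edges(data=True):
        if u == v:
            continue
        w = abs(float(d.get("weight", 1.0)))
        U.add_edge(u, v, weight=max(w, U.get_edge_data(u, v, {"weight": 0.0})["weight"]))
    out: dict[str, float] = {}
    for comp in nx.connected_components(U):
        comp = sorted(comp)
        if len(comp) == 1:
            out[comp[0]] = 0.0
            continue
        A = nx.to_numpy_array(U, nodelist=comp, weight="weight")
        # positive shift keeps the Perron vector but breaks the +/- lambda
        # tie of bipartite components, where unshifted iteration oscillates
        A = A + (1.0 + A.sum(axis=1).max()) * np.eye(len(comp))
        x = np.full(len(comp), 1.0 / np.sqrt(len(comp)))
        for _ in range(max_iter):
            y = A @ x
            ny = np.linalg.norm(y)
            if ny == 0.0:
                break
            y /= ny
            if np.max(np.abs(y - x)) < tol:
                x = y
                break
            x = y
        x = np.abs(x)
        x /= x.max()
        out.update({g: float(v) for g, v in zip(comp, x)})
    return out


def trace_flow(
    G: GeneNetwork | nx.DiGraph,
    sources: Sequence[str],
    max_hops: int = 6,
    significant_only: bool = True,
) -> list[dict]:
    """Enumerate simple directed paths of length <= max_hops from each source.

    Path sign is the product of edge signs (promote/inhibit algebra); output
    is ordered by descending path weight (product of |edge weights|).
    """
    H = (G.to_graph(significant_only=significant_only)
         if isinstance(G, GeneNetwork) else G)
    unknown = [s for s in sources if s not in H]
    if unknown:
        raise FitError(f"unknown source nodes: {unknown}")
    paths: list[dict] = []

    def dfs(path: list[str], weight: float, sign: int) -> None:
        if len(path) > 1:
            paths.append({
                "path": list(path),
                "sign": "promote" if sign > 0 else "inhibit",
                "weight": weight,
            })
        if len(path) - 1 >= max_hops:
            return
        for _u, v, d in H.out_edges(path[-1], data=True):
            if v in path:
                continue
            w = float(d.get("weight", 1.0))
            path.append(v)
            dfs(path, weight * abs(w), sign * (1 if w >= 0 else -1))
            path.pop()

    for s in sources:
        dfs([s], 1.0, 1)
    paths.sort(key=lambda p: (-p["weight"], p["path"]))
    return paths
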