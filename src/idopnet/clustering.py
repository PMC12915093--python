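"""Functional clustering of genes into modules by mixture-model EM.

Genes are clustered on the similarity of their index-varying expression
trajectories.  Each module's mean curve per variate is a power equation
alpha_k * E^beta_k; residuals follow SAD(1) along each grid, with the scion
and rootstock variates of the same grafting combination coupled through a
cross-correlation of their SAD innovations, and different combinations
independent.  The octa-variate version joins all four combinations x two
segments; the one-variate version covers a single grid.

The innovation-correlated block form keeps the residual covariance in closed
form (bidiagonal whitening, per-position 2x2 blocks), so both the E-step
density and the covariance M-step are exact and fast.  Module means are
refreshed by a profiled power-law search; every M-step block update is
accepted only when it does not lower the expected complete-data objective
(generalized EM), which keeps the observed log-likelihood monotone.
Recursive subdivision re-runs the clustering inside every oversized module
(Dunbar-scale leaf sizes) to build the multilayer module tree
(M36 -> SM36_16 -> ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from idopnet.errors import FitError
from idopnet.io_indices import IndexSeries
from idopnet.sad import SADParams

_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# fast profiled power-law least squares (internal work-horse)


def _fast_power_ls(y: np.ndarray, E: np.ndarray,
                   lo: float = -1.5, hi: float = 3.5) -> tuple[float, float]:
    """(alpha, beta) minimizing ||y - alpha E^beta||^2 by grid-refined search."""
    logE = np.log(E)
    center, width = 0.5 * (lo + hi), 0.5 * (hi - lo)
    best_b, best_a = 0.0, max(float(np.mean(y)), 1e-12)
    for _ in range(4):
        betas = np.linspace(center - width, center + width, 33)
        P = np.exp(np.outer(betas, logE))          # (33, n)
        num = P @ y
        den = np.einsum("ij,ij->i", P, P)
        alphas = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
        rss = np.sum(y * y) - alphas * num         # ||y||^2 - a * (P y)
        i = int(np.argmin(rss))
        best_b, best_a = float(betas[i]), float(alphas[i])
        center, width = best_b, width / 8.0
    return max(best_a, 1e-12), best_b


# ---------------------------------------------------------------------------
# residual covariance: SAD(1) per variate, innovation-correlated pairs


@dataclass
class InnovCov:
    """Scion/rootstock SAD(1) blocks with innovation cross-correlation rho."""

    scion: SADParams
    rootstock: SADParams
    rho: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.rho) >= 1.0:
            raise FitError(f"|rho| must be < 1, got {self.rho}")


def _whiten_rows(R: np.ndarray, phi: float) -> np.ndarray:
    eps = R.copy()
    eps[:, 1:] -= phi * R[:, :-1]
    return eps


def _sad_logpdf_rows(R: np.ndarray, p: SADParams) -> np.ndarray:
    eps = _whiten_rows(R, p.phi)
    return -0.5 * (R.shape[1] * (_LOG2PI + np.log(p.nu2))
                   + np.sum(eps * eps, axis=1) / p.nu2)


def _bivar_logpdf_rows(Rs: np.ndarray, Rr: np.ndarray, c: InnovCov) -> np.ndarray:
    n = Rs.shape[1]
    es = _whiten_rows(Rs, c.scion.phi)
    er = _whiten_rows(Rr, c.rootstock.phi)
    v_s, v_r, rho = c.scion.nu2, c.rootstock.nu2, c.rho
    om = 1.0 - rho * rho
    quad = (np.sum(es * es, axis=1) / v_s
            - 2.0 * rho * np.sum(es * er, axis=1) / np.sqrt(v_s * v_r)
            + np.sum(er * er, axis=1) / v_r) / om
    logdet = n * (np.log(v_s) + np.log(v_r) + np.log(om))
    return -0.5 * (2 * n * _LOG2PI + logdet + quad)


def _group_logpdf(Y, mu, cov, cols) -> np.ndarray:
    """log N(y_j | mu, Sigma) for every gene j (block-diagonal groups)."""
    out = np.zeros(Y.shape[0])
    for c, idx in zip(cov, cols):
        if isinstance(c, SADParams):
            out += _sad_logpdf_rows(Y[:, idx] - mu[idx], c)
        else:
            half = idx.size // 2
            out += _bivar_logpdf_rows(
                Y[:, idx[:half]] - mu[idx[:half]],
                Y[:, idx[half:]] - mu[idx[half:]], c,
            )
    return out


def _weighted_phi(R: np.ndarray, w: np.ndarray) -> float:
    num = float(np.sum(w[:, None] * R[:, 1:] * R[:, :-1]))
    den = float(np.sum(w[:, None] * R[:, :-1] ** 2))
    return float(np.clip(num / den, -0.99, 0.99)) if den > 0 else 0.0


def _update_group_cov(c, Rs_list, Rr_list, w_list):
    """Closed-form covariance refresh from posterior-weighted residuals.

    phi by weighted lag-one regression, then (nu2s, nu2r, rho) by the exact
    bivariate-normal MLE of the innovations.  Caller Q-checks acceptance.
    """
    Rs = np.vstack(Rs_list)
    w = np.concatenate(w_list)
    W = float(np.sum(w))
    n = Rs.shape[1]
    if Rr_list is None:
        phi = _weighted_phi(Rs, w)
        eps = _whiten_rows(Rs, phi)
        nu2 = float(np.sum(w[:, None] * eps * eps) / (W * n))
        return SADParams(phi, max(nu2, 1e-12), n)
    Rr = np.vstack(Rr_list)
    phis = _weighted_phi(Rs, w)
    phir = _weighted_phi(Rr, w)
    es = _whiten_rows(Rs, phis)
    er = _whiten_rows(Rr, phir)
    v_s = float(np.sum(w[:, None] * es * es) / (W * n))
    v_r = float(np.sum(w[:, None] * er * er) / (W * n))
    v_s, v_r = max(v_s, 1e-12), max(v_r, 1e-12)
    rho = float(np.sum(w[:, None] * es * er) / (W * n * np.sqrt(v_s * v_r)))
    rho = float(np.clip(rho, -0.99, 0.99))
    return InnovCov(SADParams(phis, v_s, n), SADParams(phir, v_r, n), rho)


def _n_cov_params(cov) -> int:
    return sum(2 if isinstance(c, SADParams) else 5 for c in cov)


# ---------------------------------------------------------------------------
# model containers


@dataclass
class ClusterModel:
    """Fitted mixture: K modules over V variates."""

    K: int
    pi: np.ndarray                      # (K,)
    means: list[list[tuple[float, float]]]   # [k][v] -> (alpha, beta)
    cov: list[SADParams | InnovCov]     # one per variate group
    loglik: float
    bic: float
    posteriors: np.ndarray              # (m, K), rows sum to 1
    labels: np.ndarray                  # argmax assignment, ties -> lower index
    loglik_trace: list[float] = field(default_factory=list)
    n_params: int = 0
    n_iter: int = 0
    converged: bool = True

    def mean_curve(self, k: int, v: int, E: np.ndarray) -> np.ndarray:
        a, b = self.means[k][v]
        return a * np.asarray(E, dtype=float) ** b


@dataclass
class ModuleNode:
    label: str
    gene_indices: np.ndarray
    model: ClusterModel | None = None
    children: list["ModuleNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __len__(self) -> int:
        return self.gene_indices.size


@dataclass
class ModuleTree:
    """Recursive clustering result; every gene sits in exactly one leaf."""

    root: ModuleNode
    Y: np.ndarray
    E_grids: list[np.ndarray]

    def leaves(self) -> list[ModuleNode]:
        out: list[ModuleNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf and node is not self.root:
                out.append(node)
            stack.extend(reversed(node.children))
        if not out:
            out = [self.root]
        return out

    def leaf_labels(self) -> np.ndarray:
        labels = np.empty(self.Y.shape[0], dtype=object)
        for leaf in self.leaves():
            labels[leaf.gene_indices] = leaf.label
        return labels


# ---------------------------------------------------------------------------
# helpers


def _as_grids(E_grids) -> list[np.ndarray]:
    if isinstance(E_grids, IndexSeries):
        E_grids = [E_grids]
    if isinstance(E_grids, np.ndarray) and E_grids.ndim == 1:
        E_grids = [E_grids]
    out = []
    for g in E_grids:
        v = g.sorted_values if isinstance(g, IndexSeries) else np.asarray(g, float)
        if np.any(v <= 0):
            raise FitError("index grids must be strictly positive")
        out.append(v)
    return out


def _variate_groups(V: int) -> list[tuple[int, ...]]:
    """Scion/rootstock pairs per combination when V is even, else singletons."""
    if V == 1:
        return [(0,)]
    if V % 2 == 0:
        return [(2 * c, 2 * c + 1) for c in range(V // 2)]
    return [(v,) for v in range(V)]


def _group_cols(groups, n) -> list[np.ndarray]:
    return [np.concatenate([np.arange(v * n, (v + 1) * n) for v in gr])
            for gr in groups]


class _EmptyCluster(Exception):
    pass


def _mean_matrix(means_k, grids) -> np.ndarray:
    return np.concatenate([a * g**b for (a, b), g in zip(means_k, grids)])


def _init_params(Y, grids, K, seed, groups, cols):
    from sklearn.cluster import KMeans

    m = Y.shape[0]
    n = grids[0].size
    if K == 1:
        labels = np.zeros(m, dtype=int)
    else:
        km = KMeans(n_clusters=K, n_init=1, random_state=int(seed) % (2**31))
        labels = km.fit_predict(np.log1p(np.maximum(Y, 0.0)))
    pi = np.maximum(np.bincount(labels, minlength=K) / m, 1.0 / (2 * m))
    pi = pi / pi.sum()
    means = []
    for k in range(K):
        rows = Y[labels == k] if np.any(labels == k) else Y
        ybar = rows.mean(axis=0)
        means.append([
            _fast_power_ls(ybar[v * n:(v + 1) * n], grids[v])
            for v in range(len(grids))
        ])
    mu = np.stack([_mean_matrix(means[k], grids) for k in range(K)])
    resid = Y - mu[labels]
    w = [np.ones(m)]
    cov = []
    for gr, idx in zip(groups, cols):
        if len(gr) == 1:
            cov.append(_update_group_cov(None, [resid[:, idx]], None, w))
        else:
            half = idx.size // 2
            cov.append(_update_group_cov(
                None, [resid[:, idx[:half]]], [resid[:, idx[half:]]], w,
            ))
    return pi, means, cov


def em_fit(
    Y: np.ndarray,
    E_grids,
    K: int,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
    rel_tol: float = 1e-8,
    max_restarts: int = 5,
) -> ClusterModel:
    """Fit the K-module mixture by (generalized) EM.

    Y is (m, V*n): each variate's block is ordered by its own grid.  The
    observed log-likelihood is nondecreasing across iterations; an empty
    cluster (posterior mass < 1e-8) triggers a re-seeded restart.
    """
    Y = np.asarray(Y, dtype=float)
    grids = _as_grids(E_grids)
    n = grids[0].size
    V = len(grids)
    if Y.shape[1] != V * n:
        raise FitError(f"Y has {Y.shape[1]} columns, expected {V}*{n}")
    m = Y.shape[0]
    if K < 1 or m <= K:
        raise FitError("need K >= 1 and more genes than modules")

    last_err: Exception | None = None
    for attempt in range(max_restarts):
        try:
            return _em_once(Y, grids, K, seed + 1013 * attempt, max_iter,
                            tol, rel_tol)
        except _EmptyCluster as err:
            last_err = err
    raise FitError(f"EM failed after {max_restarts} restarts: {last_err}")


def _em_once(Y, grids, K, seed, max_iter, tol, rel_tol=1e-8) -> ClusterModel:
    m = Y.shape[0]
    n = grids[0].size
    V = len(grids)
    groups = _variate_groups(V)
    cols = _group_cols(groups, n)
    pi, means, cov = _init_params(Y, grids, K, seed, groups, cols)
    mu = np.stack([_mean_matrix(means[k], grids) for k in range(K)])

    loglik = -np.inf
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logpdf = np.stack(
            [_group_logpdf(Y, mu[k], cov, cols) for k in range(K)], axis=1
        )
        logw = np.log(pi)[None, :] + logpdf
        norm = logsumexp(logw, axis=1)
        new_loglik = float(norm.sum())
        post = np.exp(logw - norm[:, None])
        trace.append(new_loglik)
        mass = post.sum(axis=0)
        if np.any(mass < 1e-8):
            raise _EmptyCluster(f"empty cluster at iteration {it}")
        if new_loglik < loglik - 1e-9 * max(1.0, abs(loglik)):
            raise FitError("EM log-likelihood decreased (internal error)")
        stop_gain = max(tol, rel_tol * abs(new_loglik))
        if np.isfinite(loglik) and new_loglik - loglik < stop_gain:
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik

        # --- M-step (generalized: each block update accepted only if it
        # does not lower the expected complete-data objective) ---
        pi = mass / m
        for k in range(K):
            ybar = (post[:, k] @ Y) / mass[k]
            cand = [
                _fast_power_ls(ybar[v * n:(v + 1) * n], grids[v])
                for v in range(V)
            ]
            mu_new = _mean_matrix(cand, grids)
            q_old = float(post[:, k] @ _group_logpdf(Y, mu[k], cov, cols))
            q_new = float(post[:, k] @ _group_logpdf(Y, mu_new, cov, cols))
            if q_new >= q_old:
                means[k] = cand
                mu[k] = mu_new
        for gi, (gr, idx) in enumerate(zip(groups, cols)):
            half = idx.size // 2
            Rs_list, Rr_list, w_list = [], [], []
            for k in range(K):
                R = Y[:, idx] - mu[k][idx]
                if len(gr) == 1:
                    Rs_list.append(R)
                else:
                    Rs_list.append(R[:, :half])
                    Rr_list.append(R[:, half:])
                w_list.append(post[:, k])
            cand = _update_group_cov(
                cov[gi], Rs_list, Rr_list if len(gr) > 1 else None, w_list,
            )
            old_q = new_q = 0.0
            for k in range(K):
                old_q += float(post[:, k] @ _group_logpdf(
                    Y[:, idx], mu[k][idx], [cov[gi]], [np.arange(idx.size)]))
                new_q += float(post[:, k] @ _group_logpdf(
                    Y[:, idx], mu[k][idx], [cand], [np.arange(idx.size)]))
            if new_q >= old_q:
                cov[gi] = cand

    labels = np.argmax(post, axis=1)  # argmax -> ties to lower module index
    p = (K - 1) + 2 * V * K + _n_cov_params(cov)
    bic = -2.0 * loglik + p * np.log(m)
    return ClusterModel(
        K=K, pi=pi, means=means, cov=cov, loglik=loglik, bic=float(bic),
        posteriors=post, labels=labels, loglik_trace=trace,
        n_params=p, n_iter=it, converged=converged,
    )


def select_K(
    Y: np.ndarray,
    E_grids,
    K_range,
    seed: int = 0,
    n_restarts: int = 3,
    max_iter: int = 200,
) -> ClusterModel:
    """BIC model selection over a range of module counts.

    Each K is fit with ``n_restarts`` seeded restarts keeping the best
    log-likelihood; the model minimizing BIC is returned (ties: smaller K).
    """
    K_range = list(K_range)
    if not K_range:
        raise FitError("empty K range")
    best: ClusterModel | None = None
    for K in K_range:
        best_k: ClusterModel | None = None
        for r in range(n_restarts):
            try:
                fit = em_fit(Y, E_grids, K, seed=seed + 7919 * r,
                             max_iter=max_iter)
            except FitError:
                continue
            if best_k is None or fit.loglik > best_k.loglik:
                best_k = fit
        if best_k is None:
            continue
        if best is None or best_k.bic < best.bic - 1e-9:
            best = best_k
    if best is None:
        raise FitError("no K in range could be fit")
    return best


def cluster_tree(
    Y: np.ndarray,
    E_grids,
    K_range,
    max_leaf: int = 100,
    seed: int = 0,
    max_depth: int = 4,
) -> ModuleTree:
    """Top-level clustering followed by recursive subdivision."""
    Y = np.asarray(Y, dtype=float)
    grids = _as_grids(E_grids)
    root = ModuleNode("root", np.arange(Y.shape[0]))
    model = select_K(Y, grids, K_range, seed=seed)
    root.model = model
    for k in range(model.K):
        idx = np.flatnonzero(model.labels == k)
        root.children.append(ModuleNode(f"M{k + 1}", idx))
    tree = ModuleTree(root, Y, grids)
    return subdivide(tree, max_leaf=max_leaf, K_range=K_range, seed=seed,
                     max_depth=max_depth)


def subdivide(
    tree: ModuleTree,
    max_leaf: int = 100,
    K_range=range(1, 9),
    seed: int = 0,
    max_depth: int = 4,
) -> ModuleTree:
    """Re-cluster every oversized leaf until all leaves hold <= max_leaf genes.

    Labels follow the M# -> SM#_# convention (deeper levels append _#).  A
    leaf whose best model is K=1 cannot split and is kept oversize with a
    warning.
    """
    import warnings

    if max_leaf < 2:
        raise FitError("max_leaf must be >= 2")

    def child_label(parent: ModuleNode, k: int) -> str:
        if parent.label.startswith("SM"):
            return f"{parent.label}_{k + 1}"
        return f"SM{parent.label.lstrip('M')}_{k + 1}"

    def recurse(node: ModuleNode, depth: int) -> None:
        for child in node.children:
            recurse(child, depth + 1)
        if node.children or node is tree.root:
            return
        if len(node) <= max_leaf or depth >= max_depth:
            if len(node) > max_leaf:
                warnings.warn(
                    f"module {node.label} kept oversize at depth limit"
                )
            return
        ks = [k for k in K_range if k < len(node)]
        if not ks:
            return
        try:
            model = select_K(tree.Y[node.gene_indices], tree.E_grids, ks,
                             seed=seed + 31 * depth)
        except FitError:
            warnings.warn(f"module {node.label} could not be refit; kept")
            return
        if model.K == 1:
            warnings.warn(f"module {node.label} does not split; kept oversize")
            return
        node.model = model
        for k in range(model.K):
            idx = node.gene_indices[model.labels == k]
            if idx.size == 0:
                continue
            node.children.append(ModuleNode(child_label(node, k), idx))
        for child in node.children:
            recurse(child, depth + 1)

    recurse(tree.root, 0)
    return tree
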