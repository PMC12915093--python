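import itertools

import networkx as nx
import numpy as np
import pytest

from idopnet.errors import FitError
from idopnet.io_indices import IndexKind, IndexSeries
from idopnet.lop import LOPCurve
from idopnet.network import (
    GeneEdge,
    GeneNetwork,
    GeneNode,
    apply_significance,
    fit_network,
    hubness,
    integrate_system,
    lr_test,
    network_metrics,
    trace_flow,
)
from idopnet.simulate import SimConfig, sim_network


def leg_const(c, domain=(0.0, 10.0)):
    return LOPCurve(np.array([c]), domain, extrapolate="clamp")


class TestIntegrateSystem:
    def test_zero_kernel_constant_trajectory(self):
        traj, ind, dep, genes = integrate_system(
            {"a": leg_const(0.0)}, {}, {"a": 5.0}, np.linspace(0, 1, 11)
        )
        np.testing.assert_allclose(traj[:, 0], 5.0)
        np.testing.assert_allclose(ind[:, 0], 0.0)

    def test_constant_kernel_linear_trajectory(self):
        grid = np.linspace(2.0, 6.0, 9)
        traj, ind, dep, _ = integrate_system(
            {"a": leg_const(1.5)}, {}, {"a": 1.0}, grid
        )
        np.testing.assert_allclose(traj[:, 0], 1.0 + 1.5 * (grid - 2.0),
                                   atol=1e-12)

    def test_rk4_exponential_and_order(self):
        # dy/dE = y on [0,1]: f(y) = y as a Legendre series over y-domain
        # [0, 3]: y = 1.5(t+1) -> coeffs [1.5, 1.5]
        kernel = LOPCurve(np.array([1.5, 1.5]), (0.0, 3.0),
                          extrapolate="clamp")
        errs = {}
        for steps in (100, 200):
            grid = np.linspace(0.0, 1.0, steps + 1)
            traj, *_ = integrate_system({"a": kernel}, {}, {"a": 1.0}, grid)
            errs[steps] = abs(traj[-1, 0] - np.e)
        assert errs[100] < 1e-6
        ratio = errs[100] / errs[200]
        assert 10.0 < ratio < 26.0   # ~16x for a 4th-order scheme

    def test_conservation_identity(self):
        ds, truth, grid = sim_network(SimConfig(seed=7, network_m=6))
        kernels = {n.gene: n.kernel for n in truth.nodes}
        edges = {(e.source, e.target): e.kernel for e in truth.edges}
        y0 = {g: float(ds.values[j, 0]) for j, g in enumerate(ds.gene_ids)}
        traj, ind, dep, genes = integrate_system(
            kernels, edges, {g: truth.fits[g].y0 if truth.fits else y0[g]
                             for g in kernels}, grid)
        recon = traj[0][None, :] + ind + dep
        np.testing.assert_allclose(recon, traj, atol=1e-9)

    def test_requires_strictly_increasing_grid(self):
        with pytest.raises(FitError, match="increasing"):
            integrate_system({"a": leg_const(1.0)}, {}, {"a": 1.0},
                             np.array([0.0, 1.0, 1.0, 2.0]))


@pytest.fixture(scope="module")
def fitted_network():
    ds, truth, grid = sim_network(SimConfig(seed=13, network_m=8))
    E = IndexSeries(IndexKind.COMPARTMENT, grid)
    parents = {g: [] for g in ds.gene_ids}
    for e in truth.edges:
        parents[e.target].append(e.source)
    parents["g0"] = []          # keep one gene regulator-free for null cases
    net = fit_network(ds.values, ds.gene_ids, E, parents, seed=13,
                      maxfev=800)
    return ds, truth, net


class TestFitNetwork:
    def test_decomposition_conservation(self, fitted_network):
        _ds, _truth, net = fitted_network
        for gf in net.fits.values():
            recon = gf.y0 + gf.indep_cum + gf.dep_cum
            np.testing.assert_allclose(recon, gf.trajectory, atol=1e-6)

    def test_empty_parent_set_means_zero_dependent(self, fitted_network):
        _ds, truth, net = fitted_network
        lonely = [g for g in net.fits if not net.fits[g].parents]
        assert lonely, "fixture should include an independent gene"
        for g in lonely:
            np.testing.assert_allclose(net.fits[g].dep_cum, 0.0)
            assert net.fits[g].loglik_full == net.fits[g].loglik_null

    def test_edge_signs_follow_weights(self, fitted_network):
        _ds, _truth, net = fitted_network
        for e in net.edges:
            assert e.sign == ("promote" if e.weight >= 0 else "inhibit")

    def test_no_self_edges(self, fitted_network):
        _ds, _truth, net = fitted_network
        assert all(e.source != e.target for e in net.edges)


class TestLrTest:
    def test_lr_zero_without_regulators(self, fitted_network):
        _ds, _truth, net = fitted_network
        lonely = next(g for g in net.fits if not net.fits[g].parents)
        res = lr_test(net, lonely, n_perm=50, seed=0)
        assert res.lr == 0.0 and not res.significant

    def test_lr_nonnegative_everywhere(self, fitted_network):
        _ds, _truth, net = fitted_network
        for g, gf in net.fits.items():
            assert 2.0 * (gf.loglik_full - gf.loglik_null) >= -1e-9

    def test_requires_minimum_permutations(self, fitted_network):
        _ds, _truth, net = fitted_network
        g = next(iter(net.fits))
        with pytest.raises(FitError, match="50"):
            lr_test(net, g, n_perm=10)


def brute_force_metrics(U: nx.Graph):
    """BFS/min-cut oracle for the four graph statistics."""
    total, pairs = 0.0, 0
    for comp in nx.connected_components(U):
        sub = U.subgraph(comp)
        nodes = list(sub)
        for s in nodes:
            lengths = nx.single_source_shortest_path_length(sub, s)
            for t in nodes:
                if t != s:
                    total += lengths[t]
                    pairs += 1
    giant = U.subgraph(max(nx.connected_components(U), key=len))
    conn = (min(
        len(nx.minimum_node_cut(giant, s, t))
        for s, t in itertools.combinations(giant, 2)
        if not giant.has_edge(s, t)
    ) if any(not giant.has_edge(s, t)
             for s, t in itertools.combinations(giant, 2))
        else giant.number_of_nodes() - 1) if giant.number_of_nodes() > 1 else 0
    diam = (max(
        max(nx.single_source_shortest_path_length(giant, s).values())
        for s in giant
    ) if giant.number_of_nodes() > 1 else 0)
    return {
        "mean_distance": total / pairs if pairs else 0.0,
        "clustering_coefficient": nx.average_clustering(U),
        "vertex_connectivity": float(conn),
        "diameter": float(diam),
    }


class TestNetworkMetrics:
    def test_ten_cycle(self):
        m = network_metrics(nx.cycle_graph(10))
        assert m["diameter"] == 5.0
        assert m["clustering_coefficient"] == 0.0

    def test_complete_graph_k4(self):
        m = network_metrics(nx.complete_graph(4))
        assert m["clustering_coefficient"] == 1.0
        assert m["diameter"] == 1.0
        assert m["vertex_connectivity"] == 3.0

    @pytest.mark.parametrize("n_nodes", range(3, 13))
    def test_matches_brute_force_oracle(self, n_nodes):
        rng = np.random.default_rng(n_nodes)
        G = nx.gnp_random_graph(n_nodes, 0.4, seed=int(rng.integers(2**31)))
        if G.number_of_edges() == 0:
            G.add_edge(0, 1)
        got = network_metrics(G)
        want = brute_force_metrics(G)
        for k in want:
            assert got[k] == pytest.approx(want[k], abs=1e-9), k

    def test_single_node_graph_warns_zeros(self):
        G = nx.Graph()
        G.add_node("a")
        with pytest.warns(UserWarning, match="single-node"):
            m = network_metrics(G)
        assert all(v == 0.0 for v in m.values())


class TestHubness:
    def test_star_center_is_hub(self):
        G = nx.star_graph(5)
        h = hubness(G)
        assert h[0] == pytest.approx(1.0)
        leaf_values = [h[i] for i in range(1, 6)]
        assert max(leaf_values) < 1.0
        assert np.ptp(leaf_values) < 1e-9

    def test_ring_all_equal(self):
        h = hubness(nx.cycle_graph(6))
        assert np.ptp(list(h.values())) < 1e-9

    def test_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(3)
        G = nx.gnp_random_graph(9, 0.5, seed=7)
        for u, v in G.edges:
            G.edges[u, v]["weight"] = float(rng.uniform(-2, 2))
        h = hubness(G)
        comp = max(nx.connected_components(G), key=len)
        nodes = sorted(comp)
        A = np.abs(nx.to_numpy_array(G, nodelist=nodes, weight="weight"))
        w, v = np.linalg.eigh(A)
        lead = np.abs(v[:, np.argmax(w)])
        lead = lead / lead.max()
        for i, nnode in enumerate(nodes):
            assert h[nnode] == pytest.approx(lead[i], abs=1e-8)


class TestTraceFlow:
    @staticmethod
    def chain_network():
        nodes = [GeneNode(g, leg_const(0.0), np.zeros(3))
                 for g in "abc"]
        edges = [
            GeneEdge("a", "b", leg_const(1.0), np.zeros(3), weight=2.0),
            GeneEdge("b", "c", leg_const(-1.0), np.zeros(3), weight=-0.5),
        ]
        return GeneNetwork(nodes=nodes, edges=edges)

    def test_chain_paths(self):
        net = self.chain_network()
        paths = trace_flow(net, ["a"], max_hops=2)
        assert [p["path"] for p in paths] == [["a", "b"], ["a", "b", "c"]]

    def test_sign_algebra_promote_then_inhibit(self):
        net = self.chain_network()
        paths = trace_flow(net, ["a"], max_hops=2)
        two_hop = next(p for p in paths if len(p["path"]) == 3)
        assert two_hop["sign"] == "inhibit"
        assert two_hop["weight"] == pytest.approx(1.0)

    def test_max_hops_limits_depth(self):
        net = self.chain_network()
        paths = trace_flow(net, ["a"], max_hops=1)
        assert [p["path"] for p in paths] == [["a", "b"]]

    def test_path_count_matches_exhaustive_dfs(self):
        rng = np.random.default_rng(17)
        G = nx.gnp_random_graph(7, 0.35, directed=True, seed=11)
        for u, v in G.edges:
            G.edges[u, v]["weight"] = float(rng.uniform(0.1, 2.0))
        got = trace_flow(G, list(G.nodes), max_hops=6)
        want = sum(
            1
            for s in G.nodes
            for t in G.nodes
            if s != t
            for p in nx.all_simple_paths(G, s, t, cutoff=6)
        )
        assert len(got) == want
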