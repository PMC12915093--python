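import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from idopnet.clustering import (
    ClusterModel,
    em_fit,
    select_K,
    subdivide,
    cluster_tree,
)
from idopnet.errors import FitError
from idopnet.simulate import SimConfig, sim_modules


def two_module_univariate(rng, m=80, n=24, noise=0.02):
    """Two well-separated power-law modules on one grid."""
    grid = np.sort(rng.uniform(20.0, 200.0, n))
    mid = np.exp(0.5 * (np.log(grid[0]) + np.log(grid[-1])))
    labels = (np.arange(m) % 2)
    Y = np.empty((m, n))
    for j in range(m):
        beta = 0.5 if labels[j] == 0 else 1.5
        curve = 40.0 / mid**beta * grid**beta
        Y[j] = curve + rng.normal(0, noise * 40.0, n)
    return Y, grid, labels


class TestEmFit:
    def test_k1_reduces_to_single_fit(self, rng):
        Y, grid, _ = two_module_univariate(rng, m=30)
        model = em_fit(Y, grid, K=1, seed=0)
        assert model.K == 1
        np.testing.assert_allclose(model.pi, [1.0])
        # the K=1 "mixture" log-likelihood equals the direct single-class
        # Gaussian evaluation with the same parameters
        from idopnet.clustering import _group_logpdf, _group_cols, _variate_groups
        cols = _group_cols(_variate_groups(1), grid.size)
        mu = model.mean_curve(0, 0, np.sort(grid))
        direct = float(np.sum(_group_logpdf(Y, mu, model.cov, cols)))
        assert model.loglik == pytest.approx(direct, abs=1e-6)

    def test_two_separated_modules_ari_one(self, rng):
        Y, grid, labels = two_module_univariate(rng)
        model = em_fit(Y, grid, K=2, seed=0)
        assert adjusted_rand_score(labels, model.labels) == 1.0

    def test_posterior_rows_sum_to_one(self, rng):
        Y, grid, _ = two_module_univariate(rng)
        model = em_fit(Y, grid, K=3, seed=1)
        np.testing.assert_allclose(model.posteriors.sum(axis=1), 1.0,
                                   atol=1e-12)

    def test_loglik_monotone_across_iterations(self, rng):
        ds, grids, _ = sim_modules(SimConfig(seed=5, m=60))
        model = em_fit(ds.values, grids, K=3, seed=2)
        trace = np.asarray(model.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-9 * np.maximum(1.0,
                                                           np.abs(trace[:-1])))

    def test_octa_variate_recovery(self):
        cfg = SimConfig(seed=11, m=90, K=3)
        ds, grids, labels = sim_modules(cfg)
        model = em_fit(ds.values, grids, K=3, seed=3)
        assert adjusted_rand_score(labels, model.labels) >= 0.9
        # per-module beta estimates sit near their generating centers
        truth = np.linspace(cfg.beta_range[0], cfg.beta_range[1], 3)
        est = sorted(np.mean([model.means[k][v][1] for v in range(8)])
                     for k in range(3))
        np.testing.assert_allclose(est, truth, atol=0.1)

    def test_rejects_more_modules_than_genes(self, rng):
        Y, grid, _ = two_module_univariate(rng, m=5)
        with pytest.raises(FitError):
            em_fit(Y, grid, K=5, seed=0)


class TestSelectK:
    def test_single_cluster_data_selects_k1(self, rng):
        grid = np.sort(rng.uniform(20.0, 200.0, 24))
        curve = 2.0 * grid**0.8
        Y = curve + rng.normal(0, 0.02 * curve.mean(), (40, 24))
        model = select_K(Y, grid, range(1, 4), seed=0)
        assert model.K == 1

    def test_bic_prefers_true_k(self):
        ds, grids, labels = sim_modules(SimConfig(seed=21, m=120, K=3))
        model = select_K(ds.values, grids, range(1, 6), seed=21)
        assert model.K == 3
        assert adjusted_rand_score(labels, model.labels) >= 0.9

    def test_label_permutation_leaves_bic_and_ari_unchanged(self, rng):
        Y, grid, labels = two_module_univariate(rng)
        m1 = em_fit(Y, grid, K=2, seed=0)
        # relabeling clusters is just a column permutation of posteriors
        perm = np.array([1, 0])
        relabeled = perm[m1.labels]
        assert adjusted_rand_score(labels, m1.labels) == pytest.approx(
            adjusted_rand_score(labels, relabeled))


class TestSubdivide:
    def test_small_module_is_fixed_point(self, rng):
        Y, grid, _ = two_module_univariate(rng, m=40)
        tree = cluster_tree(Y, grid, range(1, 4), max_leaf=100, seed=0)
        # every leaf is already small; no second level appears
        assert all(leaf.label.startswith("M") and "_" not in leaf.label
                   for leaf in tree.leaves())

    def test_oversize_modules_split_with_label_convention(self):
        # four true modules, but the top level is constrained to two
        # superclusters, so the oversized leaves carry real substructure
        # and a second round of clustering resolves it
        cfg = SimConfig(seed=31, m=120, K=4, beta_range=(0.3, 1.5))
        ds, grids, labels = sim_modules(cfg)
        from idopnet.clustering import ModuleNode, ModuleTree, em_fit
        top = em_fit(ds.values, grids, K=2, seed=31)
        root = ModuleNode("root", np.arange(120))
        for k in range(2):
            idx = np.flatnonzero(top.labels == k)
            root.children.append(ModuleNode(f"M{k + 1}", idx))
        tree = subdivide(ModuleTree(root, ds.values, grids), max_leaf=40,
                         K_range=range(1, 5), seed=31)
        leaves = tree.leaves()
        labels_found = [leaf.label for leaf in leaves]
        assert any(lab.startswith("SM") for lab in labels_found)
        # SM labels carry the parent module number: "SM<parent>_<child>"
        for lab in labels_found:
            if lab.startswith("SM"):
                parent, child = lab[2:].split("_")[:2]
                assert parent.isdigit() and child.isdigit()

    def test_every_gene_in_exactly_one_leaf(self):
        ds, grids, _ = sim_modules(SimConfig(seed=41, m=80, K=2))
        tree = cluster_tree(ds.values, grids, range(1, 4), max_leaf=30,
                            seed=41)
        seen = np.concatenate([leaf.gene_indices for leaf in tree.leaves()])
        assert sorted(seen) == list(range(80))

    def test_max_leaf_validation(self, rng):
        Y, grid, _ = two_module_univariate(rng, m=20)
        tree = cluster_tree(Y, grid, range(1, 3), max_leaf=100, seed=0)
        with pytest.raises(FitError):
            subdivide(tree, max_leaf=1)
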