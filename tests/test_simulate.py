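import numpy as np
import pytest

from idopnet.errors import FitError
from idopnet.simulate import (
    SimConfig,
    sim_crosstalk,
    sim_modules,
    sim_network,
)


class TestSimConfig:
    def test_rejects_bad_proportions(self):
        with pytest.raises(FitError, match="sum to 1"):
            SimConfig(type_proportions=np.ones((3, 3)))

    def test_rejects_negative_noise(self):
        with pytest.raises(FitError):
            SimConfig(noise_add_frac=-0.1)


class TestSimModules:
    def test_same_seed_bit_identical(self):
        a = sim_modules(SimConfig(seed=4, m=30))
        b = sim_modules(SimConfig(seed=4, m=30))
        np.testing.assert_array_equal(a[0].values, b[0].values)
        np.testing.assert_array_equal(a[2], b[2])

    def test_different_seeds_differ(self):
        a = sim_modules(SimConfig(seed=4, m=30))
        b = sim_modules(SimConfig(seed=5, m=30))
        assert not np.array_equal(a[0].values, b[0].values)

    def test_noise_free_genes_sit_on_module_curves(self):
        cfg = SimConfig(seed=2, m=20, noise_add_frac=0.0, gene_jitter=0.0,
                        noise_mult_sigma=0.0)
        ds, grids, labels = sim_modules(cfg)
        # genes sharing a module are identical without any noise source
        for k in range(cfg.K):
            rows = ds.values[labels == k]
            if len(rows) > 1:
                assert float(np.abs(rows - rows[0]).max()) < 1e-9

    def test_dataset_invariants_hold(self):
        ds, grids, labels = sim_modules(SimConfig(seed=9, m=40))
        assert ds.values.min() >= 0
        assert len(set(ds.gene_ids)) == 40
        assert len(ds.sample_meta) == ds.values.shape[1] == 8 * 24
        assert all(np.all(np.diff(g) >= 0) and g.min() > 0 for g in grids)


class TestSimNetwork:
    def test_edge_bookkeeping(self):
        ds, truth, grid = sim_network(SimConfig(seed=6))
        targets = {e.target for e in truth.edges}
        assert all(e.source != e.target for e in truth.edges)
        parent_counts = {}
        for e in truth.edges:
            parent_counts[e.target] = parent_counts.get(e.target, 0) + 1
        assert max(parent_counts.values()) <= 3

    def test_zero_parent_config_gives_independent_genes(self):
        cfg = SimConfig(seed=6, parent_probs=(1.0,))
        ds, truth, grid = sim_network(cfg)
        assert truth.edges == []

    def test_deterministic_under_seed(self):
        a = sim_network(SimConfig(seed=8))
        b = sim_network(SimConfig(seed=8))
        np.testing.assert_array_equal(a[0].values, b[0].values)

    def test_noiseless_data_on_true_trajectories(self):
        from idopnet.network import integrate_system

        cfg = SimConfig(seed=6, network_noise_sigma=0.0)
        ds, truth, grid = sim_network(cfg)
        kernels = {n.gene: n.kernel for n in truth.nodes}
        edges = {(e.source, e.target): e.kernel for e in truth.edges}
        y0 = {g: float(ds.values[j, 0])
              for j, g in enumerate(ds.gene_ids)}
        traj, *_ = integrate_system(kernels, edges, y0, grid)
        np.testing.assert_allclose(ds.values, traj.T, rtol=1e-9)


class TestSimCrosstalk:
    def test_multinomial_counts_returned_exactly(self):
        cfg = SimConfig(seed=3, n=24)
        scion, root, pairs, counts = sim_crosstalk(cfg, n_genes=15)
        assert counts.sum() == 15
        assert scion.shape == root.shape == (15, 24)
        assert len(pairs) == 15

    def test_all_neutral_config_is_uncoupled(self):
        props = np.zeros((3, 3))
        props[1, 1] = 1.0          # the (0, 0) cell
        cfg = SimConfig(seed=3, type_proportions=props)
        _s, _r, pairs, counts = sim_crosstalk(cfg, n_genes=6)
        assert all(p == (0, 0) for p in pairs)
        assert counts[4] == 6

    def test_rows_positive_and_deterministic(self):
        cfg = SimConfig(seed=12)
        a = sim_crosstalk(cfg, n_genes=5)
        b = sim_crosstalk(cfg, n_genes=5)
        np.testing.assert_array_equal(a[0], b[0])
        assert a[0].min() > 0 and a[1].min() > 0
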