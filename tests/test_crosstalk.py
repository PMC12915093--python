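import numpy as np
import pytest

from idopnet.crosstalk import (
    SIGN_TABLE,
    CrosstalkCall,
    DirectionalEffect,
    InteractionType,
    classify_crosstalk,
    fit_crosstalk,
    type_frequencies,
)
from idopnet.errors import FitError
from idopnet.simulate import SimConfig, _gene_rng, crosstalk_pair


def draw_pair(signs, seed=1, noise=0.0, tries=300):
    cfg = SimConfig(seed=seed)
    for att in range(tries):
        try:
            return crosstalk_pair(cfg, signs, _gene_rng(seed, att,
                                                        stream=50),
                                  noise_sigma=noise)
        except FitError:
            continue
    pytest.skip(f"no stable draw for {signs}")


def make_call(gene, s12, s21, combination="AA"):
    eff = lambda s: DirectionalEffect(value=float(s), stat=1.0, threshold=0.0,
                                      significant=s != 0)
    return CrosstalkCall(
        gene=gene, combination=combination,
        effect_on_rootstock=eff(s12), effect_on_scion=eff(s21),
        type=SIGN_TABLE[(s12, s21)],
    )


class TestSignTable:
    def test_total_and_injective_onto_nine_labels(self):
        cells = [(a, b) for a in (1, 0, -1) for b in (1, 0, -1)]
        labels = [SIGN_TABLE[c] for c in cells]
        assert len(labels) == 9
        assert len(set(labels)) == 9
        assert set(labels) == set(InteractionType)

    def test_headline_cells(self):
        assert SIGN_TABLE[(1, 1)] is InteractionType.MUTUALISM
        assert SIGN_TABLE[(-1, -1)] is InteractionType.ANTAGONISM
        assert SIGN_TABLE[(0, 0)] is InteractionType.NEUTRALISM

    def test_dove_hawk_roles(self):
        call = make_call("g", 1, -1)
        assert call.scion_role == "dove"       # promotes the rootstock
        assert call.rootstock_role == "hawk"   # inhibits the scion


class TestFitCrosstalk:
    def test_conservation_per_compartment(self):
        scion, root, _ = draw_pair((1, -1))
        fit = fit_crosstalk("g", scion, root, seed=0)
        for seg in ("rootstock", "scion"):
            traj = fit.traj_root if seg == "rootstock" else fit.traj_scion
            recon = (traj[0]
                     + fit.components[f"independent_{seg}"]
                     + fit.components[f"dependent_{seg}"])
            np.testing.assert_allclose(recon, traj, atol=1e-6)

    def test_uncoupled_pair_has_negligible_dependent_part(self):
        scion, root, _ = draw_pair((0, 0))
        fit = fit_crosstalk("g", scion, root, seed=0)
        for seg in ("rootstock", "scion"):
            dep = fit.components[f"dependent_{seg}"]
            tot = fit.traj_root if seg == "rootstock" else fit.traj_scion
            assert np.mean(np.abs(np.diff(dep))) < 0.05 * np.ptp(tot)

    def test_rejects_non_niche_series(self):
        from idopnet.io_indices import IndexKind, IndexSeries

        with pytest.raises(FitError, match="niche"):
            fit_crosstalk("g", np.ones(8), np.ones(8),
                          N=IndexSeries(IndexKind.COMPARTMENT,
                                        np.arange(1.0, 9.0)))


class TestClassify:
    def test_uncoupled_is_neutral(self):
        scion, root, _ = draw_pair((0, 0))
        fit = fit_crosstalk("g", scion, root, seed=0)
        call = classify_crosstalk(fit, n_perm=100, seed=0)
        assert call.type is InteractionType.NEUTRALISM

    def test_one_way_inhibition_detected(self):
        scion, root, _ = draw_pair((0, -1))
        fit = fit_crosstalk("g", scion, root, seed=0)
        call = classify_crosstalk(fit, n_perm=100, seed=0)
        assert call.effect_on_scion.significant
        assert not call.effect_on_rootstock.significant

    def test_direction_swap_mirrors_the_call(self):
        # feeding (scion, rootstock) swapped must swap the two directions
        scion, root, _ = draw_pair((0, -1))
        fit_fwd = fit_crosstalk("g", scion, root, seed=0)
        fit_rev = fit_crosstalk("g", root, scion, seed=0)
        call_fwd = classify_crosstalk(fit_fwd, n_perm=100, seed=0)
        call_rev = classify_crosstalk(fit_rev, n_perm=100, seed=0)
        assert (call_fwd.effect_on_scion.significant
                == call_rev.effect_on_rootstock.significant)
        assert (call_fwd.effect_on_rootstock.significant
                == call_rev.effect_on_scion.significant)


class TestTypeFrequencies:
    def test_single_type_fills_one_cell(self):
        calls = [make_call(f"g{i}", 1, 1) for i in range(10)]
        tables = type_frequencies(calls)
        assert tables["AA"].loc["+", "+"] == 10
        assert tables["AA"].to_numpy().sum() == 10

    def test_counts_conserve_input_length(self, rng):
        signs = [(int(a), int(b))
                 for a, b in rng.integers(-1, 2, size=(25, 2))]
        calls = [make_call(f"g{i}", a, b, combination="BB")
                 for i, (a, b) in enumerate(signs)]
        tables = type_frequencies(calls)
        assert tables["BB"].to_numpy().sum() == 25

    def test_matches_direct_tally_oracle(self, rng):
        signs = [(int(a), int(b))
                 for a, b in rng.integers(-1, 2, size=(40, 2))]
        calls = [make_call(f"g{i}", a, b) for i, (a, b) in enumerate(signs)]
        tables = type_frequencies(calls)
        pos = {1: 0, 0: 1, -1: 2}
        oracle = np.zeros((3, 3), dtype=int)
        for a, b in signs:
            oracle[pos[a], pos[b]] += 1
        np.testing.assert_array_equal(tables["AA"].to_numpy(), oracle)

    def test_empty_input_rejected(self):
        with pytest.raises(FitError):
            type_frequencies([])
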