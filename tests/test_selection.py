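import numpy as np
import pytest

from idopnet.errors import FitError
from idopnet.lop import lop_design
from idopnet.selection import (
    boundary_weight,
    build_problem,
    choose_lambda,
    group_lasso_path,
    lambda_max,
    sweep_objectives,
)


def make_regression(rng, n=100, n_candidates=29, k_true=2, noise=0.1,
                    order=4):
    """Synthetic additive regression with known support.

    Candidate groups are incoherent (independent Gaussian designs), the
    standard construction for validating a group selector; the unpenalized
    self block and the boundary-vanishing weights mirror the production
    problem layout.
    """
    from idopnet.selection import RegressionProblem

    r1 = order + 1
    grid = np.sort(rng.uniform(10.0, 100.0, n))
    groups = {f"g{j}": rng.normal(size=(n, r1))
              for j in range(1, n_candidates + 1)}
    self_design = np.column_stack([np.ones(n), rng.normal(size=(n, r1))])
    true_support = list(rng.choice(list(groups), k_true, replace=False)
                        ) if k_true else []
    y = self_design @ rng.normal(0, 1.0, r1 + 1)
    for g in true_support:
        y = y + groups[g] @ rng.normal(0, 1.0, r1)
    sd = max(float(np.std(y)), 1.0)
    y = y + rng.normal(0.0, noise * sd, n)
    p = RegressionProblem("t", y, grid, self_design, groups,
                          boundary_weight(grid))
    return p, true_support


class TestBuildProblem:
    def test_group_shapes(self, rng):
        grid = np.linspace(1.0, 10.0, 12)
        curves = {"a": grid**0.5, "b": grid**1.2, "c": np.log(grid) + 1}
        p = build_problem("a", curves, grid, order=2)
        assert set(p.groups) == {"b", "c"}
        assert all(X.shape == (12, 3) for X in p.groups.values())

    def test_boundary_weight_bump(self):
        grid = np.linspace(2.0, 8.0, 7)
        Z = boundary_weight(grid)
        assert Z[0] == 0.0 and Z[-1] == 0.0
        assert Z.argmax() == 3 and Z.max() == pytest.approx(1.0)
        assert np.all(Z >= 0)

    def test_groups_are_integrated_designs(self, rng):
        # group columns are running integrals of the pointwise Legendre
        # design in the regulator's normalized values (trapezoid oracle)
        grid = np.sort(rng.uniform(1, 20, 15))
        curves = {"t": grid**1.1, "r": grid**0.6}
        p = build_problem("t", curves, grid, order=3)
        X = lop_design(curves["r"], (curves["r"].min(), curves["r"].max()), 3)
        oracle = np.zeros_like(X)
        for i in range(1, 15):
            oracle[i] = oracle[i - 1] + 0.5 * (grid[i] - grid[i - 1]) * (
                X[i - 1] + X[i]
            )
        np.testing.assert_allclose(p.groups["r"], oracle, atol=1e-12)

    def test_constant_regulator_dropped(self, rng):
        grid = np.linspace(1.0, 5.0, 10)
        curves = {"a": grid, "b": np.full(10, 3.0)}
        with pytest.warns(UserWarning, match="degenerate"):
            p = build_problem("a", curves, grid, order=2)
        assert "b" not in p.groups


class TestGroupLassoPath:
    def test_exact_zero_at_lambda_max(self, rng):
        p, _ = make_regression(rng, n=40, n_candidates=6)
        lmax = lambda_max(p)
        res = group_lasso_path(p, lambdas=np.array([2 * lmax, lmax]))
        for r in res:
            assert r.selected == []

    def test_groups_activate_below_lambda_max(self, rng):
        p, _ = make_regression(rng, n=40, n_candidates=6)
        res = group_lasso_path(p)
        assert any(r.selected for r in res[5:])

    def test_lambda_zero_matches_weighted_least_squares(self, rng):
        p, _ = make_regression(rng, n=60, n_candidates=3)
        res = group_lasso_path(
            p, lambdas=np.array([1.0, 0.0]), max_sweeps=60_000
        )[-1]
        X = np.hstack([p.self_design] + [p.groups[g] for g in p.groups])
        sw = np.sqrt(p.weights)
        beta = np.linalg.lstsq(sw[:, None] * X, sw * p.y, rcond=None)[0]
        r = p.y - X @ beta
        wrss_oracle = float(r @ (p.weights * r))
        assert res.weighted_rss == pytest.approx(wrss_oracle, abs=1e-4)

    def test_objective_nonincreasing_across_sweeps(self, rng):
        p, _ = make_regression(rng, n=50, n_candidates=8)
        objs = sweep_objectives(p, lam=0.3 * lambda_max(p), n_sweeps=30)
        assert all(b <= a + 1e-9 for a, b in zip(objs, objs[1:]))

    def test_selection_invariant_to_relabeling(self, rng):
        p, _ = make_regression(rng, n=50, n_candidates=6)
        best = choose_lambda(group_lasso_path(p))
        renamed = dict(p.groups)
        remap = {g: f"x_{g}" for g in renamed}
        p.groups = {remap[g]: X for g, X in renamed.items()}
        best2 = choose_lambda(group_lasso_path(p))
        assert sorted(remap[g] for g in best.selected) == sorted(best2.selected)


class TestChooseLambda:
    def test_unique_minimizer_returned(self, rng):
        p, _ = make_regression(rng, n=60, n_candidates=8)
        path = group_lasso_path(p)
        best = choose_lambda(path, criterion="BIC")
        assert best.criterion == min(r.criterion for r in path)

    def test_null_data_yields_empty_selection(self, rng):
        # pure-noise responses: extended BIC should keep the model empty
        empty = 0
        reps = 20
        for i in range(reps):
            r = np.random.default_rng(500 + i)
            p, _ = make_regression(r, n=40, n_candidates=10, k_true=0,
                                   noise=1.0)
            best = choose_lambda(group_lasso_path(p), criterion="extendedBIC")
            empty += not best.selected
        assert empty >= int(0.9 * reps)

    def test_support_recovery_on_constructed_problem(self, rng):
        # 2-of-29 design: mean F1 across seeds
        f1s = []
        for i in range(15):
            r = np.random.default_rng(900 + i)
            p, truth = make_regression(r, n=100, n_candidates=29, k_true=2,
                                       noise=0.1)  # 10% of signal SD
            best = choose_lambda(group_lasso_path(p), criterion="extendedBIC")
            sel = set(best.selected)
            tp = len(sel & set(truth))
            f1 = 2 * tp / (2 * tp + len(sel - set(truth))
                           + len(set(truth) - sel)) if tp else 0.0
            f1s.append(f1)
        assert np.mean(f1s) >= 0.8

    def test_rejects_unknown_criterion(self, rng):
        p, _ = make_regression(rng, n=30, n_candidates=3)
        path = group_lasso_path(p, lambdas=np.array([1.0]))
        with pytest.raises(FitError, match="criterion"):
            choose_lambda(path, criterion="AIC")
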