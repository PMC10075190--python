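"""The constrained optimizer: feasibility, optimality, and invariances."""

import numpy as np
import pytest

import chronocorrect as cc
from chronocorrect.correction import InfeasibleError

from conftest import constraint, random_violated_instance, violated_subset


def assert_feasible(T, R, result, eps_topo=None):
    tol = 1e-6 * max(T.root_age, 1.0)
    d = result.dates
    for i in range(2, T.num_nodes + 1):
        assert d[T.parent[i]] - d[i] >= -tol
    for _, (i, j) in R:
        assert d[i] - d[j] >= -tol
    for i in T.leaf_ids:
        assert d[i] == T.dates[i]


class TestIdentity:
    @pytest.mark.parametrize("obj", cc.OBJECTIVES)
    def test_satisfied_input_returned_unchanged(self, fix_a, obj):
        R = cc.resolve([constraint("c1", ("C", "D"), ("A", "B"))], fix_a)  # satisfied
        res = cc.error_correct(cc.CorrectionProblem(T=fix_a, R=R, objective=obj))
        assert res.phi == 0.0
        np.testing.assert_allclose(
            res.dates[1:], fix_a.dates[1:], atol=1e-9 * fix_a.root_age
        )

    @pytest.mark.parametrize("obj", cc.OBJECTIVES)
    def test_empty_constraints_identity(self, fix_a, obj):
        R = cc.resolve([], fix_a)
        res = cc.error_correct(cc.CorrectionProblem(T=fix_a, R=R, objective=obj))
        assert res.phi == 0.0


class TestFixAWorkedInstance:
    """The violated instance on the 4-leaf example, against the grid oracle."""

    @pytest.mark.parametrize("obj", cc.OBJECTIVES)
    def test_matches_grid_oracle(self, fix_a, u_older_v, obj):
        res = cc.error_correct(
            cc.CorrectionProblem(T=fix_a, R=u_older_v, objective=obj)
        )
        oracle = cc.grid_minimize(fix_a, u_older_v, obj)
        # optimizer can only do as well or better than the grid, up to grid error
        assert res.phi <= oracle.phi + 1e-3 * max(oracle.phi, 1.0)
        assert res.phi >= 0.0
        np.testing.assert_allclose(res.dates[1:4], oracle.dates[1:4], atol=0.6)

    def test_sbd_constraint_barely_active(self, fix_a, u_older_v):
        # single-tree correction tends to just barely satisfy the constraint
        res = cc.error_correct(
            cc.CorrectionProblem(T=fix_a, R=u_older_v, objective="sbd")
        )
        u, v = u_older_v.resolved["c1"]
        assert 0.0 <= res.dates[u] - res.dates[v] <= 0.02

    def test_sbd_and_sdd_argmins_differ(self, fix_a, u_older_v):
        r1 = cc.error_correct(
            cc.CorrectionProblem(T=fix_a, R=u_older_v, objective="sbd")
        )
        r2 = cc.error_correct(
            cc.CorrectionProblem(T=fix_a, R=u_older_v, objective="sdd")
        )
        assert not np.allclose(r1.dates[1:4], r2.dates[1:4], atol=0.05)
        assert_feasible(fix_a, u_older_v, r1)
        assert_feasible(fix_a, u_older_v, r2)


class TestFeasibilityOnRandomInstances:
    @pytest.mark.parametrize("obj", cc.OBJECTIVES)
    def test_corrections_satisfy_everything(self, obj):
        for seed in range(4):
            inst = random_violated_instance(seed, n_leaves=15, n_transfers=8)
            R = inst.constraints
            res = cc.error_correct(
                cc.CorrectionProblem(T=inst.perturbed, R=R, objective=obj)
            )
            assert_feasible(inst.perturbed, R, res)
            assert cc.count_violations(res.corrected(inst.perturbed), R) == 0


class TestScaleEquivariance:
    @pytest.mark.parametrize("obj", cc.OBJECTIVES)
    @pytest.mark.parametrize("c", [0.1, 3.0, 1000.0])
    def test_scaling_dates_scales_solution(self, fix_a, u_older_v, obj, c):
        base = cc.error_correct(
            cc.CorrectionProblem(T=fix_a, R=u_older_v, objective=obj)
        )
        scaled_T = fix_a.copy(dates=fix_a.dates * c)
        scaled_R = u_older_v  # same node ids
        res = cc.error_correct(
            cc.CorrectionProblem(T=scaled_T, R=scaled_R, objective=obj)
        )
        np.testing.assert_allclose(
            res.dates[1:], base.dates[1:] * c, rtol=1e-6, atol=1e-6 * c * 30
        )


class TestSolverContract:
    def test_inconsistent_constraints_raise(self, fix_a):
        R = cc.resolve(
            [
                constraint("c1", ("A", "B"), ("C", "D")),
                constraint("c2", ("C", "D"), ("A", "B")),
            ],
            fix_a,
        )
        # one of the two is violated, and together they force a cycle only
        # if strict; equal dates satisfy both, but the cycle check rejects
        with pytest.raises(InfeasibleError, match="cycle"):
            cc.error_correct(cc.CorrectionProblem(T=fix_a, R=R, objective="sbd"))

    def test_conflicting_absolute_bounds_raise(self, fix_a, u_older_v):
        u, v = u_older_v.resolved["c1"]
        bounds = {u: (None, 5.0), v: (25.0, None)}  # u<=5 but u>=v>=25
        with pytest.raises(InfeasibleError):
            cc.error_correct(
                cc.CorrectionProblem(
                    T=fix_a, R=u_older_v, objective="sbd", absolute_bounds=bounds
                )
            )

    def test_absolute_bounds_respected_when_feasible(self, fix_a, u_older_v):
        u, v = u_older_v.resolved["c1"]
        bounds = {1: (None, 32.0)}  # cap the root
        res = cc.error_correct(
            cc.CorrectionProblem(
                T=fix_a, R=u_older_v, objective="sbd", absolute_bounds=bounds
            )
        )
        assert res.dates[1] <= 32.0 + 1e-6 * 30
        assert_feasible(fix_a, u_older_v, res)

    def test_slrb_multistart_deterministic(self):
        inst = random_violated_instance(3, n_leaves=12, n_transfers=8)
        runs = [
            cc.error_correct(
                cc.CorrectionProblem(
                    T=inst.perturbed,
                    R=inst.constraints,
                    objective="slrb",
                    multistart=2,
                    seed=11,
                )
            )
            for _ in range(2)
        ]
        np.testing.assert_array_equal(runs[0].dates, runs[1].dates)
        assert runs[0].phi == runs[1].phi

    def test_result_diagnostics_shape(self, fix_a, u_older_v):
        res = cc.error_correct(
            cc.CorrectionProblem(T=fix_a, R=u_older_v, objective="sbd")
        )
        assert set(res.constraint_residuals) == {"c1"}
        assert len(res.edge_length_changes) == 2 * fix_a.n - 2
        assert res.phi > 0


class TestOracleEquivalenceSmall:
    """Spot checks vs the exhaustive grid on random 5-leaf instances."""

    @pytest.mark.parametrize("obj", cc.OBJECTIVES)
    def test_solver_at_least_as_good_as_grid(self, obj):
        checked = 0
        for seed in range(10):
            try:
                inst = random_violated_instance(
                    seed, n_leaves=5, n_transfers=3, sigma2=0.5
                )
            except RuntimeError:
                continue
            R = violated_subset(inst.perturbed, inst.constraints)
            res = cc.error_correct(
                cc.CorrectionProblem(T=inst.perturbed, R=R, objective=obj,
                                     gtol=1e-12, xtol=1e-14)
            )
            oracle = cc.grid_minimize(inst.perturbed, R, obj)
            assert res.phi <= oracle.phi + 1e-3 * max(oracle.phi, 1e-9)
            checked += 1
            if checked >= 3:
                break
        assert checked >= 3
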