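"""Tests for the transcription, the reduced-space solver, and the oracle."""

import numpy as np
import pytest

import paceopt as po
from paceopt.ocp import _ReducedEvaluator


@pytest.fixture(scope="module")
def small_spec(wr_params, good_default):
    grid = po.Grid.minute_mesh(30.0)
    return po.assemble_ocp(wr_params, good_default, po.catalog()[1], grid, p=0.5)


class TestTVSplit:
    @pytest.mark.parametrize(
        "f,zeta,iota",
        [
            ((5.0, 8.0), (3.0,), (0.0,)),
            ((8.0, 6.0), (0.0,), (2.0,)),
            ((4.0, 4.0, 4.0), (0.0, 0.0), (0.0, 0.0)),
        ],
    )
    def test_examples(self, f, zeta, iota):
        z, i = po.tv_split(np.array(f))
        np.testing.assert_allclose(z, zeta)
        np.testing.assert_allclose(i, iota)

    def test_split_properties_random(self):
        rng = np.random.default_rng(11)
        f = rng.uniform(0, 36000, 50)
        z, i = po.tv_split(f)
        np.testing.assert_allclose(z - i, np.diff(f), rtol=1e-12)
        assert np.all(z >= 0) and np.all(i >= 0)
        assert np.all(z * i == 0.0)
        assert np.sum(z + i) == pytest.approx(po.total_variation(f), rel=1e-12)


class TestAssembly:
    def test_world_record_layout(self, wr_params, good_default):
        grid = po.Grid.minute_mesh(120.0)
        spec = po.assemble_ocp(wr_params, good_default, po.catalog()[11], grid, p=0.5)
        sl = spec.slices
        assert sl["f"].stop - sl["f"].start == 120
        for name in ("EF", "EG", "V", "N"):
            assert sl[name].stop - sl[name].start == 121
        for name in ("zeta", "iota"):
            assert sl[name].stop - sl[name].start == 119
        assert spec.n_var == 120 + 4 * 121 + 2 * 119
        lb, ub = spec.bounds_full()
        assert np.all(lb == 0.0)
        assert ub[sl["f"]][0] == wr_params.f_max
        assert ub[sl["V"]][0] == wr_params.vvo2max
        assert ub[sl["EG"]][0] == pytest.approx(
            wr_params.EG0 + wr_params.c3 * spec.total_nutrition_kj
        )

    def test_negative_penalty_rejected(self, wr_params, good_default):
        grid = po.Grid.minute_mesh(10.0)
        with pytest.raises(ValueError):
            po.assemble_ocp(wr_params, good_default, po.catalog()[0], grid, p=-0.1)

    def test_zero_penalty_objective_is_distance_only(self, wr_params, good_default):
        grid = po.Grid.minute_mesh(10.0)
        spec = po.assemble_ocp(wr_params, good_default, po.catalog()[0], grid, p=0.0)
        f = np.full(10, 1.0e4)
        traj = po.simulate_forward(wr_params, good_default, f, spec.s, grid)
        z, i = po.tv_split(f)
        J = spec.objective_full(spec.pack(traj, z, i))
        assert J == pytest.approx(-grid.delta * np.sum(traj.V[:-1]), rel=1e-12)

    def test_zero_source_keeps_nutrition_empty(self, wr_params, good_default):
        grid = po.Grid.minute_mesh(20.0)
        spec = po.assemble_ocp(wr_params, good_default, po.catalog()[0], grid, p=0.5)
        traj = po.simulate_forward(wr_params, good_default, np.full(20, 1e4), spec.s, grid)
        assert np.all(traj.N == 0.0)


class TestGradients:
    def test_analytic_jacobians_match_finite_differences(self, small_spec):
        ev = _ReducedEvaluator(small_spec)
        rng = np.random.default_rng(0)
        K = ev.K
        x = np.concatenate(
            [rng.uniform(0.2, 0.6, K), rng.uniform(0, 0.01, K - 1), rng.uniform(0, 0.01, K - 1)]
        )
        eps = 1e-7
        fd_g = np.zeros_like(x)
        fd_J = np.zeros((3 * K, len(x)))
        for j in range(len(x)):
            xp, xm = x.copy(), x.copy()
            xp[j] += eps
            xm[j] -= eps
            fd_g[j] = (ev.objective(xp) - ev.objective(xm)) / (2 * eps)
            fd_J[:, j] = (ev.ineq(xp) - ev.ineq(xm)) / (2 * eps)
        np.testing.assert_allclose(ev.objective_grad(x), fd_g, atol=1e-7)
        np.testing.assert_allclose(ev.ineq_jac(x), fd_J, atol=1e-6)


class TestSolve:
    def test_deterministic_repeat(self, small_spec):
        d1 = po.solve_ocp(small_spec).distance_m
        d2 = po.solve_ocp(small_spec).distance_m
        assert abs(d1 - d2) <= 1e-9

    def test_guess_independence(self, small_spec):
        d_warm = po.solve_ocp(small_spec, initial_guess="warm").distance_m
        d_paper = po.solve_ocp(small_spec, initial_guess="paper").distance_m
        d_arr = po.solve_ocp(small_spec, initial_guess=np.full(30, 1.2e4)).distance_m
        assert d_paper == pytest.approx(d_warm, rel=1e-4)
        assert d_arr == pytest.approx(d_warm, rel=1e-4)

    def test_converged_solution_is_feasible(self, small_spec):
        sol = po.solve_ocp(small_spec)
        assert sol.status == "converged"
        assert sol.constraint_residual <= 1e-6
        traj = sol.trajectory
        assert np.min(traj.EG) >= -1e-8
        assert np.min(traj.EF) >= -1e-8
        assert np.max(traj.V) <= small_spec.params.vvo2max + 1e-8
        assert np.all(traj.f >= -1e-12) and np.all(traj.f <= small_spec.params.f_max + 1e-8)
        # reconstructed full decision vector satisfies the transcription
        X = small_spec.pack(traj, sol.zeta, sol.iota)
        res = small_spec.constraint_residuals(X)
        assert max(res[k] for k in res if k != "bounds") <= 1e-8

    def test_empty_glycogen_forces_rest(self, wr_params, good_default):
        params = wr_params.replace(EG0=0.0)
        grid = po.Grid.minute_mesh(10.0)
        spec = po.assemble_ocp(params, good_default, po.catalog()[0], grid, p=0.5)
        sol = po.solve_ocp(spec)
        assert sol.distance_m <= 1.0

    def test_bad_guess_length_raises(self, small_spec):
        with pytest.raises(ValueError):
            po.solve_ocp(small_spec, initial_guess=np.zeros(7))


class TestTVPenalty:
    def test_tv_nonincreasing_in_p_two_phase_instance(self, wr_params, good_default):
        """With nearly empty initial stores and one mid-race gel the optimal
        pace is genuinely two-phase; raising the variation penalty must
        not increase the total variation of the force schedule."""
        params = wr_params.replace(EG0=2.0)
        grid = po.Grid.minute_mesh(30.0)
        strat = po.NutritionStrategy.explicit("midgel", [(15.0, 100.0)])
        tvs = []
        for pv in (0.0, 0.05, 0.5, 5.0):
            sol = po.solve_ocp(po.assemble_ocp(params, good_default, strat, grid, p=pv))
            assert sol.status == "converged"
            tvs.append(sol.tv)
        assert tvs[0] > 1000.0                       # unpenalized solution varies
        for a, b in zip(tvs, tvs[1:]):
            assert b <= a + 1e-6 * wr_params.f_max


class TestOracle:
    def test_nlp_beats_ladder_oracle(self, good_default):
        params = po.RunnerParams.world_record().replace(EG0=4.0)
        grid = po.Grid.minute_mesh(8.0)
        s0 = po.catalog()[0]
        ladder = np.linspace(0.0, params.f_max, 4)
        best = po.dp_oracle(params, good_default, s0, grid, ladder)
        sol = po.solve_ocp(po.assemble_ocp(params, good_default, s0, grid, p=0.0))
        assert best > 0.0
        assert sol.distance_m >= 0.99 * best

    def test_bang_control_matches_closed_form(self, good_default):
        """With effectively unlimited glycogen the two-level oracle picks
        max force everywhere, i.e. the constant-force ramp trajectory."""
        params = po.RunnerParams.world_record().replace(EG0=1.0e6)
        grid = po.Grid.minute_mesh(5.0)
        best = po.dp_oracle(params, good_default, po.catalog()[0], grid, [0.0, params.f_max])
        f = np.full(5, params.f_max)
        traj = po.simulate_forward(params, good_default, f, np.zeros(5), grid)
        assert best == pytest.approx(traj.distance(), rel=1e-12)

    def test_zero_energy_gives_zero_distance(self, good_default):
        params = po.RunnerParams.world_record().replace(EG0=0.0)
        grid = po.Grid.minute_mesh(5.0)
        best = po.dp_oracle(params, good_default, po.catalog()[0], grid, [0.0, 18000.0])
        assert best == 0.0

    def test_oracle_refuses_large_instances(self, wr_params, good_default):
        with pytest.raises(ValueError):
            po.dp_oracle(wr_params, good_default, po.catalog()[0], po.Grid.minute_mesh(20.0), [0, 1])


def test_optimize_over_strategies_small(wr_params, good_default):
    grid = po.Grid.minute_mesh(20.0)
    strategies = [po.catalog()[0], po.catalog()[1]]
    table, sols = po.optimize_over_strategies(wr_params, good_default, strategies, grid, p=0.5)
    assert set(table["strategy"]) == {"s0", "s1"}
    assert set(sols) == {"s0", "s1"}
    assert table["distance_km"].is_monotonic_decreasing
    assert bool(table["co_optimal"].iloc[0])
    with pytest.raises(ValueError):
        po.optimize_over_strategies(wr_params, good_default, [], grid)
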