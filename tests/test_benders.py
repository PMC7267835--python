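"""Hybrid Benders algorithm: primitives, master/slave, and the full loop."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nihba.benders import (
    BendersCut,
    BranchState,
    CorePoint,
    HBAConfig,
    hamming_distance,
    mip_gap,
    run_hba,
    solve_master,
    solve_slave,
    update_core_point,
)
from nihba.fba import follower_min_production
from nihba.milp import (
    brute_force_interdiction,
    build_single_level_milp,
    sample_penalties,
)
from nihba.model import DesignVector

from conftest import random_case


class TestPrimitives:
    def test_hamming_examples(self):
        assert hamming_distance((1, 0, 1), (1, 0, 1)) == 0
        assert hamming_distance((1, 0, 1), (0, 0, 1)) == 1
        with pytest.raises(ValueError):
            hamming_distance((1, 0), (1, 0, 1))

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=20),
           st.data())
    @settings(max_examples=30, deadline=None)
    def test_hamming_symmetry(self, y, data):
        y2 = data.draw(st.lists(st.integers(0, 1), min_size=len(y),
                                max_size=len(y)))
        assert hamming_distance(y, y2) == hamming_distance(y2, y)

    def test_core_point_average(self):
        core = CorePoint(np.array([0.5, 0.5]))
        updated = update_core_point(core, np.array([1, 0]))
        assert np.allclose(updated.y_hat, [0.75, 0.25])

    def test_core_point_stays_interior(self):
        core = CorePoint(np.array([0.4, 0.4, 0.4]))
        rng = np.random.default_rng(0)
        for _ in range(100):
            core = update_core_point(core, rng.integers(0, 2, size=3))
            assert np.all(core.y_hat > 0) and np.all(core.y_hat < 1)

    def test_core_point_rejects_boundary(self):
        with pytest.raises(ValueError):
            CorePoint(np.array([0.0, 0.5]))

    def test_gap_schedule(self):
        assert mip_gap(0) == pytest.approx(301.0)
        assert mip_gap(4) == pytest.approx(101.0)
        assert mip_gap(10000) == pytest.approx(3.9703, abs=1e-4)
        gaps = [mip_gap(i) for i in range(0, 200, 10)]
        assert gaps == sorted(gaps, reverse=True)
        with pytest.raises(ValueError):
            mip_gap(-1)


class TestMaster:
    def test_cap_binds_without_cuts(self):
        branch = BranchState(np.zeros(3, int), r=3)
        sol = solve_master([], branch, K=2, z_cap=10.0, n_candidates=3)
        assert sol.status == "optimal"
        assert sol.z_value == pytest.approx(10.0)

    def test_two_cuts_single_candidate(self):
        cuts = [
            BendersCut("optimality", 4.0, np.array([3.0])),   # z <= 4 - 3 y
            BendersCut("optimality", 1.0, np.array([-2.0])),  # z <= 1 + 2 y
        ]
        branch = BranchState(None, r=1)
        sol = solve_master(cuts, branch, K=1, z_cap=10.0, n_candidates=1)
        assert sol.z_value == pytest.approx(1.0)

    def test_feasibility_cut_excludes_design(self):
        cuts = [BendersCut("feasibility", 2.0, np.array([3.0]))]  # 2 - 3y >= 0
        branch = BranchState(None, r=1)
        sol = solve_master(cuts, branch, K=1, z_cap=10.0, n_candidates=1)
        assert sol.y_bar[0] == 0

    def test_empty_hamming_ball_reported_infeasible(self):
        # reverse constraint excludes everything within Sum y <= K
        branch = BranchState(np.zeros(2, int), r=3,
                             reverses=[(np.zeros(2, int), 3)])
        sol = solve_master([], branch, K=1, z_cap=5.0, n_candidates=2)
        assert sol.status == "infeasible"


class TestSlave:
    def _milp(self, toy5, cand, K):
        return build_single_level_milp(
            toy5, cand, toy5.index("PRD"), K=K, growth_floor=1.0
        )

    def test_optimality_cut_at_good_design(self, toy5, toy5_candidates):
        milp = self._milp(toy5, toy5_candidates, 1)
        kind, value, cut, x = solve_slave(milp, np.array([1, 0]))
        assert kind == "optimality"
        assert value == pytest.approx(1.0, abs=1e-6)
        # the cut is tight at the probed design
        assert cut.rhs_at(np.array([1, 0])) == pytest.approx(1.0, abs=1e-5)

    def test_feasibility_cut_excludes_exactly_infeasible(self, toy5, toy5_candidates):
        milp = self._milp(toy5, toy5_candidates, 2)
        kind, value, cut, x = solve_slave(milp, np.array([1, 1]))
        assert kind == "feasibility" and value is None
        for y in itertools.product((0, 1), repeat=2):
            design = DesignVector.from_knockouts(
                {c for c, b in zip(toy5_candidates, y) if b}, toy5_candidates, 2
            )
            feasible = follower_min_production(
                toy5, toy5.index("PRD"), design, 1.0
            ).optimal
            if feasible:
                assert cut.rhs_at(np.array(y)) >= -1e-6
        assert cut.rhs_at(np.array([1, 1])) < -1e-9

    def test_perturbation_negligible(self, toy5, toy5_candidates):
        milp = self._milp(toy5, toy5_candidates, 1)
        core = CorePoint(np.array([0.3, 0.3]))
        for y in ([0, 0], [1, 0], [0, 1]):
            _, v_pert, _, _ = solve_slave(milp, np.array(y), core,
                                          recompute_exact=False)
            _, v_exact, _, _ = solve_slave(milp, np.array(y),
                                           recompute_exact=False)
            assert v_pert == pytest.approx(v_exact, abs=1e-5)

    def test_pareto_cut_not_dominated(self, toy5, toy5_candidates):
        """The core-point cut is valid and never strictly dominated by the
        unperturbed cut over the enumerable feasible designs."""
        milp = self._milp(toy5, toy5_candidates, 1)
        core = CorePoint(np.array([0.3, 0.3]))
        _, _, pareto, _ = solve_slave(milp, np.array([0, 0]), core)
        _, _, plain, _ = solve_slave(milp, np.array([0, 0]))
        feasible = [np.array(y) for y in ([0, 0], [1, 0], [0, 1])]
        truth = {(0, 0): 0.0, (1, 0): 1.0, (0, 1): 0.0}
        for y in feasible:
            assert pareto.rhs_at(y) >= truth[tuple(y)] - 1e-6
            assert plain.rhs_at(y) >= truth[tuple(y)] - 1e-6
        plain_leq = all(plain.rhs_at(y) <= pareto.rhs_at(y) + 1e-9
                        for y in feasible)
        plain_strict = any(plain.rhs_at(y) < pareto.rhs_at(y) - 1e-9
                           for y in feasible)
        assert not (plain_leq and plain_strict)


class TestRunHBA:
    def test_toy5_canonical(self, toy5, toy5_candidates):
        res = run_hba(toy5, toy5_candidates, toy5.index("PRD"),
                      HBAConfig(K=1, growth_floor=1.0, max_iter=200))
        assert res.status == "optimal"
        assert res.best_value == pytest.approx(1.0, abs=1e-6)
        assert res.best.knocked_ids == ("R1",)

    def test_empty_candidates_rejected(self, toy5):
        from nihba.errors import ConfigurationError
        with pytest.raises(ConfigurationError):
            run_hba(toy5, (), toy5.index("PRD"), HBAConfig(K=1))

    def test_bounds_monotone_and_close(self, toy5, toy5_candidates):
        res = run_hba(toy5, toy5_candidates, toy5.index("PRD"),
                      HBAConfig(K=1, growth_floor=1.0, max_iter=200))
        uppers = [t.z_upper for t in res.trace]
        lowers = [t.z_lower for t in res.trace if np.isfinite(t.z_lower)]
        assert all(a >= b - 1e-9 for a, b in zip(uppers, uppers[1:]))
        assert all(a <= b + 1e-9 for a, b in zip(lowers, lowers[1:]))
        assert res.trace[-1].z_upper - res.trace[-1].z_lower <= 1e-4

    def test_pool_unique_and_reevaluates(self, random_fixture):
        case = random_fixture
        res = run_hba(case["model"], case["candidates"], case["target"],
                      HBAConfig(K=case["K"], growth_floor=case["growth_floor"],
                                max_iter=500))
        keys = [tuple(rec.design.y) for rec in res.pool]
        assert len(keys) == len(set(keys))
        for rec in res.pool:
            check = follower_min_production(
                case["model"], case["target"], rec.design, case["growth_floor"]
            )
            assert check.optimal
            assert check.objective_value == pytest.approx(
                rec.min_production_at_floor, abs=1e-6
            )

    def test_optimality_cuts_bound_all_designs(self, toy5, toy5_candidates):
        """Every optimality cut upper-bounds the true interdiction value at
        every enumerable feasible design."""
        res = run_hba(toy5, toy5_candidates, toy5.index("PRD"),
                      HBAConfig(K=2, growth_floor=1.0, max_iter=200))
        for y in itertools.product((0, 1), repeat=2):
            design = DesignVector.from_knockouts(
                {c for c, b in zip(toy5_candidates, y) if b}, toy5_candidates, 2
            )
            sol = follower_min_production(toy5, toy5.index("PRD"), design, 1.0)
            for cut in res.cuts:
                rhs = cut.rhs_at(np.array(y))
                if cut.kind == "optimality" and sol.optimal:
                    assert rhs >= sol.objective_value - 1e-6
                if cut.kind == "feasibility" and sol.optimal:
                    assert rhs >= -1e-6

    def test_threshold_filters_pool(self, toy5, toy5_candidates):
        res = run_hba(toy5, toy5_candidates, toy5.index("PRD"),
                      HBAConfig(K=1, growth_floor=1.0, threshold_fraction=0.05,
                                max_iter=200))
        # wild type guarantees 0 < 5% TMP, so only {R1} qualifies
        assert [rec.knocked_ids for rec in res.pool] == [("R1",)]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force(self, seed):
        case = random_case(seed + 50)
        best, _ = brute_force_interdiction(
            case["model"], case["candidates"], case["K"], case["target"],
            case["growth_floor"],
        )
        res = run_hba(case["model"], case["candidates"], case["target"],
                      HBAConfig(K=case["K"], growth_floor=case["growth_floor"],
                                max_iter=500))
        assert res.status == "optimal"
        assert res.best_value == pytest.approx(best, abs=1e-5)
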