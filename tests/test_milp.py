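"""Penalty sampling, follower LP reformulation, single-level MILP, direct
solve and the brute-force oracle."""

import itertools

import numpy as np
import pytest

from nihba import _solver
from nihba.errors import CapabilityError
from nihba.fba import follower_min_production, theoretical_max_production
from nihba.milp import (
    brute_force_interdiction,
    build_follower_lp,
    build_single_level_milp,
    sample_penalties,
    solve_direct,
)
from nihba.model import DesignVector

from conftest import random_case


class TestPenalties:
    def test_default_range(self):
        pen = sample_penalties(200)
        assert np.all(pen.M >= 90.0) and np.all(pen.M <= 110.0)

    def test_deterministic(self):
        assert np.array_equal(sample_penalties(50, seed=7).M,
                              sample_penalties(50, seed=7).M)

    def test_degenerate_interval(self):
        pen = sample_penalties(10, low=100.0, high=100.0)
        assert np.all(pen.M == 100.0)

    def test_bad_interval(self):
        with pytest.raises(ValueError):
            sample_penalties(5, low=110.0, high=90.0)


class TestFollowerLagrangian:
    def test_penalty_silences_knocked_reaction(self, toy5, toy5_candidates):
        pen = sample_penalties(2)
        design = DesignVector.from_knockouts({toy5.index("R1")}, toy5_candidates, 1)
        sol = build_follower_lp(toy5, toy5.index("PRD"), pen, design, 1.0).solve()
        assert sol.objective_value == pytest.approx(1.0)
        assert abs(sol.v[toy5.index("R1")]) <= 1e-9

    def test_empty_design_reduces_to_plain_follower(self, toy5, toy5_candidates):
        pen = sample_penalties(2)
        design = DesignVector.from_knockouts(set(), toy5_candidates, 1)
        sol = build_follower_lp(toy5, toy5.index("PRD"), pen, design, 1.0).solve()
        assert sol.objective_value == pytest.approx(0.0)

    def test_matches_exact_follower_on_random_designs(self, random_fixture):
        """Lagrangian reformulation == direct inner LP over 50 random designs."""
        case = random_fixture
        model, cand = case["model"], case["candidates"]
        pen = sample_penalties(len(cand))
        rng = np.random.default_rng(case["seed"])
        for _ in range(50):
            k = int(rng.integers(0, case["K"] + 1))
            knocked = set(rng.choice(cand, size=k, replace=False).tolist())
            design = DesignVector.from_knockouts(knocked, cand, case["K"])
            exact = follower_min_production(
                model, case["target"], design, case["growth_floor"]
            )
            lagr = build_follower_lp(
                model, case["target"], pen, design, case["growth_floor"]
            ).solve()
            if exact.optimal:
                assert lagr.optimal
                assert lagr.objective_value == pytest.approx(
                    exact.objective_value, abs=1e-6
                )
                for j in design.knocked_indices:
                    assert abs(lagr.v[j]) <= 1e-6
            else:
                # the penalized LP stays feasible: infeasibility of the exact
                # follower shows up as penalty activation (a knocked reaction
                # forced to carry flux)
                assert any(abs(lagr.v[j]) > 1e-6
                           for j in design.knocked_indices)


class TestSingleLevelMILP:
    def test_toy5_direct_matches_oracle(self, toy5, toy5_candidates):
        milp = build_single_level_milp(
            toy5, toy5_candidates, toy5.index("PRD"), K=1,
            growth_floor=1.0,
        )
        value, design, status = solve_direct(milp)
        assert status == "optimal"
        assert value == pytest.approx(1.0, abs=1e-6)
        assert design.knocked_ids(toy5) == ("R1",)

    def test_zero_budget_gives_wild_type_minimum(self, toy5, toy5_candidates):
        milp = build_single_level_milp(
            toy5, toy5_candidates, toy5.index("PRD"), K=0, growth_floor=1.0
        )
        value, design, status = solve_direct(milp)
        assert value == pytest.approx(0.0, abs=1e-6)
        assert design.n_knockouts == 0

    def test_restricted_candidates_tie_at_zero(self, toy5):
        milp = build_single_level_milp(
            toy5, (toy5.index("R3"),), toy5.index("PRD"), K=1, growth_floor=1.0
        )
        value, design, status = solve_direct(milp)
        assert value == pytest.approx(0.0, abs=1e-6)  # both designs attain 0

    def test_strong_duality_at_optimum(self, toy5, toy5_candidates):
        milp = build_single_level_milp(
            toy5, toy5_candidates, toy5.index("PRD"), K=1, growth_floor=1.0
        )
        _, design, _ = solve_direct(milp)
        res = _solver.solve_lp(
            milp.c, A_eq=milp.A_eq, b_eq=milp.b_eq, A_ub=milp.A_ub,
            b_ub=milp.rhs(np.array(design.y, float)), bounds=milp.x_bounds,
            sense="max",
        )
        assert milp.duality_residual(res.x) <= 1e-6

    def test_penalty_sufficiency_at_optimum(self, random_fixture):
        case = random_fixture
        milp = build_single_level_milp(
            case["model"], case["candidates"], case["target"], case["K"],
            growth_floor=case["growth_floor"],
        )
        _, design, status = solve_direct(milp)
        assert status == "optimal"
        res = _solver.solve_lp(
            milp.c, A_eq=milp.A_eq, b_eq=milp.b_eq, A_ub=milp.A_ub,
            b_ub=milp.rhs(np.array(design.y, float)), bounds=milp.x_bounds,
            sense="max",
        )
        v = milp.split(res.x)["v"]
        for j in design.knocked_indices:
            assert abs(v[j]) <= 1e-6

    def test_objective_sandwich_and_monotone_in_k(self, toy5, toy5_candidates):
        tmp = theoretical_max_production(toy5, toy5.index("PRD"))
        values = []
        for K in (0, 1, 2):
            best, _ = brute_force_interdiction(
                toy5, toy5_candidates, K, toy5.index("PRD"), 1.0
            )
            assert -1e-9 <= best <= tmp + 1e-9
            values.append(best)
        assert values == sorted(values)

    def test_lp_file_writer(self, toy5, toy5_candidates, tmp_path):
        milp = build_single_level_milp(
            toy5, toy5_candidates, toy5.index("PRD"), K=1, growth_floor=1.0
        )
        path = tmp_path / "model.lp"
        milp.write_lp(path)
        text = path.read_text()
        assert text.startswith("Maximize")
        assert "Binary" in text and "<= 1" in text


class TestBruteForce:
    def test_toy5_k1(self, toy5, toy5_candidates):
        value, designs = brute_force_interdiction(
            toy5, toy5_candidates, 1, toy5.index("PRD"), 1.0
        )
        assert value == pytest.approx(1.0)
        assert [d.knocked_ids(toy5) for d in designs] == [("R1",)]

    def test_toy5_k2_skips_infeasible(self, toy5, toy5_candidates):
        value, designs = brute_force_interdiction(
            toy5, toy5_candidates, 2, toy5.index("PRD"), 1.0
        )
        assert value == pytest.approx(1.0)
        assert [d.knocked_ids(toy5) for d in designs] == [("R1",)]

    def test_k0_single_subset(self, toy5, toy5_candidates):
        value, designs = brute_force_interdiction(
            toy5, toy5_candidates, 0, toy5.index("PRD"), 1.0
        )
        assert value == pytest.approx(0.0)
        assert designs[0].n_knockouts == 0

    def test_guard(self, toy5):
        with pytest.raises(CapabilityError):
            brute_force_interdiction(
                toy5, tuple(range(5)), 3, toy5.index("PRD"), 0.0, guard=2
            )


@pytest.mark.parametrize("seed", range(6))
def test_direct_solve_equals_brute_force(seed):
    case = random_case(seed)
    best, _ = brute_force_interdiction(
        case["model"], case["candidates"], case["K"], case["target"],
        case["growth_floor"],
    )
    milp = build_single_level_milp(
        case["model"], case["candidates"], case["target"], case["K"],
        growth_floor=case["growth_floor"],
    )
    value, _, status = solve_direct(milp)
    assert status == "optimal"
    assert value == pytest.approx(best, abs=1e-5)
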