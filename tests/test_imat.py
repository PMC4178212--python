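"""The cue-agreement MILP: structure, optima, classification, comparison."""

import math

import numpy as np
import pytest

from fluxcue.imat import (
    IMATConfig,
    brute_force_imat,
    build_milp,
    classify_activity,
    compare_conditions,
    solve_imat,
    ActivityCall,
)
from fluxcue.model import MetabolicModel, Metabolite, Reaction

from conftest import make_chain, make_diamond, random_cued_network, states_for


class TestBuildMilp:
    def test_chain_with_one_high_cue_counts(self, chain):
        problem = build_milp(chain, states_for(chain, R2=1), IMATConfig())
        assert problem.n_flux == 4
        assert problem.n_binary == 1
        # one mass-balance row per metabolite
        assert problem.constraints[0].A.shape[0] == 3

    def test_no_cues_is_a_pure_lp(self, chain):
        problem = build_milp(chain, states_for(chain), IMATConfig())
        assert problem.n_binary == 0

    def test_reversible_high_reaction_gets_two_linked_binaries(self):
        model = MetabolicModel(
            [Metabolite("A")],
            [
                Reaction("IN", {"A": 1.0}, -10.0, 10.0, is_exchange=True),
                Reaction("OUT", {"A": -1.0}, -10.0, 10.0, is_exchange=True),
            ],
        )
        problem = build_milp(model, states_for(model, IN=1), IMATConfig())
        assert problem.n_binary == 2
        sol = solve_imat(model, states_for(model, IN=1))
        assert sol.objective == 1  # at most one direction can satisfy the cue

    def test_unknown_reaction_in_states_rejected(self, chain):
        states = states_for(chain)
        states.states["GHOST"] = 1
        with pytest.raises(ValueError, match="GHOST"):
            build_milp(chain, states, IMATConfig())

    def test_epsilon_must_exceed_zero_tol(self):
        with pytest.raises(ValueError):
            IMATConfig(epsilon=1e-9, zero_tol=1e-6)


class TestSolve:
    def test_chain_single_high_cue(self, chain):
        sol = solve_imat(chain, states_for(chain, R2=1))
        assert sol.solver_status == "optimal"
        assert sol.objective == 1
        assert all(v >= 1.0 - 1e-7 for v in sol.flux.values())

    def test_all_moderate_has_objective_zero(self, chain):
        sol = solve_imat(chain, states_for(chain))
        assert sol.objective == 0

    def test_conflicting_cues_on_coupled_reactions(self, chain):
        # mass balance forces v_R1 = v_R2, so "R1 high" and "R2 low"
        # cannot both hold
        sol = solve_imat(chain, states_for(chain, R1=1, R2=-1))
        assert sol.objective == 1

    def test_infeasible_base_reports_status_not_exception(self):
        model = MetabolicModel(
            [Metabolite("A")],
            [Reaction("IN", {"A": 1.0}, 2.0, 3.0, is_exchange=True)],
        )
        sol = solve_imat(model, states_for(model))
        assert sol.solver_status == "infeasible"

    def test_indicators_reflect_flux(self, chain):
        sol = solve_imat(chain, states_for(chain, R2=1, R3=1))
        assert sol.objective == 2
        assert sol.indicators == {"R2": True, "R3": True}


class TestClassification:
    def test_chain_cue_activates_whole_chain(self, chain):
        calls = classify_activity(chain, states_for(chain, R2=1))
        assert {c.verdict for c in calls} == {"active"}
        for c in calls:
            assert c.objective_if_forced_inactive < c.objective_if_forced_active

    def test_blocked_reaction_is_inactive(self):
        # M -> with no producer of M: zero flux in every feasible solution
        model = MetabolicModel(
            [Metabolite("M")],
            [Reaction("OUT", {"M": -1.0}, 0.0, 10.0, is_exchange=True)],
        )
        calls = classify_activity(model, states_for(model))
        assert calls[0].verdict == "inactive"
        assert calls[0].objective_if_forced_active == -math.inf

    def test_diamond_branches_undetermined(self, diamond):
        calls = {
            c.reaction: c
            for c in classify_activity(diamond, states_for(diamond, SRC=1, SNK=1))
        }
        assert calls["SRC"].verdict == "active"
        assert calls["SNK"].verdict == "active"
        for branch in ("AB", "BD", "AC", "CD"):
            assert calls[branch].verdict == "undetermined"
            assert (
                calls[branch].objective_if_forced_active
                == calls[branch].objective_if_forced_inactive
            )

    def test_low_cue_keeps_chain_silent(self, chain):
        calls = {c.reaction: c for c in classify_activity(chain, states_for(chain, R3=-1))}
        assert all(c.verdict == "inactive" for c in calls.values())

    def test_flux_ranges_cover_optimum_preserving_solutions(self, chain):
        calls = classify_activity(chain, states_for(chain, R2=1), compute_ranges=True)
        for c in calls:
            lo, hi = c.flux_range
            assert lo == pytest.approx(1.0, abs=1e-6)
            assert hi == pytest.approx(10.0, abs=1e-6)


class TestOracleAgreement:
    def test_shipped_fixtures_match_brute_force(self, chain, diamond):
        scenarios = [
            (chain, states_for(chain, R2=1)),
            (chain, states_for(chain, R1=1, R2=-1)),
            (chain, states_for(chain)),
            (chain, states_for(chain, R1=1, R2=1, R3=-1, R4=-1)),
            (diamond, states_for(diamond, SRC=1, SNK=1)),
            (diamond, states_for(diamond, AB=1, AC=-1, SNK=1)),
        ]
        for model, states in scenarios:
            assert (
                solve_imat(model, states).objective
                == brute_force_imat(model, states).objective
            )

    def test_random_networks_match_brute_force(self):
        rng = np.random.default_rng(20240917)
        for _ in range(10):
            model, states = random_cued_network(rng)
            assert (
                solve_imat(model, states).objective
                == brute_force_imat(model, states).objective
            )

    def test_adding_a_cue_changes_objective_by_zero_or_one(self, chain):
        base = states_for(chain, R2=1)
        before = solve_imat(chain, base).objective
        for rid, state in [("R3", 1), ("R3", -1), ("R1", 1)]:
            augmented = states_for(chain, R2=1, **{rid: state})
            after = solve_imat(chain, augmented).objective
            assert after in (before, before + 1)

    def test_brute_force_refuses_large_instances(self):
        mets = [Metabolite(f"m{i}") for i in range(14)]
        rxns = [
            Reaction(f"x{i}", {mets[i].id: 1.0}, 0.0, 10.0, is_exchange=True)
            for i in range(14)
        ] + [
            Reaction(f"y{i}", {mets[i].id: -1.0}, 0.0, 10.0, is_exchange=True)
            for i in range(14)
        ]
        model = MetabolicModel(mets, rxns)
        states = states_for(model, **{f"x{i}": 1 for i in range(13)})
        with pytest.raises(ValueError, match="brute-force limit"):
            brute_force_imat(model, states)

    def test_empty_cue_set_objective_zero(self, chain):
        assert brute_force_imat(chain, states_for(chain)).objective == 0


class TestInvariants:
    def test_conservation_of_returned_flux(self, chain):
        config = IMATConfig()
        sol = solve_imat(chain, states_for(chain, R2=1, R3=-1), config)
        S = chain.stoichiometric_matrix()
        v = np.array([sol.flux[r] for r in chain.reaction_ids])
        assert np.abs(S @ v).max() <= config.zero_tol
        for r in chain.reactions:
            assert r.lower_bound - 1e-9 <= sol.flux[r.id] <= r.upper_bound + 1e-9

    def test_scale_invariance(self, chain):
        states = states_for(chain, R2=1, R3=-1)
        base_obj = solve_imat(chain, states).objective
        base_verdicts = [c.verdict for c in classify_activity(chain, states)]
        scale = 7.0
        scaled = make_chain(ub=10.0 * scale)
        config = IMATConfig(epsilon=1.0 * scale, zero_tol=1e-6 * scale)
        assert solve_imat(scaled, states_for(scaled, R2=1, R3=-1), config).objective == base_obj
        scaled_verdicts = [
            c.verdict for c in classify_activity(scaled, states_for(scaled, R2=1, R3=-1), config)
        ]
        assert scaled_verdicts == base_verdicts

    def test_same_inputs_reproduce_identical_solution(self, chain):
        states = states_for(chain, R2=1, R4=-1)
        a = solve_imat(chain, states)
        b = solve_imat(chain, states)
        assert a.objective == b.objective and a.flux == b.flux


class TestCompareConditions:
    @staticmethod
    def call(reaction, condition, verdict, rng):
        return ActivityCall(condition, reaction, verdict, 0, 0, rng)

    def test_separated_ranges_called_higher(self):
        a = [self.call("R", "A", "active", (1.0, 2.0))]
        b = [self.call("R", "B", "inactive", (0.0, 0.0))]
        assert compare_conditions(a, b)[0].call == "higher_in_a"
        assert compare_conditions(b, a)[0].call == "higher_in_b"

    def test_identical_ranges_indistinguishable(self):
        a = [self.call("R", "A", "active", (0.0, 5.0))]
        b = [self.call("R", "B", "active", (0.0, 5.0))]
        assert compare_conditions(a, b)[0].call == "indistinguishable"

    def test_mismatched_reactions_rejected(self):
        a = [self.call("R1", "A", "active", (0.0, 1.0))]
        b = [self.call("R2", "B", "active", (0.0, 1.0))]
        with pytest.raises(ValueError, match="mismatched"):
            compare_conditions(a, b)
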