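"""GPR evaluation, discretization, and reaction-state assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluxcue.expression import (
    ExpressionProfile,
    GeneStateMap,
    assign_reaction_states,
    center_by_gene,
    condition_summaries,
    discretize_expression,
    discretize_profile,
    summarize_condition,
)
from fluxcue.gpr import GprParseError, evaluate_gpr, gpr_to_string, parse_gpr

from conftest import make_chain


class TestGpr:
    @pytest.mark.parametrize(
        "rule, states, expected",
        [
            ("(g1 and g2) or g3", {"g1": 1, "g2": 0, "g3": -1}, 0),
            ("g1 or g2", {"g1": 1, "g2": -1}, 1),
            ("g1 and g2", {"g1": 1, "g2": -1}, -1),
            ("", {}, 0),
            ("g1 and (g2 or g3)", {"g1": 1, "g2": -1, "g3": 1}, 1),
            ("G1 AND g2", {"G1": 1, "g2": 1}, 1),  # case-insensitive keywords
        ],
    )
    def test_evaluation(self, rule, states, expected):
        assert evaluate_gpr(parse_gpr(rule), states) == expected

    def test_missing_gene_counts_as_moderate(self):
        assert evaluate_gpr(parse_gpr("g1 and g_absent"), {"g1": 1}) == 0

    def test_string_round_trip(self):
        for rule in ["g1", "g1 and g2", "(g1 and g2) or g3", "g1 or (g2 and (g3 or g4))"]:
            tree = parse_gpr(rule)
            assert parse_gpr(gpr_to_string(tree)) == tree

    @pytest.mark.parametrize("bad", ["g1 and", "and g1", "(g1 or g2", "g1 g2", "()"])
    def test_malformed_rules_rejected(self, bad):
        with pytest.raises(GprParseError):
            parse_gpr(bad)

    @given(st.permutations(["g1", "g2", "g3", "g4"]))
    @settings(max_examples=24, deadline=None)
    def test_commutativity_of_children(self, genes):
        # reordering AND/OR children never changes the value
        states = {"g1": 1, "g2": 0, "g3": -1, "g4": 1}
        assert evaluate_gpr(parse_gpr(" and ".join(genes)), states) == -1
        assert evaluate_gpr(parse_gpr(" or ".join(genes)), states) == 1


def make_profile():
    values = pd.DataFrame(
        {"s1": [4.0, 1.0], "s2": [6.0, 1.0], "s3": [7.0, 2.0]},
        index=pd.Index(["gA", "gB"], name="gene"),
    )
    design = pd.Series({"s1": "c1", "s2": "c1", "s3": "c2"})
    return ExpressionProfile(values, design)


class TestSummaries:
    def test_replicates_collapse_by_mean(self):
        summary = summarize_condition(make_profile(), "c1")
        assert summary["gA"] == 5.0 and summary["gB"] == 1.0

    def test_single_sample_condition_is_identity(self):
        summary = summarize_condition(make_profile(), "c2")
        assert summary["gA"] == 7.0

    def test_unknown_condition_raises(self):
        with pytest.raises(KeyError):
            summarize_condition(make_profile(), "nope")

    def test_gene_centering_removes_baseline(self):
        centered = center_by_gene(condition_summaries(make_profile()))
        # gA: c1=5, c2=7 -> baseline 6 -> (-1, +1); gB: 1, 2 -> (-0.5, +0.5)
        assert centered.loc["gA", "c1"] == -1.0 and centered.loc["gA", "c2"] == 1.0
        assert np.allclose(centered.mean(axis=1), 0.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"values": pd.DataFrame([[1.0]], index=["g", ], columns=["s"]),
             "design": pd.Series({"other": "c"})},
            {"values": pd.DataFrame([[np.inf]], index=["g"], columns=["s"]),
             "design": pd.Series({"s": "c"})},
            {"values": pd.DataFrame([[1.0], [2.0]], index=["g", "g"], columns=["s"]),
             "design": pd.Series({"s": "c"})},
        ],
        ids=["unlabelled-sample", "non-finite", "duplicate-gene"],
    )
    def test_profile_invariants_enforced(self, kwargs):
        with pytest.raises(ValueError):
            ExpressionProfile(**kwargs)


class TestDiscretization:
    def test_quartiles_on_one_to_eight(self):
        # quantiles of 1..8 with linear interpolation: q25=2.75, q75=6.25,
        # so exactly {1,2} are low and {7,8} high
        summary = pd.Series(np.arange(1.0, 9.0), index=[f"g{i}" for i in range(8)])
        states = discretize_expression(summary, 0.25, 0.75).states
        assert sorted(g for g, s in states.items() if s == -1) == ["g0", "g1"]
        assert sorted(g for g, s in states.items() if s == 1) == ["g6", "g7"]
        assert sum(1 for s in states.values() if s == 0) == 4

    def test_constant_vector_yields_no_cues(self):
        summary = pd.Series([3.0, 3.0, 3.0], index=list("abc"))
        assert set(discretize_expression(summary).states.values()) == {0}

    def test_explicit_thresholds(self):
        summary = pd.Series([1.0, 2.0, 4.0, 7.0, 8.0], index=list("abcde"))
        states = discretize_expression(summary, t_low=2.5, t_high=6.5).states
        assert [states[g] for g in "abcde"] == [-1, -1, 0, 1, 1]

    @pytest.mark.parametrize("q_low, q_high", [(0.0, 0.75), (0.5, 0.5), (0.25, 1.0)])
    def test_invalid_quantiles_rejected(self, q_low, q_high):
        with pytest.raises(ValueError):
            discretize_expression(pd.Series([1.0, 2.0]), q_low, q_high)

    @given(
        st.lists(st.floats(min_value=-50, max_value=50), min_size=4, max_size=12),
        st.integers(min_value=0, max_value=11),
        st.floats(min_value=0.1, max_value=20),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_each_gene(self, values, idx, bump):
        # raising one gene's value never lowers its state
        idx = idx % len(values)
        genes = [f"g{i}" for i in range(len(values))]
        before = discretize_expression(pd.Series(values, index=genes)).states
        values = list(values)
        values[idx] += bump
        after = discretize_expression(pd.Series(values, index=genes)).states
        assert after[genes[idx]] >= before[genes[idx]]


class TestDiscretizeProfile:
    def make_two_condition_profile(self):
        # gA induced in c2; gB..gE flat backgrounds at staggered levels
        values = pd.DataFrame(
            {
                "a1": [2.0, 1.0, 3.0, 5.0, 7.0],
                "b1": [8.0, 1.0, 3.0, 5.0, 7.0],
            },
            index=pd.Index(list("ABCDE"), name="gene"),
        )
        design = pd.Series({"a1": "c1", "b1": "c2"})
        return ExpressionProfile(values, design)

    def test_centered_mode_cues_only_the_regulated_gene(self):
        maps = discretize_profile(
            self.make_two_condition_profile(), center="gene", t_low=-1.5, t_high=1.5
        )
        assert maps["c1"].states == {"A": -1, "B": 0, "C": 0, "D": 0, "E": 0}
        assert maps["c2"].states == {"A": 1, "B": 0, "C": 0, "D": 0, "E": 0}

    def test_pooled_quantiles_shared_across_conditions(self):
        profile = self.make_two_condition_profile()
        maps = discretize_profile(profile, 0.25, 0.75, pooled=True)
        # pooled values {1,1,2,3,3,5,5,7,7,8}: q25=2.25, q75=6.5
        assert maps["c1"].states["B"] == -1 and maps["c2"].states["B"] == -1
        assert maps["c1"].states["E"] == 1 and maps["c2"].states["A"] == 1
        per_condition = discretize_profile(profile, 0.25, 0.75, pooled=False)
        assert per_condition["c1"].states != maps["c1"].states

    def test_unknown_center_mode_rejected(self):
        with pytest.raises(ValueError, match="center"):
            discretize_profile(self.make_two_condition_profile(), center="sample")


class TestReactionStates:
    def test_single_high_gene_maps_to_single_high_reaction(self, chain):
        gs = GeneStateMap("c1", {"g2": 1, "g3": 0})
        assignment = assign_reaction_states(chain, gs)
        assert assignment.r_high == ["R2"] and assignment.r_low == []

    def test_all_moderate_genes_give_all_moderate_reactions(self, chain):
        gs = GeneStateMap("c1", {"g2": 0, "g3": 0})
        assert set(assign_reaction_states(chain, gs).states.values()) == {0}

    def test_and_rule_takes_minimum(self, chain):
        chain.reactions[1].gpr = parse_gpr("gA and gB")
        gs = GeneStateMap("c1", {"gA": 1, "gB": -1, "g3": 0})
        assert assign_reaction_states(chain, gs).states["R2"] == -1

    def test_empty_gpr_reactions_stay_moderate(self, chain):
        gs = GeneStateMap("c1", {"g2": 1, "g3": -1})
        assignment = assign_reaction_states(chain, gs)
        assert assignment.states["R1"] == 0 and assignment.states["R4"] == 0
        gpr_bearing = sum(1 for r in chain.reactions if r.gpr is not None)
        assert len(assignment.r_high) + len(assignment.r_low) <= gpr_bearing
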