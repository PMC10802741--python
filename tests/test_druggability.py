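"""Circuit validation, signal propagation, in-silico inhibition and
favorable-response rates, checked against brute-force recursion."""

import numpy as np
import pandas as pd
import pytest

from lnresponse import druggability as dr
from lnresponse import simulate as sim


def chain_circuit():
    return dr.CircuitGraph.from_tables(
        "chain", [("R", ("g1",)), ("A", ("g2",)), ("E", ("g3",))],
        [("R", "A", 1), ("A", "E", 1)])


def brute_force_signal(circuit, values, node):
    """Independent recursive evaluation of the propagation rule."""
    g = circuit.graph
    def s(n):
        parents = list(g.predecessors(n))
        if not parents:
            return values[n]
        act = [s(p) for p in parents if g.edges[p, n]["sign"] > 0]
        inh = [s(p) for p in parents if g.edges[p, n]["sign"] < 0]
        a = 1.0 - np.prod([1.0 - x for x in act]) if act else 0.0
        i = np.prod([1.0 - x for x in inh]) if inh else 1.0
        return values[n] * a * i
    return s(node)


class TestCircuitValidation:
    def test_cycle_rejected_with_cycle_named(self):
        with pytest.raises(ValueError, match="cycle"):
            dr.CircuitGraph.from_tables(
                "bad", [("a", ("g",)), ("b", ("g",))],
                [("a", "b", 1), ("b", "a", 1)])

    def test_multiple_effectors_rejected(self):
        with pytest.raises(ValueError, match="effector"):
            dr.CircuitGraph.from_tables(
                "bad", [("r", ("g",)), ("e1", ("g",)), ("e2", ("g",))],
                [("r", "e1", 1), ("r", "e2", 1)])

    def test_roles_assigned(self):
        circ = chain_circuit()
        roles = {n: d["role"] for n, d in circ.graph.nodes(data=True)}
        assert roles == {"R": "receptor", "A": "intermediate",
                         "E": "effector"}


class TestPropagate:
    def test_activation_chain_hand_example(self):
        S = dr.propagate(chain_circuit(), {"R": 0.5, "A": 0.5, "E": 0.5})
        assert S["R"] == pytest.approx(0.5)
        assert S["A"] == pytest.approx(0.25)
        assert S["E"] == pytest.approx(0.125)

    def test_mixed_inputs_hand_example(self):
        circ = dr.CircuitGraph.from_tables(
            "m", [("A", ("a",)), ("I", ("i",)), ("E", ("e",))],
            [("A", "E", 1), ("I", "E", -1)])
        S = dr.propagate(circ, {"A": 0.25, "I": 0.5, "E": 0.5})
        assert S["E"] == pytest.approx(0.0625)

    def test_zero_receptor_absorbs(self):
        S = dr.propagate(chain_circuit(), {"R": 0.0, "A": 0.9, "E": 0.9})
        assert S["A"] == 0.0 and S["E"] == 0.0

    def test_matches_brute_force_on_random_circuits(self, rng):
        circuits = sim.generate_circuits(60, 8, inhibitor_fraction=0.35,
                                         seed=99)
        for circ in circuits:
            values = {n: float(rng.uniform(0, 1)) for n in circ.graph}
            S = dr.propagate(circ, values)
            for node in circ.graph:
                assert S[node] == pytest.approx(
                    brute_force_signal(circ, values, node), abs=1e-12)
                assert 0.0 <= S[node] <= 1.0

    def test_monotone_in_edge_sign(self, rng):
        """Raising the value of a node with a single outgoing activation
        (inhibition) never decreases (increases) effector activity."""
        circuits = sim.generate_circuits(40, 7, inhibitor_fraction=0.4,
                                         seed=123)
        for circ in circuits:
            g = circ.graph
            values = {n: float(rng.uniform(0.1, 0.9)) for n in g}
            base = dr.propagate(circ, values)[circ.effector]
            for node in g:
                out_edges = list(g.out_edges(node, data=True))
                if len(out_edges) != 1 or out_edges[0][1] != circ.effector:
                    continue
                bumped = dict(values)
                bumped[node] = min(1.0, values[node] + 0.2)
                new = dr.propagate(circ, bumped)[circ.effector]
                if out_edges[0][2]["sign"] > 0:
                    assert new >= base - 1e-12
                else:
                    assert new <= base + 1e-12

    def test_inhibiting_pure_activation_chain_never_raises_activity(self):
        circ = chain_circuit()
        values = {"R": 0.7, "A": 0.6, "E": 0.5}
        base = dr.propagate(circ, values)[circ.effector]
        for node in values:
            lowered = dict(values)
            lowered[node] = values[node] * 0.1
            assert dr.propagate(circ, lowered)[circ.effector] <= base + 1e-12


class TestRankScaling:
    def test_top_rank_of_nine_samples(self):
        expr = pd.DataFrame([np.arange(1.0, 10.0)], index=["g"],
                            columns=[f"s{i}" for i in range(9)])
        circ = dr.CircuitGraph.from_tables(
            "c", [("R", ("g",)), ("E", ("g",))], [("R", "E", 1)])
        nv = dr.compute_node_values(expr, circ)
        assert nv.loc["R", "s8"] == pytest.approx(0.9)

    def test_single_gene_node_equals_gene_value(self, rng):
        expr = pd.DataFrame(rng.normal(5, 1, (2, 7)), index=["g1", "g2"],
                            columns=[f"s{i}" for i in range(7)])
        circ = dr.CircuitGraph.from_tables(
            "c", [("R", ("g1",)), ("E", ("g2",))], [("R", "E", 1)])
        nv = dr.compute_node_values(expr, circ)
        from scipy.stats import rankdata
        np.testing.assert_allclose(
            nv.loc["R"].to_numpy(),
            rankdata(expr.loc["g1"]) / 8.0)

    def test_inhibition_strictly_lowers_scaled_value(self):
        expr = pd.DataFrame([[1.0, 2.0, 4.0, 8.0, 16.0]], index=["g"],
                            columns=list("abcde"))
        circ = dr.CircuitGraph.from_tables(
            "c", [("R", ("g",)), ("E", ("g",))], [("R", "E", 1)])
        before = dr.compute_node_values(expr, circ)
        perturbed = dr.simulate_inhibition(expr, ["g"], 0.1)
        after = dr.compute_node_values(perturbed, circ, reference=expr)
        assert after.loc["R", "e"] < before.loc["R", "e"]

    def test_missing_node_genes_rejected(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["a", "b"])
        circ = dr.CircuitGraph.from_tables(
            "c", [("R", ("absent",)), ("E", ("g",))], [("R", "E", 1)])
        with pytest.raises(ValueError, match="measured"):
            dr.compute_node_values(expr, circ)


class TestInhibition:
    def test_multiplies_targets_only(self):
        expr = pd.DataFrame({"s": [8.0, 3.0]}, index=["t", "u"])
        out = dr.simulate_inhibition(expr, ["t"], 0.1)
        assert out.loc["t", "s"] == pytest.approx(0.8)
        assert out.loc["u", "s"] == pytest.approx(3.0)

    def test_factor_one_is_identity(self):
        expr = pd.DataFrame({"s": [8.0, 3.0]}, index=["t", "u"])
        pd.testing.assert_frame_equal(
            dr.simulate_inhibition(expr, ["t"], 1.0), expr)

    def test_absent_targets_rejected(self):
        expr = pd.DataFrame({"s": [8.0]}, index=["g"])
        with pytest.raises(ValueError, match="zzz"):
            dr.simulate_inhibition(expr, ["zzz"])


class TestResponseScore:
    def test_hand_example_via_direct_node_values(self):
        circ = chain_circuit()
        before = dr.propagate(circ, {"R": 0.5, "A": 0.5, "E": 0.5})
        after = dr.propagate(circ, {"R": 0.5, "A": 0.05, "E": 0.5})
        assert abs(after["E"] - before["E"]) == pytest.approx(0.1125)

    def test_targets_outside_all_circuits_score_zero(self, rng):
        expr = pd.DataFrame(rng.uniform(1, 10, (4, 6)),
                            index=["g1", "g2", "g3", "x"],
                            columns=[f"s{i}" for i in range(6)])
        circ = chain_circuit()
        with pytest.warns(UserWarning, match="no circuit"):
            scores = dr.response_score(expr, [circ], ["x"])
        assert (scores["score"] == 0).all()

    def test_factor_one_scores_zero(self, rng):
        expr = pd.DataFrame(rng.uniform(1, 10, (3, 6)),
                            index=["g1", "g2", "g3"],
                            columns=[f"s{i}" for i in range(6)])
        scores = dr.response_score(expr, [chain_circuit()], ["g2"],
                                   factor=1.0)
        np.testing.assert_allclose(scores["score"].to_numpy(), 0.0)

    def test_inhibition_changes_scores(self, rng):
        expr = pd.DataFrame(rng.uniform(1, 10, (3, 12)),
                            index=["g1", "g2", "g3"],
                            columns=[f"s{i}" for i in range(12)])
        scores = dr.response_score(expr, [chain_circuit()], ["g2"])
        assert scores["score"].max() > 0

    def test_score_invariant_to_circuit_order(self, rng):
        expr = pd.DataFrame(rng.uniform(1, 10, (6, 10)),
                            index=[f"g{i}" for i in range(6)],
                            columns=[f"s{i}" for i in range(10)])
        c1 = dr.CircuitGraph.from_tables(
            "a", [("R", ("g0",)), ("E", ("g1",))], [("R", "E", 1)])
        c2 = dr.CircuitGraph.from_tables(
            "b", [("R", ("g2",)), ("E", ("g3",))], [("R", "E", 1)])
        s12 = dr.response_score(expr, [c1, c2], ["g0", "g2"])
        s21 = dr.response_score(expr, [c2, c1], ["g0", "g2"])
        pd.testing.assert_frame_equal(s12, s21)

    def test_upshifted_arm_scores_higher(self, rng):
        """Samples with elevated pathway-gene expression move more under
        inhibition of an upstream target."""
        n = 40
        expr = pd.DataFrame(rng.uniform(1, 4, (3, n)),
                            index=["g1", "g2", "g3"],
                            columns=[f"s{i}" for i in range(n)])
        expr.iloc[:, : n // 2] *= 3.0  # arm with up-shifted pathway
        scores = dr.response_score(expr, [chain_circuit()], ["g1"])
        up = scores["score"].iloc[: n // 2].mean()
        down = scores["score"].iloc[n // 2:].mean()
        assert up > down


class TestFavorableRate:
    def test_toy_vector(self):
        scores = pd.Series([1.0, 2.0, 3.0, 10.0], index=list("abcd"))
        assert dr.favorable_rate(scores) == pytest.approx(0.25)

    def test_all_equal_rate_one(self):
        scores = pd.Series([2.0, 2.0, 2.0], index=list("abc"))
        assert dr.favorable_rate(scores) == pytest.approx(1.0)

    def test_single_patient_rate_one(self):
        assert dr.favorable_rate(pd.Series([5.0], index=["a"])) == 1.0

    def test_group_scoped_against_cohort_mean(self):
        scores = pd.Series([1.0, 2.0, 3.0, 10.0], index=list("abcd"))
        rate = dr.favorable_rate(scores, group=["c", "d"])
        assert rate == pytest.approx(0.5)  # mean 4; only d >= 4

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            dr.favorable_rate(pd.Series([1.0], index=["a"]), group=[])
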