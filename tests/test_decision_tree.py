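"""Decision-tree construction, outcome labeling, expected impact, sampling."""

import math
from dataclasses import replace
from datetime import date, timedelta

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pji_cea.decision_tree import (
    died_without_pji,
    DecisionTreeCEModel,
    Outcome,
    ROOT,
    assign_outcome,
    build_tree,
    expected_impact,
    sample_path,
)
from pji_cea.records import TreatmentMethod
from .conftest import OP_A, OP_B, OP_C, make_record


def prefix_count_oracle(sequences):
    """Exhaustive prefix-count probabilities for (label-sequence, outcome)
    pairs; independent of the tree builder.  Returns {(parent, child): p}."""
    full = [tuple(seq) + (out,) for seq, out in sequences]
    probs = {}

    def walk(prefix):
        holders = [s for s in full if s[: len(prefix)] == prefix and len(s) > len(prefix)]
        if not holders:
            return
        nxt = {}
        for s in holders:
            nxt.setdefault(s[len(prefix)], 0)
        for s in holders:
            nxt[s[len(prefix)]] += 1
        for label, n in nxt.items():
            probs[(prefix, prefix + (label,))] = n / len(holders)
            walk(prefix + (label,))

    walk(())
    return probs


class TestAssignOutcome:
    def test_death_requires_confirmed_pji(self):
        assert assign_outcome(make_record([OP_A], "Death")) is Outcome.DEATH

    def test_alive_with_pji_is_failure(self):
        assert assign_outcome(make_record([OP_A], "Failure")) is Outcome.FAILURE

    def test_no_pji_is_success(self):
        assert assign_outcome(make_record([OP_A], "Success")) is Outcome.SUCCESS

    def test_death_without_pji_counts_as_success_with_flag(self):
        r = make_record([OP_A], "Success")
        r = replace(r, death_date=r.censor_date)
        assert assign_outcome(r) is Outcome.SUCCESS
        assert died_without_pji(r)
        assert not died_without_pji(make_record([OP_A], "Death"))


class TestBuildTree:
    def test_toy_probabilities_match_hand_counts(self, toy_tree_records):
        tree = build_tree(toy_tree_records, TreatmentMethod.RA)
        g = tree.graph
        a = (OP_A,)
        assert g.edges[ROOT, a]["probability"] == 1.0
        assert g.edges[a, a + (OP_B,)]["probability"] == pytest.approx(2 / 3)
        assert g.edges[a, a + (OP_C,)]["probability"] == pytest.approx(1 / 3)
        ab = a + (OP_B,)
        assert g.edges[ab, ab + ("Success",)]["probability"] == pytest.approx(1 / 2)
        assert g.edges[ab, ab + ("Failure",)]["probability"] == pytest.approx(1 / 2)
        ac = a + (OP_C,)
        assert g.edges[ac, ac + ("Success",)]["probability"] == 1.0

    def test_single_record_gives_certain_chain(self):
        tree = build_tree([make_record([OP_A, OP_B])], TreatmentMethod.RA)
        assert all(d["probability"] == 1.0 for _, _, d in tree.edges())
        assert tree.graph.number_of_nodes() == 4  # root, A, B, Success

    def test_no_records_for_method_is_an_error(self, toy_tree_records):
        with pytest.raises(ValueError, match="1-stage"):
            build_tree(toy_tree_records, TreatmentMethod.ONE_STAGE)

    def test_support_conservation(self, default_cohort):
        tree = build_tree(default_cohort, TreatmentMethod.TWO_STAGE_GT2M)
        g = tree.graph
        for node in g.nodes:
            children = list(g.successors(node))
            if children:
                assert g.nodes[node]["support"] == sum(
                    g.nodes[c]["support"] for c in children
                )

    def test_probability_normalization_on_real_cohort(self, default_cohort):
        for method in (TreatmentMethod.RA, TreatmentMethod.ONE_STAGE):
            tree = build_tree(default_cohort, method)
            tree.validate()  # outgoing sums == 1 +- 1e-9 at every inner node

    def test_horizon_truncation_drops_late_operations(self):
        r = make_record([OP_A, OP_B], months_between=30, censor_months=48)
        tree = build_tree([r], TreatmentMethod.RA, horizon_months=24)
        labels = {d["label"] for _, d in tree.graph.nodes(data=True)}
        assert OP_B not in labels  # second operation falls in month 30 > 24

    def test_edge_costs_are_mean_recorded_costs(self):
        recs = [
            make_record([OP_A], costs=[100.0], pid="a"),
            make_record([OP_A], costs=[300.0], pid="b"),
        ]
        tree = build_tree(recs, TreatmentMethod.RA)
        assert tree.graph.edges[ROOT, (OP_A,)]["cost"] == pytest.approx(200.0)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        seqs=st.lists(
            st.tuples(
                st.lists(st.sampled_from([OP_A, OP_B, OP_C]), max_size=4),
                st.sampled_from(["Success", "Failure", "Death"]),
            ),
            min_size=1,
            max_size=20,
        )
    )
    def test_edge_probabilities_equal_prefix_count_oracle(self, seqs):
        records = [
            make_record(list(s), out, pid=f"p{i}", months_between=1, censor_months=30)
            for i, (s, out) in enumerate(seqs)
        ]
        tree = build_tree(records, TreatmentMethod.RA, horizon_months=30)
        oracle = prefix_count_oracle(seqs)
        built = {
            (a, b): d["probability"] for a, b, d in tree.graph.edges(data=True)
        }
        assert built.keys() == oracle.keys()
        for k in oracle:
            assert built[k] == pytest.approx(oracle[k])


class TestExpectedImpact:
    def test_certain_chain_sums_costs(self):
        tree = build_tree(
            [make_record([OP_A, OP_B], costs=[100.0, 50.0])], TreatmentMethod.RA
        )
        assert expected_impact(tree, "rubles") == pytest.approx(150.0)

    def test_symmetric_two_leaf_expectation(self):
        recs = [
            make_record([OP_A], costs=[100.0], pid="a"),
            make_record([OP_B], costs=[200.0], pid="b"),
        ]
        tree = build_tree(recs, TreatmentMethod.RA)
        assert expected_impact(tree, "rubles") == pytest.approx(150.0)

    def test_missing_unit_rejected(self, toy_tree_records):
        tree = build_tree(toy_tree_records, TreatmentMethod.RA)
        with pytest.raises(ValueError, match="unit"):
            expected_impact(tree, "dollars")

    def test_monte_carlo_agreement(self, toy_tree_records):
        tree = build_tree(toy_tree_records, TreatmentMethod.RA)
        rng = np.random.default_rng(99)
        n = 20_000
        draws = np.array([sample_path(tree, rng)[1] for _ in range(n)])
        se = draws.std(ddof=1) / math.sqrt(n)
        assert abs(draws.mean() - expected_impact(tree, "rubles")) < 3 * se


class TestSamplePath:
    def test_degenerate_tree_always_takes_unique_path(self):
        tree = build_tree([make_record([OP_A, OP_B])], TreatmentMethod.RA)
        rng = np.random.default_rng(0)
        for _ in range(20):
            labels, _, _ = sample_path(tree, rng)
            assert labels == ["RA", OP_A, OP_B, "Success"]

    def test_fixed_seed_reproduces_path(self, toy_tree_records):
        tree = build_tree(toy_tree_records, TreatmentMethod.RA)
        assert sample_path(tree, 42) == sample_path(tree, 42)

    def test_leaf_frequencies_match_path_probabilities(self, toy_tree_records):
        # P(leaf): A->B->Success 1/3, A->B->Failure 1/3, A->C->Success 1/3
        tree = build_tree(toy_tree_records, TreatmentMethod.RA)
        rng = np.random.default_rng(7)
        n = 10_000
        counts = {}
        for _ in range(n):
            labels, _, _ = sample_path(tree, rng)
            key = tuple(labels[1:])
            counts[key] = counts.get(key, 0) + 1
        for key, p in {
            (OP_A, OP_B, "Success"): 1 / 3,
            (OP_A, OP_B, "Failure"): 1 / 3,
            (OP_A, OP_C, "Success"): 1 / 3,
        }.items():
            se = math.sqrt(p * (1 - p) / n)
            assert abs(counts[key] / n - p) < 2.576 * se  # 99% binomial CI


class TestEstimatorInterface:
    def test_fit_exposes_tree_and_params_roundtrip(self, toy_tree_records):
        model = DecisionTreeCEModel(method=TreatmentMethod.RA, bootstrap=False)
        params = model.get_params()
        model.set_params(**params)
        model.fit(toy_tree_records)
        assert model.n_records_ == 3
        assert model.expected_impact("QALY") > 0

    def test_bootstrap_intervals_contain_point_estimates(self, default_cohort):
        model = DecisionTreeCEModel(
            method=TreatmentMethod.RA, bootstrap=True, random_state=5
        ).fit(default_cohort)
        for _, _, d in model.tree_.graph.edges(data=True):
            assert d["lower"] - 1e-12 <= 1.0 and d["lower"] <= d["upper"]

    def test_serialization_round_trip_structures(self, toy_tree_records):
        import json

        model = DecisionTreeCEModel(method=TreatmentMethod.RA).fit(toy_tree_records)
        payload = json.loads(model.tree_.to_json())
        assert payload["method"] == "RA"
        assert len(payload["edges"]) == model.tree_.graph.number_of_edges()
        assert "digraph" in model.tree_.to_dot()
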