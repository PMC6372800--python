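"""Recognition-group partitioning, stimulation utilities, partition scoring."""

import itertools

import numpy as np
import pandas as pd
import pytest

from kinscope import (
    CompatibilityMatrix,
    PairwiseComparison,
    RecognitionGrouping,
    classify_stimulation,
    compare_partitions,
    partition_experimental,
    partition_predicted,
    stimulation_efficacy,
)


def facts_matrix(ids, compatible_pairs):
    """Build a CompatibilityMatrix directly from stated pair facts."""
    compatible_pairs = {frozenset(p) for p in compatible_pairs}
    m = CompatibilityMatrix(ids)
    for a, b in itertools.combinations_with_replacement(ids, 2):
        ok = a == b or frozenset((a, b)) in compatible_pairs
        m.put(
            PairwiseComparison(
                allele_a=a, allele_b=b,
                percent_identity=100.0 if ok else 60.0,
                aligned_length=198, n_gap_columns=0,
                switch_a="A", switch_b="A",
                compatible=ok,
                failure_reasons=() if ok else ("identity",),
            )
        )
    return m


def diagonal_table(ids):
    return pd.DataFrame(np.eye(len(ids), dtype=int), index=ids, columns=ids)


class TestPartitionPredicted:
    def test_only_self_pairs_gives_singletons(self):
        ids = [f"A_{i}" for i in range(10)]
        grouping = partition_predicted(facts_matrix(ids, []))
        assert grouping.n_groups == 10
        assert all(len(g) == 1 for g in grouping.groups.values())

    def test_planted_groups_recovered(self, default_family):
        from kinscope import predict_groups

        registry, truth = default_family
        grouping, _, _ = predict_groups(registry)
        assert grouping.partition_sets() == sorted(
            truth.partition_sets(), key=min
        )
        assert grouping.diagnostics == []

    def test_deterministic_labels_follow_smallest_member(self):
        grouping = partition_predicted(
            facts_matrix(["b", "a", "d", "c"], [("b", "a"), ("d", "c")])
        )
        assert grouping.groups["A"] == {"a", "b"}
        assert grouping.groups["B"] == {"c", "d"}

    def test_label_map_pins_published_groups(self):
        grouping = partition_predicted(
            facts_matrix(["x", "y", "z"], [("x", "y")]),
            label_map={"x": "D"},
        )
        assert grouping.groups["D"] == {"x", "y"}

    def test_non_transitive_triple_reported_not_split(self):
        m = facts_matrix(["a", "b", "c"], [("a", "b"), ("b", "c")])
        grouping = partition_predicted(m)
        assert grouping.n_groups == 1  # single linkage keeps the component
        assert len(grouping.diagnostics) == 1
        d = grouping.diagnostics[0]
        assert {d.a, d.c} == {"a", "c"} and d.b == "b"

    def test_permutation_invariance(self):
        ids = [f"A_{i}" for i in range(6)]
        pairs = [("A_0", "A_1"), ("A_2", "A_3")]
        base = partition_predicted(facts_matrix(ids, pairs)).partition_sets()
        for perm in (list(reversed(ids)), ids[3:] + ids[:3]):
            got = partition_predicted(facts_matrix(perm, pairs)).partition_sets()
            assert got == base

    def test_output_is_a_partition(self, three_group_family):
        from kinscope import predict_groups

        registry, _ = three_group_family
        grouping, _, _ = predict_groups(registry)
        members = [a for g in grouping.groups.values() for a in g]
        assert sorted(members) == sorted(registry.ids)


class TestPartitionExperimental:
    def test_diagonal_table_gives_one_group_per_allele(self):
        ids = [f"S_{i}" for i in range(10)]
        grouping = partition_experimental(diagonal_table(ids))
        assert grouping.n_groups == 10

    def test_mutual_positive_links_pair(self):
        ids = [f"S_{i}" for i in range(10)]
        table = diagonal_table(ids)
        table.loc["S_0", "S_1"] = table.loc["S_1", "S_0"] = 1
        assert partition_experimental(table).n_groups == 9

    def test_one_directional_positive_with_require_both(self):
        ids = ["S_0", "S_1"]
        table = diagonal_table(ids)
        table.loc["S_0", "S_1"] = 1
        strict = partition_experimental(table, require_both_orientations=True)
        assert strict.n_groups == 2
        assert len(strict.diagnostics) == 1  # asymmetry reported
        lenient = partition_experimental(table)
        assert lenient.n_groups == 1

    def test_untested_cells_treated_negative(self):
        ids = ["S_0", "S_1"]
        table = pd.DataFrame(
            [[1, np.nan], [np.nan, 1]], index=ids, columns=ids
        )
        assert partition_experimental(table).n_groups == 2

    def test_non_square_table_rejected(self):
        table = pd.DataFrame([[1, 0]], index=["a"], columns=["a", "b"])
        with pytest.raises(ValueError):
            partition_experimental(table)


class TestStimulation:
    @pytest.mark.parametrize(
        "d_allele,d_control,expected",
        [(5.0, 5.0, 1.0), (1.0, 4.0, 0.25), (0.0, 4.0, 0.0)],
    )
    def test_efficacy(self, d_allele, d_control, expected):
        assert stimulation_efficacy(d_allele, d_control) == expected

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            stimulation_efficacy(1.0, 0.0)

    @pytest.mark.parametrize(
        "efficacy,category",
        [
            (0.80, "wild_type"),
            (0.76, "wild_type"),
            (0.75, "weak"),  # band boundary: wild-type requires > 0.75
            (0.20, "weak"),
            (0.05, "weak"),
            (0.03, "very_weak"),
            (0.0, "none"),
        ],
    )
    def test_classification_bands(self, efficacy, category):
        assert classify_stimulation(efficacy) == category

    def test_negative_efficacy_rejected(self):
        with pytest.raises(ValueError):
            classify_stimulation(-0.1)


class TestComparePartitions:
    def grouping(self, sets):
        return RecognitionGrouping(
            groups={chr(65 + i): frozenset(s) for i, s in enumerate(sets)},
            method="predicted",
        )

    def test_identical_partitions(self):
        g = self.grouping([{"a", "b"}, {"c"}])
        res = compare_partitions(g, [{"a", "b"}, {"c"}])
        assert res["exact_match"] and res["adjusted_rand"] == 1.0

    def test_singletons_vs_one_block_ari_zero(self):
        # closed form: with one partition trivial (all singletons) the
        # expected and observed pair agreements coincide, so ARI = 0
        g = self.grouping([{"a"}, {"b"}, {"c"}, {"d"}])
        res = compare_partitions(g, [{"a", "b", "c", "d"}])
        assert not res["exact_match"]
        assert res["adjusted_rand"] == pytest.approx(0.0)

    def test_universe_mismatch_rejected(self):
        g = self.grouping([{"a"}])
        with pytest.raises(ValueError):
            compare_partitions(g, [{"a", "b"}])

    def test_planted_recovery_scores_exact(self, default_family):
        from kinscope import predict_groups

        registry, truth = default_family
        grouping, _, _ = predict_groups(registry)
        res = compare_partitions(grouping, truth.partition_sets())
        assert res["exact_match"] and res["adjusted_rand"] == 1.0
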