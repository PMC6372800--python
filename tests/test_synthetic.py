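"""Synthetic family generator: determinism, identity guarantees, recovery."""

import io

import pytest

from kinscope import (
    GenerationError,
    SCNCCP,
    SyntheticParams,
    find_scnccp,
    generate_family,
    generate_founders,
    generate_stimulation_table,
    partition_experimental,
    singleton_family,
    vd_identity,
)


def family_fasta_bytes(registry, tmp_path, name):
    path = tmp_path / name
    registry.to_fasta(path)
    return path.read_bytes()


class TestParams:
    def test_ranges_validated(self):
        with pytest.raises(ValueError):
            SyntheticParams(within_identity_range=(80.0, 100.0))  # below threshold
        with pytest.raises(ValueError):
            SyntheticParams(between_identity_range=(45.0, 96.0))  # overlaps within
        with pytest.raises(ValueError):
            SyntheticParams(between_indel_prob=1.5)

    def test_switch_states_validated(self):
        with pytest.raises(ValueError):
            SyntheticParams(n_groups=2, switch_states=("A",))
        with pytest.raises(ValueError):
            SyntheticParams(n_groups=1, switch_states=("Z",))


class TestFounders:
    def test_single_group_unconstrained(self):
        founders, switch_pos = generate_founders(SyntheticParams(n_groups=1, seed=3))
        assert len(founders) == 1
        assert len(founders[0]) == 198
        assert switch_pos == [144]

    def test_pairwise_identities_inside_between_range(self):
        params = SyntheticParams(n_groups=3, seed=4)
        founders, _ = generate_founders(params)
        lo, hi = params.between_identity_range
        for i in range(3):
            for j in range(i + 1, 3):
                pid, _, _ = vd_identity(founders[i], founders[j])
                assert lo <= pid <= hi

    def test_infeasible_range_raises(self):
        params = SyntheticParams(
            n_groups=4,
            between_identity_range=(98.0, 98.5),
            within_identity_range=(99.5, 100.0),
            max_attempts=20,
        )
        with pytest.raises(GenerationError):
            generate_founders(params)

    def test_seeded_determinism(self):
        a, _ = generate_founders(SyntheticParams(seed=9))
        b, _ = generate_founders(SyntheticParams(seed=9))
        assert a == b


class TestFamily:
    def test_family_shape_and_truth_cover(self, default_family):
        registry, truth = default_family
        assert len(registry) == 20
        assert sorted(a for g in truth.partition for a in g) == sorted(registry.ids)

    def test_every_allele_contains_scnccp_exactly_once(self, default_family):
        registry, _ = default_family
        for rec in registry:
            assert rec.sequence.count(SCNCCP) == 1
            assert find_scnccp(rec.sequence) is not None

    def test_realized_identities_inside_requested_intervals(self, default_family):
        registry, truth = default_family
        params = truth.params
        profiles = {
            rec.allele_id: rec.sequence[
                len(params.signal_stub) : len(rec.sequence) - len(params.cterm_template)
            ]
            for rec in registry
        }
        ids = list(profiles)
        lo_w, hi_w = params.within_identity_range
        lo_b, hi_b = params.between_identity_range
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                pid, _, gaps = vd_identity(profiles[a], profiles[b])
                if truth.group_of(a) == truth.group_of(b):
                    assert lo_w <= pid <= hi_w
                    assert gaps == 0
                else:
                    assert lo_b <= pid <= hi_b

    def test_byte_identical_fasta_under_fixed_seed(self, tmp_path):
        fam1, _ = generate_family(SyntheticParams(seed=21))
        fam2, _ = generate_family(SyntheticParams(seed=21))
        assert family_fasta_bytes(fam1, tmp_path, "a.faa") == family_fasta_bytes(
            fam2, tmp_path, "b.faa"
        )

    def test_narrow_within_range_still_recovered(self):
        from kinscope import compare_partitions, predict_groups

        registry, truth = generate_family(
            SyntheticParams(
                n_groups=3,
                alleles_per_group=3,
                within_identity_range=(91.0, 94.0),
                seed=31,
            )
        )
        grouping, _, _ = predict_groups(registry)
        res = compare_partitions(grouping, truth.partition_sets())
        assert res["exact_match"]

    def test_switch_only_divergence_splits_groups(self):
        """Two groups identical except for the A/P switch residue are still
        predicted as two groups, however high their identity."""
        from kinscope import predict_groups

        registry, truth = generate_family(
            SyntheticParams(
                n_groups=1, alleles_per_group=2, switch_states=("A",), seed=55
            )
        )
        recs = list(registry)
        # clone the pair with the switch flipped to P (position 205)
        from kinscope import AlleleRecord, AlleleRegistry

        merged = AlleleRegistry()
        for rec in recs:
            merged.add(rec)
            flipped = rec.sequence[:204] + "P" + rec.sequence[205:]
            merged.add(AlleleRecord(rec.allele_id + "_P", flipped))
        grouping, matrix, _ = predict_groups(merged)
        assert grouping.n_groups == 2
        cross = matrix.get(recs[0].allele_id, recs[0].allele_id + "_P")
        assert cross.percent_identity > 94.0
        assert cross.failure_reasons == ("switch",)


class TestStimulationTable:
    def test_noiseless_table_recovers_truth(self, three_group_family):
        _, truth = three_group_family
        table = generate_stimulation_table(truth)
        grouping = partition_experimental(table)
        assert {frozenset(g) for g in grouping.groups.values()} == set(
            truth.partition_sets()
        )

    def test_singleton_groups_give_diagonal_table(self):
        _, truth = singleton_family(n_alleles=10, seed=12)
        table = generate_stimulation_table(truth)
        assert (table.values.diagonal() == 1).all()
        assert table.values.sum() == 10

    def test_full_noise_inverts_table(self, three_group_family):
        _, truth = three_group_family
        clean = generate_stimulation_table(truth)
        noisy = generate_stimulation_table(truth, noise_rate=1.0)
        assert ((clean.values + noisy.values) == 1).all()
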