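import numpy as np
import pytest

from haplomark import hapgroup
from haplomark.hapgroup import GroupingParams, classify, consensus, crosstab
from haplomark.model import HET, MISSING, EmptyPanelError, PanelError, SampleMeta
from haplomark.util import percentage

from conftest import make_matrix, random_matrix


def meta_for(matrix, subpop="indica"):
    return [SampleMeta(sample_id=s, subpopulation=subpop) for s in matrix.samples]


class TestPreprocess:
    def test_missing_threshold_strictly_greater(self):
        # 150 samples; site 0 has 101 missing after het recoding, site 1 exactly 100
        n = 150
        rows = []
        for i in range(n):
            c0 = "N" if i < 95 else ("H" if i < 101 else "A")
            c1 = "N" if i < 100 else "C"
            rows.append(c0 + c1 + "G")
        m = make_matrix(rows)
        out = hapgroup.preprocess(m, GroupingParams(max_missing_per_site=100))
        assert out.site_ids == [m.site_ids[1], m.site_ids[2]]

    def test_het_recoded_to_missing(self):
        m = make_matrix(["AH", "AC"])
        out = hapgroup.preprocess(m, GroupingParams())
        assert out.row("s0").tolist() == ["A", MISSING]

    def test_identity_when_clean(self):
        m = make_matrix(["ACG", "ACT", "TCG"])
        out = hapgroup.preprocess(m, GroupingParams())
        assert np.array_equal(out.calls, m.calls)
        assert out.site_ids == m.site_ids

    def test_all_sites_removed_is_explicit_error(self):
        m = make_matrix(["NN", "NN"])
        with pytest.raises(EmptyPanelError, match="max_missing_per_site"):
            hapgroup.preprocess(m, GroupingParams(max_missing_per_site=1))

    @pytest.mark.parametrize("seed", range(10))
    def test_survivors_match_bruteforce_recount(self, seed):
        rng = np.random.default_rng(seed)
        m = random_matrix(rng, n_samples=30, n_sites=15, missing_rate=0.2, het_rate=0.15)
        threshold = 7
        out = hapgroup.preprocess(m, GroupingParams(max_missing_per_site=threshold))
        expected = []
        for j, sid in enumerate(m.site_ids):
            count = sum(1 for c in m.calls[:, j] if c in (MISSING, HET))
            if count <= threshold:
                expected.append(sid)
        assert out.site_ids == expected

    def test_fractional_threshold(self):
        m = make_matrix(["NA", "NA", "AA", "AA"])  # site 0: 2/4 missing
        out = hapgroup.preprocess(m, GroupingParams(max_missing_per_site=0.25))
        assert out.n_sites == 1


class TestGroupHaplotypes:
    def test_radius_definition(self):
        base = "AAAAAAAAAAAA"
        near = "AACAAAAAAAAT"  # Hamming 2
        far = "CCCCCCCCCCAA"  # Hamming 10
        m = make_matrix([base, base, near, far])
        cls = hapgroup.group_haplotypes(m, GroupingParams(max_mismatch=3))
        sizes = sorted(g.size for g in cls.groups)
        assert sizes == [1, 3]
        assert cls.groups[0].group_id == 1 and cls.groups[0].size == 3

    def test_consensus_vectors_merge_at_radius_zero(self, consensus_fixture):
        matrix, _ = consensus_fixture
        cls = hapgroup.group_haplotypes(
            matrix, GroupingParams(max_mismatch=0, min_overlap=1.0)
        )
        assert len(cls.groups) == 10
        merged = [g for g in cls.groups if g.size == 2]
        assert len(merged) == 1
        assert sorted(merged[0].members) == ["Hap7", "Hap9"]

    def test_simulation_recovery_zero_noise(self, small_panel):
        cfg, matrix, meta, reference, ledger = small_panel
        params = GroupingParams(min_group_fraction=0.0)
        pre = hapgroup.preprocess(matrix, params)
        cls = hapgroup.group_haplotypes(pre, params)
        mem = cls.membership()
        # every truth founder maps onto exactly one recovered group
        by_founder = {}
        for s, f in zip(ledger.samples, ledger.founder_index):
            if f >= 0:
                by_founder.setdefault(int(f), set()).add(mem[s])
        for f, labels in by_founder.items():
            assert len(labels) == 1, f"founder {f} split across {labels}"

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        m = random_matrix(rng, n_samples=25, n_sites=12, missing_rate=0.1)
        cls = hapgroup.group_haplotypes(m, GroupingParams())
        perm = list(rng.permutation(m.samples))
        cls2 = hapgroup.group_haplotypes(m.subset_samples(perm), GroupingParams())
        assert {frozenset(g.members) for g in cls.groups} == {
            frozenset(g.members) for g in cls2.groups
        }

    def test_groups_numbered_by_descending_size(self):
        rng = np.random.default_rng(11)
        m = random_matrix(rng, n_samples=40, n_sites=10, missing_rate=0.05)
        cls = hapgroup.group_haplotypes(m, GroupingParams())
        sizes = [g.size for g in cls.groups]
        assert sizes == sorted(sizes, reverse=True)
        assert [g.group_id for g in cls.groups] == list(range(1, len(sizes) + 1))


class TestLabelRare:
    def _groups_of(self, sizes):
        rows = []
        for gi, size in enumerate(sizes):
            vec = "".join("ACGT"[(gi >> (2 * k)) & 3] for k in range(10))
            rows += [vec] * size
        return make_matrix(rows, samples=[f"g{gi}_{i}" for gi, size in enumerate(sizes) for i in range(size)])

    def test_threshold_arithmetic(self):
        m = self._groups_of([60, 30, 6, 4])
        cls = hapgroup.group_haplotypes(m, GroupingParams(max_mismatch=0))
        out = hapgroup.label_rare(cls, GroupingParams(min_group_fraction=0.05), n_total=100)
        assert sorted(g.size for g in out.groups) == [6, 30, 60]
        assert len(out.rare) == 4
        assert [g.group_id for g in out.groups] == [1, 2, 3]

    def test_zero_threshold_keeps_everything(self):
        m = self._groups_of([5, 3, 1])
        cls = hapgroup.group_haplotypes(m, GroupingParams(max_mismatch=0))
        out = hapgroup.label_rare(cls, GroupingParams(min_group_fraction=0.0))
        assert not out.rare and len(out.groups) == 3

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        m = random_matrix(rng, n_samples=50, n_sites=10, missing_rate=0.05)
        cls = hapgroup.group_haplotypes(m, GroupingParams())
        previous = -1
        for frac in (0.0, 0.02, 0.05, 0.1, 0.3, 1.0):
            out = hapgroup.label_rare(cls, GroupingParams(min_group_fraction=frac))
            assert len(out.rare) >= previous
            previous = len(out.rare)

    def test_planted_recombinants_flagged(self):
        # two founders at 98 samples plus a 2-sample outlier class
        m = self._groups_of([50, 48, 2])
        cls = hapgroup.group_haplotypes(m, GroupingParams(max_mismatch=0))
        out = hapgroup.label_rare(cls, GroupingParams(min_group_fraction=0.025))
        assert len(out.rare) == 2
        assert all(s.startswith("g2_") for s in out.rare)


class TestFlagUnclassified:
    def test_all_key_sites_missing(self):
        m = make_matrix(["ACGT", "NNNN", "ACGT"])
        cls = hapgroup.group_haplotypes(m, GroupingParams(min_overlap=0.0))
        out = hapgroup.flag_unclassified(m, cls, max_missing_key=3)
        assert out.unclassified == ["s1"]

    def test_fully_called_never_unclassified(self):
        m = make_matrix(["ACGT", "ACGA"])
        cls = hapgroup.group_haplotypes(m, GroupingParams())
        out = hapgroup.flag_unclassified(m, cls, max_missing_key=0)
        assert out.unclassified == []

    def test_unknown_key_site_errors(self):
        m = make_matrix(["AC", "AC"])
        cls = hapgroup.group_haplotypes(m, GroupingParams())
        with pytest.raises(PanelError, match="unknown key sites"):
            hapgroup.flag_unclassified(m, cls, key_sites=["ChrX:1"])

    def test_forced_high_missingness_samples(self):
        from haplomark import synth_panel

        cfg = synth_panel.default_config(
            seed=3,
            subpop_sizes={"indica": 80},
            mutation_noise=0.0, het_rate=0.0, missing_rate=0.0,
            high_missing_rate=0.2,
        )
        matrix, meta, reference, ledger = synth_panel.simulate_panel(cfg)
        params = GroupingParams(min_group_fraction=0.0)
        pre = hapgroup.preprocess(matrix, GroupingParams(max_missing_per_site=matrix.n_samples))
        cls = hapgroup.group_haplotypes(pre, params)
        out = hapgroup.flag_unclassified(pre, cls, max_missing_key=int(0.4 * pre.n_sites))
        forced = {s for s, hm in zip(ledger.samples, ledger.high_missing) if hm}
        assert set(out.unclassified) == forced


class TestSubgroups:
    def test_letters_and_x(self):
        rows = ["AAAA"] * 150 + ["AAAT"] * 30 + ["AATT"] * 1
        m = make_matrix(rows, samples=[f"s{i}" for i in range(181)])
        cls = hapgroup.group_haplotypes(m, GroupingParams(max_mismatch=3))
        (group,) = cls.groups
        hapgroup.assign_subgroups(group, m, GroupingParams(min_subgroup_fraction=0.01))
        assert len(group.subgroups["A"]) == 150
        assert len(group.subgroups["B"]) == 30
        assert len(group.subgroups["X"]) == 1

    def test_single_class_is_a(self):
        m = make_matrix(["ACGT", "ACGT"])
        cls = hapgroup.group_haplotypes(m, GroupingParams())
        (group,) = cls.groups
        hapgroup.assign_subgroups(group, m, GroupingParams())
        assert list(group.subgroups) == ["A"]
        assert len(group.subgroups["A"]) == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_letters_ordered_by_class_size(self, seed):
        rng = np.random.default_rng(seed)
        m = random_matrix(rng, n_samples=60, n_sites=6, missing_rate=0.0, het_rate=0.0)
        cls = hapgroup.group_haplotypes(m, GroupingParams(max_mismatch=6, min_overlap=0.0))
        group = cls.groups[0]
        hapgroup.assign_subgroups(group, m, GroupingParams(min_subgroup_fraction=0.0))
        lettered = [(k, len(v)) for k, v in group.subgroups.items() if k != "X"]
        sizes = [n for _, n in lettered]
        assert sizes == sorted(sizes, reverse=True)  # sort oracle


class TestConsensus:
    def test_identical_members(self):
        m = make_matrix(["ACGT", "ACGT"])
        cls = hapgroup.group_haplotypes(m, GroupingParams())
        assert consensus(cls.groups[0], m) == "ACGT"

    def test_majority(self):
        m = make_matrix(["G", "G", "T"])
        cls = hapgroup.group_haplotypes(m, GroupingParams(max_mismatch=1, min_overlap=0))
        assert consensus(cls.groups[0], m) == "G"

    def test_tie_alphabetical_and_all_missing(self):
        m = make_matrix(["GN", "TN"])
        cls = hapgroup.group_haplotypes(m, GroupingParams(max_mismatch=1, min_overlap=0))
        assert consensus(cls.groups[0], m) == "G" + MISSING

    def test_noisy_group_recovers_founder(self, small_panel):
        cfg, matrix, meta, reference, ledger = small_panel
        params = GroupingParams(min_group_fraction=0.0)
        cls = hapgroup.group_haplotypes(matrix, params)
        for g in cls.groups:
            if g.size > 3:
                assert g.consensus_vector == g.founder_vector


class TestCrosstab:
    def test_margins(self):
        from conftest import classification_from_members

        cls = classification_from_members({1: ["a", "b", "c"], 2: ["d", "e"]})
        meta = [
            SampleMeta("a", "indica"), SampleMeta("b", "indica"), SampleMeta("c", "aus"),
            SampleMeta("d", "aus"), SampleMeta("e", "indica"),
        ]
        table = crosstab(cls, meta)
        assert table.loc["Total", "Total"] == 5
        assert table.loc["1", "indica"] == 2
        assert table.loc["Total", "aus"] == 2

    def test_missing_meta_errors(self):
        from conftest import classification_from_members

        cls = classification_from_members({1: ["a", "b"]})
        with pytest.raises(PanelError, match="without metadata"):
            crosstab(cls, [SampleMeta("a", "indica")])

    def test_percentage_helper_rounding(self):
        assert percentage(215, 224) == 96
        assert percentage(171, 2932, 1) == 5.8
        assert percentage(1, 200) == 1  # 0.5 rounds away from zero


class TestPartitionProperties:
    @pytest.mark.parametrize("seed", range(20))
    def test_partition_and_radius(self, seed):
        rng = np.random.default_rng(seed)
        m = random_matrix(rng, n_samples=25, n_sites=12, missing_rate=0.15, het_rate=0.1)
        params = GroupingParams(min_group_fraction=0.05, min_overlap=0.5)
        cls = classify(m, params)
        labels = cls.membership()
        assert sorted(labels) == sorted(m.samples)  # partition
        overlap_min = params.overlap_threshold(len(cls.site_ids))
        pre = hapgroup.preprocess(m, params)
        for g in cls.groups:
            founder = np.array(list(g.founder_vector))
            for s in g.members:
                row = pre.row(s)
                mism, overlap = hapgroup.masked_hamming(row, founder)
                if overlap >= overlap_min:
                    assert mism <= params.max_mismatch
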