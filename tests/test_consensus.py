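import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asdpipe import (
    GeneScoreTable,
    GeneSet,
    ThresholdRule,
    consensus_vote,
    intersect_anchor,
    shortlist,
    venn_counts,
)
from conftest import make_geneset, make_shortlist, random_sets
from oracles import consensus_by_subset_enumeration, venn_pattern_tally, vote_count


def table(scores, rule):
    return GeneScoreTable("src", scores, rule)


class TestShortlist:
    def test_ge_boundary_inclusive(self):
        sl = shortlist(table({"A": 0.95, "B": 0.90, "C": 0.89}, ThresholdRule("ge", 0.90)))
        assert sl.genes == {"A", "B"}

    def test_gt_boundary_exclusive(self):
        sl = shortlist(table({"A": 5, "B": 3, "C": 1, "D": 0, "E": -2}, ThresholdRule("gt", 0)))
        assert sl.genes == {"A", "B", "C"}

    def test_le_keeps_small_scores(self):
        sl = shortlist(table({"A": 0.01, "B": 0.05, "C": 0.2}, ThresholdRule("le", 0.05)))
        assert sl.genes == {"A", "B"}

    def test_membership_keeps_everything(self):
        sl = shortlist(table({"A": 1.0, "B": -7.0}, ThresholdRule("membership")))
        assert sl.genes == {"A", "B"}

    def test_top_fraction_matches_sort_oracle(self):
        scores = {f"G{i:02d}": float(i + 1) for i in range(20)}
        sl = shortlist(table(scores, ThresholdRule("top_fraction", 0.10)))
        # brute-force oracle: sort by (score desc, name asc), keep floor(0.1*20)
        expected = set(sorted(scores, key=lambda g: (-scores[g], g))[:2])
        assert sl.genes == expected == {"G19", "G18"}

    def test_top_fraction_tie_break_is_deterministic(self):
        scores = {"B": 1.0, "A": 1.0, "C": 1.0, "D": 0.5}
        sl = shortlist(table(scores, ThresholdRule("top_fraction", 0.5)))
        assert sl.genes == {"A", "B"}  # floor(2) kept, lexicographic among ties

    def test_top_fraction_on_empty_table_raises(self):
        with pytest.raises(ValueError):
            shortlist(table({}, ThresholdRule("top_fraction", 0.1)))

    def test_shortlist_records_input_size(self):
        sl = shortlist(table({"A": 1.0, "B": 0.0}, ThresholdRule("ge", 0.5)))
        assert sl.n_input == 2 and len(sl) == 1


class TestConsensusVote:
    def test_three_sets_k3(self):
        sls = [make_shortlist("s1", {"A", "B"}), make_shortlist("s2", {"A", "C"}),
               make_shortlist("s3", {"A"})]
        assert consensus_vote(sls, 3).consensus_genes == {"A"}

    def test_k1_is_union_and_kn_is_intersection(self, rng):
        sets = random_sets(rng, 4, 30, 100)
        sls = [make_shortlist(f"s{i}", s) for i, s in enumerate(sets)]
        assert consensus_vote(sls, 1).consensus_genes == set.union(*sets)
        assert consensus_vote(sls, 4).consensus_genes == set.intersection(*sets)

    def test_matches_subset_enumeration_oracle(self, rng):
        sets = random_sets(rng, 5, 50, 200)
        sls = [make_shortlist(f"s{i}", s) for i, s in enumerate(sets)]
        result = consensus_vote(sls, 4)
        assert result.consensus_genes == consensus_by_subset_enumeration(sets, 4)
        for gene in result.membership:
            assert result.votes[gene] == vote_count(sets, gene)

    def test_monotone_in_k(self, rng):
        sets = random_sets(rng, 5, 40, 120)
        sls = [make_shortlist(f"s{i}", s) for i, s in enumerate(sets)]
        previous = None
        for k in range(1, 6):
            current = consensus_vote(sls, k).consensus_genes
            if previous is not None:
                assert current <= previous
            previous = current

    def test_votes_equal_membership_sum(self, rng):
        sets = random_sets(rng, 3, 20, 50)
        result = consensus_vote([make_shortlist(f"s{i}", s) for i, s in enumerate(sets)], 2)
        for g, vec in result.membership.items():
            assert result.votes[g] == sum(vec) >= 1

    @pytest.mark.parametrize("k", [0, 6])
    def test_k_out_of_range(self, k, rng):
        sls = [make_shortlist(f"s{i}", s) for i, s in enumerate(random_sets(rng, 5, 10, 40))]
        with pytest.raises(ValueError):
            consensus_vote(sls, k)

    def test_needs_two_shortlists(self):
        with pytest.raises(ValueError):
            consensus_vote([make_shortlist("s", {"A"})], 1)


class TestVennCounts:
    def test_two_set_regions(self):
        vc = venn_counts([make_shortlist("s1", {"A", "B"}), make_shortlist("s2", {"B", "C"})])
        assert vc.region_counts[("s1",)] == 1
        assert vc.region_counts[("s2",)] == 1
        assert vc.region_counts[("s1", "s2")] == 1

    def test_identical_sets_fill_only_the_full_region(self):
        sls = [make_shortlist(f"s{i}", {"A", "B", "C"}) for i in range(3)]
        vc = venn_counts(sls)
        assert vc.region_counts[("s0", "s1", "s2")] == 3
        assert sum(vc.region_counts.values()) == 3

    def test_matches_pattern_tally_oracle(self, rng):
        sets = random_sets(rng, 5, 60, 150)
        sls = [make_shortlist(f"s{i}", s) for i, s in enumerate(sets)]
        vc = venn_counts(sls)
        oracle = venn_pattern_tally(sets)
        for key, count in oracle.items():
            region = tuple(f"s{i}" for i in key)
            assert vc.region_counts[region] == count
        assert vc.union_size == len(set.union(*sets))

    def test_region_count_is_2n_minus_1(self, rng):
        sets = random_sets(rng, 4, 10, 40)
        vc = venn_counts([make_shortlist(f"s{i}", s) for i, s in enumerate(sets)])
        assert len(vc.region_counts) == 2**4 - 1

    def test_more_than_six_sets_unsupported(self, rng):
        sls = [make_shortlist(f"s{i}", {"A"}) for i in range(7)]
        with pytest.raises(ValueError):
            venn_counts(sls)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.sets(st.integers(0, 40), min_size=1), min_size=2, max_size=6))
    def test_conservation_property(self, raw_sets):
        sets = [{f"G{i}" for i in s} for s in raw_sets]
        sls = [make_shortlist(f"s{i}", s) for i, s in enumerate(sets)]
        vc = venn_counts(sls)
        assert vc.union_size == len(set.union(*sets))
        assert all(c >= 0 for c in vc.region_counts.values())


class TestIntersectAnchor:
    def make_consensus(self, genes):
        sls = [make_shortlist("s1", genes), make_shortlist("s2", genes)]
        return consensus_vote(sls, 2)

    def test_plain_intersection(self):
        result = self.make_consensus({"A", "B", "C"})
        out = intersect_anchor(result, make_geneset("anchor", {"B", "C", "D"}))
        assert out.genes == {"B", "C"}

    def test_exclusions_removed(self):
        result = self.make_consensus({"A", "B", "C"})
        out = intersect_anchor(
            result, make_geneset("anchor", {"B", "C", "D"}), make_geneset("excl", {"C"})
        )
        assert out.genes == {"B"}

    def test_anchor_equal_to_consensus_is_identity(self):
        result = self.make_consensus({"A", "B"})
        out = intersect_anchor(result, make_geneset("anchor", {"A", "B"}))
        assert out.genes == result.consensus_genes

    def test_empty_result_allowed(self):
        result = self.make_consensus({"A"})
        out = intersect_anchor(result, make_geneset("anchor", {"Z"}))
        assert out.genes == frozenset()


class TestReports:
    def test_consensus_report_roundtrips_votes(self, tmp_path, rng):
        import pandas as pd

        from asdpipe import write_report

        sets = random_sets(rng, 3, 15, 40)
        result = consensus_vote([make_shortlist(f"s{i}", s) for i, s in enumerate(sets)], 2)
        path = tmp_path / "consensus.tsv"
        write_report(result, path)
        back = pd.read_csv(path, sep="\t")
        assert dict(zip(back["gene"], back["votes"])) == result.votes
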