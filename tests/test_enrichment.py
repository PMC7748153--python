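import math

import numpy as np
import pytest
from scipy.stats import hypergeom as scipy_hypergeom

from asdpipe import (
    DegStudy,
    GeneSet,
    GeneSetCollection,
    bh_fdr,
    deg_overlap_tally,
    hypergeom_tail,
    ora,
    overlap_test,
)
from asdpipe.synthetic import gen_genesets
from conftest import make_geneset
from oracles import bh_stepup, comb_tail, enum_tail


class TestHypergeomTail:
    def test_small_example_matches_draw_enumeration(self):
        # universe 10, |A|=4, |B|=5, overlap 4: only the single most extreme table
        expected = float(enum_tail(10, 4, 5, 4))
        assert hypergeom_tail(10, 4, 5, 4) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(6 / 252)

    def test_zero_overlap_is_one(self):
        assert hypergeom_tail(100, 10, 20, 0) == 1.0

    def test_degenerate_a_equals_universe(self):
        assert hypergeom_tail(10, 10, 4, 4) == pytest.approx(1.0)

    def test_matches_scipy_survival_function(self, rng):
        for _ in range(200):
            n_u = int(rng.integers(10, 2000))
            n_a = int(rng.integers(1, n_u + 1))
            n_b = int(rng.integers(1, n_u + 1))
            lo = max(0, n_a + n_b - n_u)
            k = int(rng.integers(lo, min(n_a, n_b) + 1))
            ours = hypergeom_tail(n_u, n_a, n_b, k)
            ref = float(scipy_hypergeom.sf(k - 1, n_u, n_a, n_b))
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-300)

    def test_log_space_accuracy_deep_in_tail(self):
        # overlap far beyond expectation: probability ~1e-80; exact rational oracle
        p = hypergeom_tail(20000, 100, 100, 50)
        assert p == pytest.approx(float(comb_tail(20000, 100, 100, 50)), rel=1e-9)
        assert 0 < p < 1e-60

    def test_monotone_in_overlap(self):
        values = [hypergeom_tail(500, 50, 60, k) for k in range(0, 51)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    @pytest.mark.parametrize("args", [
        (0, 0, 0, 0), (10, 11, 5, 2), (10, 4, 5, 5), (10, 8, 8, 2),
    ])
    def test_invalid_counts_rejected(self, args):
        with pytest.raises(ValueError):
            hypergeom_tail(*args)


class TestOverlapTest:
    def universe(self, n):
        return make_geneset("universe", {f"G{i:03d}" for i in range(n)})

    def test_identity_overlap(self):
        u = self.universe(20)
        r = overlap_test(u, u, u)
        assert r.n_overlap == 20 and r.jaccard == 1.0 and r.p_value <= 1.0

    def test_disjoint_sets(self):
        u = self.universe(20)
        a = make_geneset("a", {"G000", "G001"})
        b = make_geneset("b", {"G010", "G011"})
        r = overlap_test(a, b, u)
        assert r.jaccard == 0.0 and r.p_value == 1.0

    def test_out_of_universe_genes_dropped_and_counted(self):
        u = self.universe(10)
        a = make_geneset("a", {"G000", "ALIEN"})
        b = make_geneset("b", {"G000"})
        r = overlap_test(a, b, u)
        assert r.n_a == 1 and r.n_dropped_a == 1 and r.n_overlap == 1

    def test_odds_ratio_two_by_two(self):
        u = self.universe(100)
        a = make_geneset("a", {f"G{i:03d}" for i in range(10)})
        b = make_geneset("b", {f"G{i:03d}" for i in range(5, 25)})
        r = overlap_test(a, b, u)
        t11, t12, t21 = 5, 5, 15
        t22 = 100 - 10 - 20 + 5
        assert r.odds_ratio == pytest.approx(t11 * t22 / (t12 * t21))

    def test_odds_ratio_infinite_on_zero_denominator_cell(self):
        u = self.universe(10)
        a = make_geneset("a", {"G000", "G001"})
        r = overlap_test(a, a, u)
        assert math.isinf(r.odds_ratio)

    def test_random_instances_match_exact_fisher_oracle(self, rng):
        genes = [f"G{i:03d}" for i in range(500)]
        u = make_geneset("universe", genes)
        for _ in range(20):
            a = make_geneset("a", rng.choice(genes, size=60, replace=False))
            b = make_geneset("b", rng.choice(genes, size=80, replace=False))
            r = overlap_test(a, b, u)
            expected = float(comb_tail(500, r.n_a, r.n_b, r.n_overlap))
            assert r.p_value == pytest.approx(expected, rel=1e-10)
            assert r.jaccard == pytest.approx(
                r.n_overlap / (r.n_a + r.n_b - r.n_overlap)
            )

    def test_empty_universe_rejected(self):
        a = make_geneset("a", {"G1"})
        with pytest.raises(ValueError):
            overlap_test(a, a, GeneSet("universe", frozenset()))


class TestBhFdr:
    def test_hand_stepup_example(self):
        # m=3: ranks give 0.01*3/1, 0.02*3/2, 0.03*3/3 -> step-up minimum is 0.03 everywhere
        assert list(bh_fdr([0.01, 0.02, 0.03])) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.123])[0] == pytest.approx(0.123)

    def test_all_ones_stay_one(self):
        assert list(bh_fdr([1.0, 1.0, 1.0])) == [1.0, 1.0, 1.0]

    def test_empty_input(self):
        assert bh_fdr([]).size == 0

    def test_matches_loop_oracle_and_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.random(int(rng.integers(1, 60)))
            ours = bh_fdr(p)
            assert list(ours) == pytest.approx(bh_stepup(list(p)), rel=1e-12)
            ref = multipletests(p, method="fdr_bh")[1]
            assert list(ours) == pytest.approx(list(ref), rel=1e-12)

    def test_preserves_rank_order(self, rng):
        p = rng.random(50)
        adj = bh_fdr(p)
        order = np.argsort(p, kind="stable")
        assert all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestOra:
    def setup_collection(self):
        genes = [f"G{i:03d}" for i in range(100)]
        universe = make_geneset("universe", genes)
        query = make_geneset("query", genes[:20])
        terms = GeneSetCollection([
            make_geneset("match", genes[:20]),
            make_geneset("other1", genes[40:60]),
            make_geneset("other2", genes[60:80]),
        ])
        return query, terms, universe

    def test_exact_match_term_ranks_first(self):
        query, terms, universe = self.setup_collection()
        res = ora(query, terms, universe, top_k=50)
        assert res.results[0].set_a == "match"
        assert res.results[0].fdr < 0.05

    def test_top_k_truncates_but_fdr_uses_all_terms(self):
        query, terms, universe = self.setup_collection()
        res = ora(query, terms, universe, top_k=1)
        assert len(res.results) == 1 and res.n_terms_tested == 3

    def test_top_k_larger_than_terms_returns_all(self):
        query, terms, universe = self.setup_collection()
        assert len(ora(query, terms, universe, top_k=99).results) == 3

    def test_tie_break_is_lexicographic(self):
        genes = [f"G{i:03d}" for i in range(50)]
        universe = make_geneset("universe", genes)
        query = make_geneset("query", genes[:10])
        terms = GeneSetCollection([
            make_geneset("zeta", genes[20:30]),
            make_geneset("alpha", genes[30:40]),
        ])
        res = ora(query, terms, universe)
        assert [r.set_a for r in res.results] == ["alpha", "zeta"]

    def test_planted_term_recovered(self):
        genes = [f"G{i:03d}" for i in range(400)]
        universe = make_geneset("universe", genes)
        query = make_geneset("query", genes[:50])
        terms, truth = gen_genesets(
            n_terms=12, term_size_range=(30, 60), universe=universe,
            planted_term_genes=query, enrichment_odds=10.0, seed=11,
        )
        res = ora(query, terms, universe, top_k=1)
        assert res.results[0].set_a in truth.planted_enriched_terms

    def test_empty_collection_rejected(self):
        query, _, universe = self.setup_collection()
        with pytest.raises(ValueError):
            ora(query, GeneSetCollection([]), universe)


class TestDegOverlap:
    def test_small_example(self):
        query = make_geneset("q", {"A", "B", "C"})
        study = DegStudy("s1", make_geneset("u", {"A"}), make_geneset("d", {"B"}))
        tally = deg_overlap_tally(query, [study])
        assert tally.rows[0] == {"study": "s1", "overlap": 2, "up": 1, "down": 1}
        assert tally.union_count == 2

    def test_no_studies(self):
        tally = deg_overlap_tally(make_geneset("q", {"A"}), [])
        assert tally.union_count == 0 and tally.rows == []

    def test_gene_in_both_directions_counted_once_in_overlap(self):
        query = make_geneset("q", {"A"})
        study = DegStudy("s", make_geneset("u", {"A"}), make_geneset("d", {"A"}))
        tally = deg_overlap_tally(query, [study])
        assert tally.rows[0]["overlap"] == 1
        assert tally.rows[0]["up"] == 1 and tally.rows[0]["down"] == 1

    def test_random_instance_matches_set_union_oracle(self, rng):
        genes = [f"G{i:03d}" for i in range(200)]
        query = make_geneset("q", rng.choice(genes, 50, replace=False))
        studies = [
            DegStudy(
                f"s{i}",
                make_geneset("u", rng.choice(genes, 30, replace=False)),
                make_geneset("d", rng.choice(genes, 30, replace=False)),
            )
            for i in range(5)
        ]
        tally = deg_overlap_tally(query, studies)
        # brute-force oracle
        seen = set()
        for i, s in enumerate(studies):
            both = s.up.genes | s.down.genes
            assert tally.rows[i]["overlap"] == len(query.genes & both)
            assert tally.rows[i]["up"] == len(query.genes & s.up.genes)
            assert tally.rows[i]["down"] == len(query.genes & s.down.genes)
            seen |= query.genes & both
        assert tally.union_count == len(seen)
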