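"""Tissue merging, network comparison, enrichment and clustering."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from csnets.downstream import (
    DifferentialNetwork,
    differential_network,
    degree_summary,
    enrichment_score,
    fisher_go_enrichment,
    hclust_average,
    merge_tissue,
    network_jaccard,
    rank_differential_targets,
    rank_set_enrichment,
    tf_target_jaccard_distance,
)
from csnets.preliminary import CellLineNetwork, RegulatoryEdge


def net(cell_line, edges):
    return CellLineNetwork.from_edges(
        cell_line,
        {
            RegulatoryEdge(tf_id=tf, gene_id=g, cell_line=cell_line, probability=0.9)
            for tf, g in edges
        },
    )


class TestTissueMerge:
    def test_union_with_support_counts(self):
        merged = merge_tissue(
            [net("A", {("T", "g1"), ("T", "g2")}), net("B", {("T", "g2"), ("T", "g3")})]
        )
        assert merged.edges == {("T", "g1"), ("T", "g2"), ("T", "g3")}
        assert merged.support[("T", "g2")] == 2 and merged.support[("T", "g1")] == 1

    def test_single_network_is_identity(self):
        merged = merge_tissue([net("A", {("T", "g1")})])
        assert merged.edges == {("T", "g1")}

    def test_disjoint_networks_sum_sizes(self):
        merged = merge_tissue([net("A", {("T", "g1")}), net("B", {("U", "g2")})])
        assert len(merged.edges) == 2


class TestDegreeSummary:
    def test_complete_bipartite(self):
        edges = {(f"T{i}", f"g{j}") for i in range(2) for j in range(10)}
        n_nodes, n_edges, mean_in, mean_out = degree_summary(merge_tissue([net("A", edges)]))
        assert (n_nodes, n_edges) == (12, 20)
        assert mean_in == 2.0 and mean_out == 10.0

    def test_single_edge(self):
        _, _, mean_in, mean_out = degree_summary(merge_tissue([net("A", {("T", "g")})]))
        assert mean_in == 1.0 and mean_out == 1.0

    def test_star(self):
        edges = {("T", f"g{j}") for j in range(7)}
        _, _, mean_in, mean_out = degree_summary(merge_tissue([net("A", edges)]))
        assert mean_in == 1.0 and mean_out == 7.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            degree_summary(merge_tissue([net("A", set())]))


class TestJaccard:
    def test_edge_set_examples(self):
        assert network_jaccard({("T", "a")}, {("T", "a")}) == 1.0
        assert network_jaccard({("T", "a")}, {("T", "b")}) == 0.0
        assert network_jaccard({("T", "a"), ("T", "b")}, {("T", "b"), ("T", "c")}) == pytest.approx(1 / 3)
        assert network_jaccard(set(), set()) == 0.0

    def test_tf_target_distance_examples(self):
        assert tf_target_jaccard_distance({"g1"}, {"g1"}) == (0.0, 0)
        assert tf_target_jaccard_distance({"g1"}, {"g2"}) == (1.0, 2)
        d, count = tf_target_jaccard_distance({"g1", "g2"}, {"g2", "g3"})
        assert d == pytest.approx(2 / 3) and count == 2

    def test_distance_triangle_inequality_on_random_triples(self):
        rng = np.random.default_rng(0)
        universe = list(range(12))
        for _ in range(200):
            a, b, c = (
                {x for x in universe if rng.random() < 0.5} or {0} for _ in range(3)
            )
            dab = tf_target_jaccard_distance(a, b)[0]
            dbc = tf_target_jaccard_distance(b, c)[0]
            dac = tf_target_jaccard_distance(a, c)[0]
            assert dac <= dab + dbc + 1e-12

    def test_both_empty_undefined(self):
        with pytest.raises(ValueError):
            tf_target_jaccard_distance(set(), set())


class TestDifferentialNetwork:
    def test_symmetric_difference_and_counts(self):
        a = net("A", {("T1", "g1"), ("T1", "g2"), ("T2", "g1")})
        b = net("B", {("T1", "g2"), ("T2", "g3")})
        diff = differential_network(a, b)
        assert diff.edges == {("T1", "g1"), ("T2", "g1"), ("T2", "g3")}
        assert diff.per_tf_counts == {"T1": 1, "T2": 2}
        assert not (diff.edges & ({("T1", "g2")}))

    def test_rank_by_differential_in_degree_with_id_ties(self):
        diff = DifferentialNetwork(
            "A", "B", edges=set(), per_gene_counts={"g2": 3, "g1": 2, "g3": 3}
        )
        assert rank_differential_targets(diff) == [("g2", 3), ("g3", 3), ("g1", 2)]

    def test_empty_differential_ranks_empty(self):
        assert rank_differential_targets(DifferentialNetwork("A", "B", set())) == []


def hypergeom_tail_oracle(a, b, c, d):
    """P(X >= a) for X ~ Hypergeom(N, a+b draws, a+c successes), exact rationals."""
    n_total = a + b + c + d
    draws, successes = a + b, a + c
    denom = comb(n_total, draws)
    p = Fraction(0)
    for x in range(a, min(draws, successes) + 1):
        p += Fraction(comb(successes, x) * comb(n_total - successes, draws - x), denom)
    return float(p)


class TestFisherEnrichment:
    def test_matches_hypergeometric_oracle_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            a, b, c, d = (int(x) for x in rng.integers(0, 50, size=4))
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            universe = {f"g{i}" for i in range(a + b + c + d)}
            ordered = sorted(universe)
            targets = set(ordered[: a + b])
            term = set(ordered[:a]) | set(ordered[a + b : a + b + c])
            test = fisher_go_enrichment(targets, term, universe)
            assert test.p == pytest.approx(hypergeom_tail_oracle(a, b, c, d), abs=1e-10)

    def test_specific_table(self):
        # 2x2 = (5, 5, 5, 85) in a universe of 100
        universe = {f"g{i}" for i in range(100)}
        ordered = sorted(universe)
        targets = set(ordered[:10])
        term = set(ordered[:5]) | set(ordered[10:15])
        test = fisher_go_enrichment(targets, term, universe)
        assert test.table == (5, 5, 5, 85)
        assert test.p == pytest.approx(hypergeom_tail_oracle(5, 5, 5, 85), abs=1e-10)

    def test_disjoint_sets_give_p_one_region(self):
        universe = {f"g{i}" for i in range(10)}
        test = fisher_go_enrichment({"g0", "g1"}, {"g5", "g6"}, universe)
        assert test.p == pytest.approx(hypergeom_tail_oracle(0, 2, 2, 6), abs=1e-10)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            fisher_go_enrichment(set(), set(), set())


class TestEnrichmentScore:
    def make_tests(self, pvals):
        from csnets.downstream import EnrichmentTest

        return [
            EnrichmentTest("T", "grp", f"GO:{i}", (1, 1, 1, 1), 1.0, p)
            for i, p in enumerate(pvals)
        ]

    def test_all_tiny_pvalues_give_one(self):
        assert enrichment_score(self.make_tests([1e-10] * 5)) == 1.0

    def test_all_unit_pvalues_give_zero(self):
        assert enrichment_score(self.make_tests([1.0] * 5)) == 0.0

    def test_bh_step_up_hand_case(self):
        # BH at q=0.2 on (0.01, 0.02, 0.04, 0.9): largest k with p_(k) <= 0.2*k/4
        # is k=3 (0.04 <= 0.15), so 3 of 4 significant
        tests = self.make_tests([0.01, 0.02, 0.04, 0.9])
        assert enrichment_score(tests, fdr=0.2) == 0.75
        assert [t.fdr_significant for t in tests] == [True, True, True, False]

    def test_invariant_to_test_ordering(self):
        pvals = [0.01, 0.5, 0.03, 0.9, 0.002]
        assert enrichment_score(self.make_tests(pvals)) == enrichment_score(
            self.make_tests(pvals[::-1])
        )

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            enrichment_score([])


class TestRankSetEnrichment:
    def test_target_set_at_top_is_maximally_enriched(self):
        scores = {f"g{i}": float(100 - i) for i in range(100)}
        es, p = rank_set_enrichment(scores, {f"g{i}" for i in range(10)}, n_perm=200, seed=0)
        assert es > 0.8 and p <= 1 / 201 + 1e-12

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(11)
        scores = {f"g{i}": float(v) for i, v in enumerate(rng.normal(size=80))}
        ps = []
        for rep in range(60):
            targets = set(rng.choice(sorted(scores), size=10, replace=False))
            _, p = rank_set_enrichment(scores, targets, n_perm=100, seed=rep)
            ps.append(p)
        assert 0.35 < np.mean(ps) < 0.65

    def test_all_equal_scores_give_near_zero_es(self):
        scores = {f"g{i}": 1.0 for i in range(50)}
        es, _ = rank_set_enrichment(scores, {f"g{i}" for i in range(5)}, n_perm=100, seed=0)
        assert es <= 0.2

    def test_empty_target_set_rejected(self):
        with pytest.raises(ValueError):
            rank_set_enrichment({"g": 1.0}, set(), n_perm=100, seed=0)


class TestHclust:
    def test_two_items_path_length_equals_their_distance(self):
        nwk = hclust_average(np.array([[0.0, 0.4], [0.4, 0.0]]), ["a", "b"])
        assert nwk == "(a:0.2,b:0.2);"

    def test_first_split_separates_well_separated_blocks(self):
        d = np.full((4, 4), 0.9)
        d[0, 1] = d[1, 0] = 0.1
        d[2, 3] = d[3, 2] = 0.1
        np.fill_diagonal(d, 0.0)
        nwk = hclust_average(d, ["a1", "a2", "b1", "b2"])
        # each block must appear as a sibling pair
        assert ("a1:0.05,a2:0.05" in nwk or "a2:0.05,a1:0.05" in nwk)
        assert ("b1:0.05,b2:0.05" in nwk or "b2:0.05,b1:0.05" in nwk)

    def test_identical_items_join_at_zero_height(self):
        d = np.zeros((2, 2))
        nwk = hclust_average(d, ["x", "y"])
        assert nwk == "(x:0,y:0);"

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 0.5], [0.4, 0.0]])
        with pytest.raises(ValueError):
            hclust_average(d, ["a", "b"])
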