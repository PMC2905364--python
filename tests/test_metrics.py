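import numpy as np
import pytest

import dendropy

from gigatree.genetree import DUPLICATION, GeneNode, GeneTree, LEAF, SPECIATION, parse_gene_tree
from gigatree.metrics import (
    bipartitions,
    extract_ortholog_pairs,
    ortholog_pair_difference,
    rf_distance,
    robustness_compare,
)

from conftest import brute_ortholog_pairs, brute_rf, random_event_tree


def leaf(label):
    return GeneNode(LEAF, label, label.rsplit("_", 1)[1])


def P(a, b):
    return frozenset((a, b))


class TestOrthologPairs:
    def test_two_cherries_under_duplication(self):
        tree = GeneTree(
            GeneNode(
                DUPLICATION,
                children=[
                    GeneNode(SPECIATION, children=[leaf("h1_HUM"), leaf("m1_MOU")]),
                    GeneNode(SPECIATION, children=[leaf("h2_HUM"), leaf("m2_MOU")]),
                ],
            )
        )
        assert extract_ortholog_pairs(tree) == {
            P("h1_HUM", "m1_MOU"),
            P("h2_HUM", "m2_MOU"),
        }

    def test_all_speciation_tree_gives_all_pairs(self):
        tree = GeneTree(
            GeneNode(
                SPECIATION,
                children=[
                    leaf("a_S1"),
                    GeneNode(SPECIATION, children=[leaf("b_S2"), leaf("c_S3")]),
                ],
            )
        )
        assert extract_ortholog_pairs(tree) == {
            P("a_S1", "b_S2"),
            P("a_S1", "c_S3"),
            P("b_S2", "c_S3"),
        }

    def test_pair_under_duplication_is_empty(self):
        tree = GeneTree(GeneNode(DUPLICATION, children=[leaf("a_S1"), leaf("b_S1")]))
        assert extract_ortholog_pairs(tree) == set()

    def test_unresolved_root_pairs_excluded(self):
        tree = GeneTree(
            GeneNode(
                "unresolved",
                children=[
                    leaf("a_S1"),
                    GeneNode(SPECIATION, children=[leaf("b_S2"), leaf("c_S3")]),
                ],
            )
        )
        assert extract_ortholog_pairs(tree) == {P("b_S2", "c_S3")}

    def test_same_species_under_speciation_rejected(self):
        tree = GeneTree(GeneNode(SPECIATION, children=[leaf("a_S1"), leaf("b_S1")]))
        with pytest.raises(ValueError, match="S1"):
            extract_ortholog_pairs(tree)

    def test_matches_bruteforce_on_random_trees(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            tree = random_event_tree(rng, int(rng.integers(2, 13)))
            assert extract_ortholog_pairs(tree) == brute_ortholog_pairs(tree)


class TestOrthologPairDifference:
    def test_identical_sets(self):
        s = {P("a", "b"), P("c", "d")}
        assert ortholog_pair_difference(s, set(s)) == 0.0

    def test_disjoint_sets(self):
        assert ortholog_pair_difference({P("a", "b")}, {P("c", "d")}) == 1.0

    def test_half_overlap(self):
        a = {P("h1", "m1"), P("h2", "m2")}
        assert ortholog_pair_difference(a, {P("h1", "m1")}) == 0.5

    def test_both_empty_defined_zero(self):
        assert ortholog_pair_difference(set(), set()) == 0.0

    def test_bounded_symmetric(self):
        rng = np.random.default_rng(1)
        universe = [P(f"g{i}", f"g{j}") for i in range(6) for j in range(i)]
        for _ in range(50):
            a = {p for p in universe if rng.random() < 0.4}
            b = {p for p in universe if rng.random() < 0.4}
            d_ab = ortholog_pair_difference(a, b)
            assert d_ab == ortholog_pair_difference(b, a)
            assert 0.0 <= d_ab <= 1.0
            assert (d_ab == 0.0) == (a == b)


class TestRfDistance:
    def test_identical_trees(self):
        t = parse_gene_tree("((a_S1,b_S2),(c_S3,d_S4));")
        assert rf_distance(t, t) == 0.0

    def test_conflicting_quartets(self):
        t1 = parse_gene_tree("((a_S1,b_S2),(c_S3,d_S4));")
        t2 = parse_gene_tree("((a_S1,c_S3),(b_S2,d_S4));")
        assert rf_distance(t1, t2) == 1.0

    def test_collapsed_edge_strictly_between(self):
        t1 = parse_gene_tree("(((a_S1,b_S2),c_S3),(d_S4,e_S5));")
        t2 = parse_gene_tree("((a_S1,b_S2,c_S3),(d_S4,e_S5));")
        assert 0.0 < rf_distance(t1, t2) < 1.0

    def test_leaf_mismatch_rejected(self):
        t1 = parse_gene_tree("((a_S1,b_S2),c_S3);")
        t2 = parse_gene_tree("((a_S1,b_S2),d_S4);")
        with pytest.raises(ValueError, match="leaf"):
            rf_distance(t1, t2)

    def test_matches_bruteforce_on_random_tree_pairs(self):
        rng = np.random.default_rng(2)
        for _ in range(60):
            n = int(rng.integers(3, 11))
            labels = [f"x{i}_SP{i:02d}" for i in range(n)]
            t1 = random_event_tree(rng, n, labels)
            t2 = random_event_tree(rng, n, labels)
            assert rf_distance(t1, t2) == brute_rf(t1, t2)

    def test_raw_count_matches_dendropy_on_binary_trees(self):
        rng = np.random.default_rng(3)
        taxa = dendropy.TaxonNamespace()
        for _ in range(25):
            n = int(rng.integers(4, 10))
            labels = [f"x{i}_SP{i:02d}" for i in range(n)]
            t1 = random_event_tree(rng, n, labels)
            t2 = random_event_tree(rng, n, labels)
            d1 = dendropy.Tree.get(
                data=t1.to_newick(nhx=False, branch_lengths=False),
                schema="newick",
                taxon_namespace=taxa,
                preserve_underscores=True,
            )
            d2 = dendropy.Tree.get(
                data=t2.to_newick(nhx=False, branch_lengths=False),
                schema="newick",
                taxon_namespace=taxa,
                preserve_underscores=True,
            )
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            expected = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
            mine = len(bipartitions(t1) ^ bipartitions(t2))
            assert mine == expected


class TestRobustness:
    def test_extra_cherry_leaf_is_invisible_after_restriction(self):
        clean = parse_gene_tree("((a_S1,b_S2),(c_S3,d_S4));")
        full = parse_gene_tree("((a_S1,(b_S2,b2_S9)),(c_S3,d_S4));")
        assert robustness_compare(full, clean) == 0.0

    def test_unrelated_topologies(self):
        clean = parse_gene_tree("((a_S1,b_S2),(c_S3,d_S4));")
        full = parse_gene_tree("(((a_S1,c_S3),(b_S2,d_S4)),e_S5);")
        assert robustness_compare(full, clean) == 1.0
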