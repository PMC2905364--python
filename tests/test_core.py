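import numpy as np
import pytest

from gigatree.alignment import compute_weights, pairwise_distances, trim_alignment
from gigatree.benchmarks import congruence_trial, determinism_trial
from gigatree.config import GigaConfig
from gigatree.core import (
    GigaError,
    RevisionEvidence,
    fragment_test,
    revision_test,
    run_giga,
)
from gigatree.genetree import DUPLICATION, SPECIATION
from gigatree.pipeline import infer_gene_tree
from gigatree.simulate import SimulationConfig, random_species_tree, simulate_family


from conftest import make_alignment


def infer(records, sptree, cfg=GigaConfig()):
    aln = make_alignment(records)
    trimmed = trim_alignment(aln, compute_weights(aln), cfg)
    return run_giga(trimmed, pairwise_distances(trimmed), sptree, cfg)


BASE = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY"


def mutated(base: str, positions: list[int]) -> str:
    aas = "ACDEFGHIKLMNPQRSTVWY"
    out = list(base)
    for pos in positions:
        out[pos] = aas[(aas.index(out[pos]) + 1) % 20]
    return "".join(out)


class TestSimpleMerges:
    def test_three_orthologs_follow_species_tree(self, basic_sptree):
        res = infer(
            {
                "A_HUMAN": mutated(BASE, [0]),
                "B_MOUSE": mutated(BASE, [1]),
                "C_YEAST": mutated(BASE, [10, 11, 12, 13]),
            },
            basic_sptree,
        )
        nwk = res.tree.to_newick(branch_lengths=False, nhx=False)
        assert nwk == "((A_HUMAN,B_MOUSE),C_YEAST);"
        assert all(
            n.kind == SPECIATION for n in res.tree.internal_nodes()
        )

    def test_accelerated_lineage_still_placed_by_species_tree(
        self, opisthokont_tree
    ):
        """A fast-evolving fungal ortholog joins last but is still placed
        inside the opisthokonts, not as an outgroup: the species-tree
        constraint overrides the join order."""
        res = infer(
            {
                "m1_HUMAN": mutated(BASE, [0]),
                "m2_MOUSE": mutated(BASE, [1]),
                "d1_DICDI": mutated(BASE, [10, 11, 12, 13, 14, 15]),
                # yeast farthest from everything (accelerated), no paralogs
                "y1_YEAST": mutated(BASE, list(range(20, 40))),
            },
            opisthokont_tree,
        )
        assert res.tree.to_newick(branch_lengths=False, nhx=False) == (
            "(((m1_HUMAN,m2_MOUSE),y1_YEAST),d1_DICDI);"
        )
        assert not [
            n for n in res.tree.internal_nodes() if n.kind == DUPLICATION
        ]

    def test_fungal_paralogs_duplication_at_fungal_ancestor(
        self, opisthokont_tree
    ):
        """Two yeast+pombe groups joined to a metazoan-containing group:
        the duplication is placed immediately prior to the fungal MRCA."""
        res = infer(
            {
                "m1_HUMAN": mutated(BASE, [0]),
                "m2_MOUSE": mutated(BASE, [1]),
                "y1_YEAST": mutated(BASE, [5, 6]),
                "s1_SCHPO": mutated(BASE, [5, 7]),
                # second fungal copy: distant from everyone, cohesive pair
                "y2_YEAST": mutated(BASE, list(range(30, 50)) + [55]),
                "s2_SCHPO": mutated(BASE, list(range(30, 50)) + [56]),
            },
            opisthokont_tree,
        )
        dups = [n for n in res.tree.internal_nodes() if n.kind == DUPLICATION]
        assert len(dups) == 1
        assert dups[0].species_label == "fungi"
        assert {leaf.label for leaf in dups[0].leaves()} == {
            "y1_YEAST",
            "s1_SCHPO",
            "y2_YEAST",
            "s2_SCHPO",
        }

    def test_missing_species_rejected(self, basic_sptree):
        with pytest.raises(GigaError, match="A_WORM"):
            infer({"A_WORM": BASE, "B_MOUSE": BASE}, basic_sptree)


class TestRevisionTest:
    def ev(self, d1, d2, sd=0.01):
        return RevisionEvidence(dist1=d1, std_dev1=sd, dist2=d2, std_dev2=sd)

    def test_equal_distances_fail_both_multipliers(self):
        ev = self.ev(0.2, 0.2)
        assert not revision_test(ev, alternative_implies_duplication=True)
        assert not revision_test(ev, alternative_implies_duplication=False)

    def test_two_sd_margin_passes_duplication_alternative(self):
        # joining group is closer to the dated group by 2*(sd1+sd2)
        ev = self.ev(0.2, 0.2 + 2 * 0.02)
        assert revision_test(ev, alternative_implies_duplication=True)

    def test_one_sd_margin_fails_orthology_alternative(self):
        ev = self.ev(0.2, 0.2 + 1.0 * 0.02)
        assert not revision_test(ev, alternative_implies_duplication=False)

    def test_literal_sign_flips_orientation(self):
        cfg = GigaConfig(revision_literal_sign=True)
        ev = self.ev(0.2 + 2 * 0.02, 0.2)
        assert revision_test(ev, True, cfg)
        assert not revision_test(ev, True)


class TestFragmentTest:
    def matrix(self, n_full=4, length=100, coverage=45):
        rows = np.zeros((n_full + 1, length), dtype=np.int8)
        rows[-1, coverage:] = -1
        return rows

    def test_low_coverage_is_fragment(self):
        mat = self.matrix(coverage=45)
        assert fragment_test(4, [0, 1, 2, 3, 4], mat, candidate_os_size=1)

    def test_high_coverage_is_not_fragment(self):
        mat = self.matrix(coverage=80)
        assert not fragment_test(4, [0, 1, 2, 3, 4], mat, candidate_os_size=1)

    def test_exact_half_coverage_is_fragment(self):
        mat = self.matrix(coverage=50)
        assert fragment_test(4, [0, 1, 2, 3, 4], mat, candidate_os_size=1)

    def test_large_os_exempts_candidate(self):
        mat = self.matrix(coverage=10)
        assert not fragment_test(4, [0, 1, 2, 3, 4], mat, candidate_os_size=4)


class TestFragmentsEndToEnd:
    @pytest.fixture
    def family_with_fragment(self):
        rng = np.random.default_rng(4)
        sptree, heights = random_species_tree(10, rng)
        fam = simulate_family(
            SimulationConfig(
                species_tree=sptree, heights=heights, sequence_length=150, seed=9
            )
        )
        frag = fam.alignment.ids[3]
        from gigatree.simulate import plant_fragment

        return sptree, plant_fragment(fam, frag, 0.6), frag

    def test_fragment_quarantined_then_reinserted(self, family_with_fragment):
        sptree, fam, frag = family_with_fragment
        res = infer_gene_tree(fam.alignment, sptree, with_branch_lengths=False)
        assert res.quarantined == [frag]
        assert res.discarded == []
        assert frag in res.tree.leaf_labels()
        actions = [e.action for e in res.events if e.seq1 == frag]
        assert "quarantine" in actions and "reinsert" in actions

    def test_leaf_conservation(self, family_with_fragment):
        sptree, fam, _ = family_with_fragment
        res = infer_gene_tree(fam.alignment, sptree, with_branch_lengths=False)
        assert res.tree.leaf_labels() | set(res.discarded) == set(fam.alignment.ids)


class TestInvariants:
    def test_duplication_free_congruence(self):
        assert all(congruence_trial(seed) for seed in range(8))

    def test_determinism(self):
        assert determinism_trial(0)

    def test_fce_revisions_only_move_rootward(self):
        found = 0
        for seed in range(25):
            rng = np.random.default_rng(seed)
            sptree, heights = random_species_tree(10, rng)
            fam = simulate_family(
                SimulationConfig(
                    species_tree=sptree,
                    heights=heights,
                    duplication_rate=0.25,
                    sequence_length=250,
                    seed=seed + 1000,
                )
            )
            res = infer_gene_tree(fam.alignment, sptree, with_branch_lengths=False)
            labels = {n.label: n for n in sptree.nodes}
            for event in res.events:
                if event.action == "revise-fce":
                    old, new = event.detail.split(";")[0].split("->")
                    assert sptree.is_ancestor_or_self(labels[new], labels[old])
                    found += 1
        assert found > 0, "no revisions exercised; fixture too easy"

    def test_paralogous_family_keeps_all_leaves(self):
        rng = np.random.default_rng(5)
        sptree, heights = random_species_tree(9, rng)
        fam = simulate_family(
            SimulationConfig(
                species_tree=sptree,
                heights=heights,
                duplication_rate=0.3,
                loss_probability=0.1,
                sequence_length=200,
                seed=77,
            )
        )
        res = infer_gene_tree(fam.alignment, sptree, with_branch_lengths=False)
        assert res.tree.leaf_labels() | set(res.discarded) == set(fam.alignment.ids)
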