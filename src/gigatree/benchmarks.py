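"""Evaluation protocols on synthetic families.

Each trial simulates a family under stated conditions, runs the full
inference, and scores one property: congruence with the species tree on
duplication-free families, recovery of a planted duplication's placement,
the deletion-parsimony dating bias, fragment quarantine and re-insertion,
robustness to taxon deletion, and byte-level determinism. These are the
protocols behind both the test suite and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import FamilyAlignment
from .core import GigaResult
from .genetree import DUPLICATION, GeneNode, GeneTree, LEAF, SPECIATION
from .metrics import extract_ortholog_pairs, rf_distance
from .pipeline import infer_gene_tree
from .simulate import (
    SimulationConfig,
    plant_fragment,
    random_species_tree,
    simulate_family,
)
from .species_tree import SpeciesNode, SpeciesTree

__all__ = [
    "species_restriction_tree",
    "subset_alignment",
    "congruence_trial",
    "placement_trial",
    "bias_trial",
    "BiasOutcome",
    "rule2_audit",
    "fragment_trial",
    "robustness_trial",
    "determinism_trial",
]


def species_restriction_tree(
    sptree: SpeciesTree, leaf_of_species: dict[str, str]
) -> GeneTree:
    """The species tree restricted to the given species, with leaves renamed
    to the corresponding gene ids — the expected topology for a family with
    one gene per species and no duplications."""

    def build(node: SpeciesNode) -> GeneNode | None:
        if node.is_leaf:
            gene = leaf_of_species.get(node.label)
            return None if gene is None else GeneNode(LEAF, gene, node.label)
        kids = [k for k in (build(c) for c in node.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        return GeneNode(SPECIATION, species_label=node.label, children=kids)

    root = build(sptree.root)
    if root is None:
        raise ValueError("no species in common")
    return GeneTree(root)


def subset_alignment(aln: FamilyAlignment, keep_ids: list[str]) -> FamilyAlignment:
    index = {sid: k for k, sid in enumerate(aln.ids)}
    rows = [index[sid] for sid in keep_ids]
    return FamilyAlignment(
        [aln.ids[r] for r in rows],
        [aln.species[r] for r in rows],
        [aln.sequences[r] for r in rows],
    )


def _sub_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def congruence_trial(
    seed: int, n_taxa: tuple[int, int] = (10, 20), sites: int = 300
) -> bool:
    """Duplication-free clock family: is the inferred tree exactly the
    species-tree restriction (normalized RF = 0)?"""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_taxa[0], n_taxa[1] + 1))
    sptree, heights = random_species_tree(n, rng)
    fam = simulate_family(
        SimulationConfig(
            species_tree=sptree,
            heights=heights,
            sequence_length=sites,
            seed=_sub_seed(rng),
        )
    )
    result = infer_gene_tree(fam.alignment, sptree, with_branch_lengths=False)
    expected = species_restriction_tree(
        sptree, dict(zip(fam.alignment.species, fam.alignment.ids))
    )
    return rf_distance(result.tree, expected) == 0.0 and rule2_audit(result)


def placement_trial(
    seed: int, n_taxa: tuple[int, int] = (8, 13), sites: int = 300
) -> bool:
    """Plant one duplication on the longest internal edge (so the event is
    identifiable at the given sequence length), zero loss, clock rates: is
    the inferred placement exactly the true edge?"""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_taxa[0], n_taxa[1] + 1))
    sptree, heights = random_species_tree(n, rng)
    internal = [nd for nd in sptree.nodes if not nd.is_leaf and nd.parent is not None]
    target = max(
        internal, key=lambda nd: heights[nd.parent.label] - heights[nd.label]
    )
    fam = simulate_family(
        SimulationConfig(
            species_tree=sptree,
            heights=heights,
            sequence_length=sites,
            forced_duplications=(target.label,),
            seed=_sub_seed(rng),
        )
    )
    result = infer_gene_tree(fam.alignment, sptree, with_branch_lengths=False)
    return (
        result.duplication_placements() == [target.label]
        and fam.true_placements == [target.label]
        and rule2_audit(result)
    )


@dataclass
class BiasOutcome:
    true_placement: str
    expected_biased_placement: str
    inferred_placements: list[str]

    @property
    def reproduces_bias(self) -> bool:
        return self.inferred_placements == [self.expected_biased_placement]


def bias_trial(seed: int = 17) -> BiasOutcome:
    """Duplication followed by a loss immediately below it.

    The true event sits on the edge into the (ALPHA,BRAVO,CHARL) clade, but
    one copy is deleted in CHARL, so the extant second-copy evidence only
    spans (ALPHA,BRAVO). Deletion parsimony must then date the duplication
    at the most recent consistent edge — the one into (ALPHA,BRAVO) — more
    recently than the truth. The loss is realized by simulating both full
    copies and removing the lost gene's sequence from the family.
    """
    from .species_tree import parse_species_tree

    sptree = parse_species_tree("(((ALPHA,BRAVO)ab,CHARL)abc,DELTA)root;")
    heights = {
        "ALPHA": 0.0,
        "BRAVO": 0.0,
        "CHARL": 0.0,
        "DELTA": 0.0,
        "ab": 0.3,
        "abc": 0.6,
        "root": 1.0,
    }
    fam = simulate_family(
        SimulationConfig(
            species_tree=sptree,
            heights=heights,
            sequence_length=300,
            forced_duplications=("abc",),
            seed=seed,
        )
    )
    # remove the second copy in CHARL: a planted deletion just below the event
    keep = [sid for sid in fam.alignment.ids if sid != "g2_CHARL"]
    aln = subset_alignment(fam.alignment, keep)
    result = infer_gene_tree(aln, sptree, with_branch_lengths=False)
    return BiasOutcome(
        true_placement="abc",
        expected_biased_placement="ab",
        inferred_placements=result.duplication_placements(),
    )


def rule2_audit(result: GigaResult) -> bool:
    """Every duplication is backed by genomic proof.

    Event-log audit: each join event recorded a nonempty species overlap
    between the two subtrees. Tree audit: every duplication node has at
    least two leaf descendants from one species.
    """
    for event in result.events:
        if event.action == "join":
            tag = [p for p in event.detail.split(";") if p.startswith("overlap=")]
            if not tag or not tag[0].removeprefix("overlap="):
                return False
    for node in result.tree.internal_nodes():
        if node.kind == DUPLICATION:
            species = [leaf.species_label for leaf in node.leaves()]
            if len(set(species)) == len(species):
                return False
    return True


def fragment_trial(
    seed: int, n_taxa: int = 12, sites: int = 200, fraction: float = 0.6
) -> tuple[bool, bool]:
    """Plant one truncated sequence; returns (quarantined?, topology over
    non-fragments identical to the run without the fragment?)."""
    rng = np.random.default_rng(seed)
    sptree, heights = random_species_tree(n_taxa, rng)
    fam = simulate_family(
        SimulationConfig(
            species_tree=sptree,
            heights=heights,
            sequence_length=sites,
            seed=_sub_seed(rng),
        )
    )
    frag = fam.alignment.ids[int(rng.integers(fam.alignment.n_sequences))]
    planted = plant_fragment(fam, frag, fraction)
    clean = infer_gene_tree(fam.alignment, sptree, with_branch_lengths=False)
    withfrag = infer_gene_tree(planted.alignment, sptree, with_branch_lengths=False)
    quarantined = frag in withfrag.quarantined
    keep = set(fam.alignment.ids) - {frag}
    preserved = (
        rf_distance(clean.tree.restrict(keep), withfrag.tree.restrict(keep)) == 0.0
    )
    return quarantined, preserved


def robustness_trial(
    seed: int, n_taxa: int = 12, sites: int = 300, n_drop: int = 3
) -> bool:
    """Clock-like duplication-free family: drop species, re-run, restrict the
    full tree to the remaining sequences — identical topology?"""
    rng = np.random.default_rng(seed)
    sptree, heights = random_species_tree(n_taxa, rng)
    fam = simulate_family(
        SimulationConfig(
            species_tree=sptree,
            heights=heights,
            sequence_length=sites,
            seed=_sub_seed(rng),
        )
    )
    full = infer_gene_tree(fam.alignment, sptree, with_branch_lengths=False)
    dropped = set(rng.choice(sorted(sptree.species), size=n_drop, replace=False))
    keep_ids = [
        sid
        for sid, sp in zip(fam.alignment.ids, fam.alignment.species)
        if sp not in dropped
    ]
    rerun = infer_gene_tree(
        subset_alignment(fam.alignment, keep_ids), sptree, with_branch_lengths=False
    )
    return rf_distance(full.tree.restrict(set(keep_ids)), rerun.tree) == 0.0


def determinism_trial(seed: int) -> bool:
    """Two independent end-to-end runs on the same inputs must produce
    byte-identical trees, event logs, and ortholog tables."""
    rng = np.random.default_rng(seed)
    sptree, heights = random_species_tree(10, rng)
    fam = simulate_family(
        SimulationConfig(
            species_tree=sptree,
            heights=heights,
            duplication_rate=0.15,
            sequence_length=250,
            seed=_sub_seed(rng),
        )
    )

    def artifacts() -> tuple[str, str, str]:
        res = infer_gene_tree(fam.alignment, sptree)
        pairs = sorted(tuple(sorted(p)) for p in extract_ortholog_pairs(res.tree))
        return (
            res.tree.to_newick(),
            res.event_log_tsv(),
            "".join(f"{a}\t{b}\n" for a, b in pairs),
        )

    return artifacts() == artifacts()
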