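"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from gigatree.alignment import FamilyAlignment, TrimmedAlignment
from gigatree.genetree import DUPLICATION, GeneNode, GeneTree, LEAF, SPECIATION
from gigatree.species_tree import parse_species_tree


@pytest.fixture
def basic_sptree():
    return parse_species_tree("((HUMAN,MOUSE),YEAST);")


@pytest.fixture
def opisthokont_tree():
    """Metazoa + fungi + amoebozoan outgroup, as in classic family figures."""
    return parse_species_tree(
        "(((HUMAN,MOUSE)euarch,(YEAST,SCHPO)fungi)opist,DICDI)root;"
    )


def make_alignment(records: dict[str, str]) -> FamilyAlignment:
    """FamilyAlignment from {seq_id: aligned_string}; species from id suffix."""
    ids = list(records)
    return FamilyAlignment(
        ids, [i.rsplit("_", 1)[1] for i in ids], [records[i] for i in ids]
    )


def make_trimmed(records: dict[str, str]) -> TrimmedAlignment:
    """TrimmedAlignment keeping every column (for post-inference fixtures)."""
    aln = make_alignment(records)
    return TrimmedAlignment(aln, list(range(aln.length)), aln.encoded())


# -- independent oracles ------------------------------------------------------


def brute_ortholog_pairs(tree: GeneTree) -> set[frozenset[str]]:
    """All-pairs MRCA scan using explicit root paths (independent of the
    package's subtree-accumulation implementation)."""

    def path(node: GeneNode) -> list[GeneNode]:
        out = []
        while node is not None:
            out.append(node)
            node = node.parent
        return out

    pairs = set()
    for a, b in combinations(tree.leaves(), 2):
        anc_b = set(id(n) for n in path(b))
        mrca = next(n for n in path(a) if id(n) in anc_b)
        if mrca.kind == SPECIATION:
            pairs.add(frozenset((a.label, b.label)))
    return pairs


def brute_bipartitions(tree: GeneTree) -> set[frozenset[frozenset[str]]]:
    def collect(node: GeneNode) -> set[str]:
        if node.is_leaf:
            return {node.label}
        out: set[str] = set()
        for c in node.children:
            out |= collect(c)
        return out

    everything = frozenset(collect(tree.root))
    splits = set()

    def visit(node: GeneNode) -> None:
        for c in node.children:
            if not c.is_leaf:
                side = frozenset(collect(c))
                rest = everything - side
                if len(side) > 1 and len(rest) > 1:
                    splits.add(frozenset((side, rest)))
                visit(c)

    visit(tree.root)
    return splits


def brute_rf(t1: GeneTree, t2: GeneTree) -> float:
    b1, b2 = brute_bipartitions(t1), brute_bipartitions(t2)
    denom = len(b1) + len(b2)
    return len(b1 ^ b2) / denom if denom else 0.0


def random_event_tree(
    rng: np.random.Generator, n_leaves: int, same_leafset_labels: list[str] | None = None
) -> GeneTree:
    """Random rooted tree (bi- and trifurcations) with random event labels.

    Leaves carry distinct species so that ortholog extraction is defined.
    """
    if same_leafset_labels is None:
        labels = [f"x{i}_SP{i:02d}" for i in range(n_leaves)]
    else:
        labels = list(same_leafset_labels)
    nodes: list[GeneNode] = [
        GeneNode(LEAF, lab, lab.rsplit("_", 1)[1]) for lab in labels
    ]
    while len(nodes) > 1:
        k = int(rng.integers(2, min(3, len(nodes)) + 1))
        picked = sorted(rng.choice(len(nodes), size=k, replace=False), reverse=True)
        children = [nodes.pop(i) for i in picked]
        kind = SPECIATION if rng.random() < 0.6 else DUPLICATION
        nodes.append(GeneNode(kind, species_label=f"n{len(nodes)}", children=children))
    return GeneTree(nodes[0])
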