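"""Tree-comparison statistics: ortholog pairs, their difference, and RF.

Two genes are orthologous under a tree iff their most recent common ancestor
is a speciation node. The ortholog-pair difference between two trees is one
minus the Jaccard overlap of their ortholog-pair sets. Topologies are
compared with the Robinson-Foulds bipartition distance, normalized by the
total number of non-trivial bipartitions in both trees (0 = identical,
1 = no shared bipartitions); multifurcating trees are handled naturally.
"""

from __future__ import annotations

from itertools import combinations

from .genetree import DUPLICATION, GeneTree, GeneNode, SPECIATION, UNRESOLVED

__all__ = [
    "extract_ortholog_pairs",
    "ortholog_pair_difference",
    "bipartitions",
    "rf_distance",
    "robustness_compare",
]

Pair = frozenset


def extract_ortholog_pairs(tree: GeneTree) -> set[frozenset[str]]:
    """Leaf pairs whose MRCA is a speciation node.

    Pairs meeting at a duplication or at the unresolved root are excluded.
    Raises if an internal node carries no event label, or if a speciation
    MRCA relates two genes of the same species (which the orthologous-subtree
    construction forbids).
    """
    pairs: set[frozenset[str]] = set()

    def collect(node: GeneNode) -> list[tuple[str, str]]:
        """Return (leaf label, species) under node; record pairs meeting here."""
        if node.is_leaf:
            return [(node.label, node.species_label)]
        if node.kind not in (SPECIATION, DUPLICATION, UNRESOLVED):
            raise ValueError(f"unlabeled internal node in gene tree: {node.kind!r}")
        child_leaves = [collect(c) for c in node.children]
        if node.kind == SPECIATION:
            for (la, lb) in combinations(range(len(child_leaves)), 2):
                for name_a, sp_a in child_leaves[la]:
                    for name_b, sp_b in child_leaves[lb]:
                        if sp_a and sp_b and sp_a == sp_b:
                            raise ValueError(
                                f"speciation MRCA relates two {sp_a} genes: "
                                f"{name_a}, {name_b}"
                            )
                        pairs.add(Pair((name_a, name_b)))
        return [leaf for sub in child_leaves for leaf in sub]

    collect(tree.root)
    return pairs


def ortholog_pair_difference(
    a: set[frozenset[str]], b: set[frozenset[str]]
) -> float:
    """1 - |a & b| / |a | b|; zero when both sets are empty."""
    union = a | b
    if not union:
        return 0.0
    return 1.0 - len(a & b) / len(union)


def bipartitions(tree: GeneTree) -> set[frozenset[frozenset[str]]]:
    """Non-trivial splits of the leaf set, in unrooted form.

    Each internal edge splits the leaves in two; splits with a side smaller
    than two leaves are trivial and excluded, and the two edges at a
    bifurcating root induce the same split (deduplicated by construction).
    """
    all_leaves = frozenset(tree.leaf_labels())
    splits: set[frozenset[frozenset[str]]] = set()
    for node in tree.root.walk():
        if node.parent is None or node.is_leaf:
            continue
        side = frozenset(node.leaf_labels())
        other = all_leaves - side
        if len(side) >= 2 and len(other) >= 2:
            splits.add(frozenset((side, other)))
    return splits


def rf_distance(t1: GeneTree, t2: GeneTree, normalized: bool = True) -> float:
    """Robinson-Foulds distance between two trees on the same leaf set."""
    if t1.leaf_labels() != t2.leaf_labels():
        raise ValueError(
            "trees have different leaf sets; restrict to shared leaves first"
        )
    b1, b2 = bipartitions(t1), bipartitions(t2)
    raw = len(b1 ^ b2)
    if not normalized:
        return float(raw)
    denom = len(b1) + len(b2)
    return raw / denom if denom else 0.0


def robustness_compare(
    full_tree: GeneTree, clean_tree: GeneTree, clean_leaves: set[str] | None = None
) -> float:
    """Normalized RF between the full tree restricted to the clean leaves
    and the clean tree — the clean-vs-full robustness protocol."""
    if clean_leaves is None:
        clean_leaves = clean_tree.leaf_labels()
    restricted = full_tree.restrict(set(clean_leaves))
    return rf_distance(restricted, clean_tree.restrict(set(clean_leaves)))
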