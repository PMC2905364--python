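"""Rooted species trees: parsing, validation, and ancestry queries.

The species tree is the topological constraint for gene-tree inference: every
orthologous subtree must be congruent with it, and duplication events are dated
relative to its nodes. Only topology is used; branch lengths present in the
input newick are ignored. Multifurcations are preserved, never resolved.
"""

from __future__ import annotations

import io
from typing import Iterable, Iterator, Optional

import dendropy

__all__ = [
    "SpeciesNode",
    "SpeciesTree",
    "SpeciesTreeError",
    "parse_species_tree",
    "mrca",
    "span_within",
]


class SpeciesTreeError(ValueError):
    """Malformed or inconsistent species-tree input."""


class SpeciesNode:
    """A node of the species tree.

    ``label`` is the species code for leaves, or a (possibly auto-generated)
    clade identifier for internal nodes. ``depth`` counts edges from the root.
    """

    __slots__ = ("label", "parent", "children", "depth", "index")

    def __init__(self, label: str, parent: Optional["SpeciesNode"] = None):
        self.label = label
        self.parent = parent
        self.children: list[SpeciesNode] = []
        self.depth: int = 0 if parent is None else parent.depth + 1
        self.index: int = -1  # preorder position, set by SpeciesTree

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def ancestors(self, include_self: bool = False) -> Iterator["SpeciesNode"]:
        node = self if include_self else self.parent
        while node is not None:
            yield node
            node = node.parent

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"SpeciesNode({self.label!r}, depth={self.depth})"


class SpeciesTree:
    """Validated rooted species tree with fast leaf lookup and MRCA queries."""

    def __init__(self, root: SpeciesNode):
        self.root = root
        self.nodes: list[SpeciesNode] = []
        self.leaf_index: dict[str, SpeciesNode] = {}
        self._finalize()

    # -- construction -----------------------------------------------------

    def _finalize(self) -> None:
        seen_labels: set[str] = set()
        stack = [self.root]
        while stack:
            node = stack.pop()
            node.index = len(self.nodes)
            self.nodes.append(node)
            if node.is_leaf:
                if node.label in self.leaf_index:
                    raise SpeciesTreeError(
                        f"duplicate species code {node.label!r} among leaves"
                    )
                self.leaf_index[node.label] = node
            if node.label:
                seen_labels.add(node.label)
            # preorder with children in given order
            stack.extend(reversed(node.children))
        # Unlabeled internal nodes get stable identifiers so duplication
        # placements are reportable.
        counter = 0
        for node in self.nodes:
            if not node.is_leaf and not node.label:
                while True:
                    candidate = f"N{counter}"
                    counter += 1
                    if candidate not in seen_labels:
                        break
                node.label = candidate
                seen_labels.add(candidate)
        self._validate()

    def _validate(self) -> None:
        for node in self.nodes:
            if node is self.root:
                if node.parent is not None:
                    raise SpeciesTreeError("root must have no parent")
            elif node.parent is None:
                raise SpeciesTreeError(f"non-root node {node.label!r} lacks a parent")
            if len(node.children) == 1:
                raise SpeciesTreeError(
                    f"internal node {node.label!r} has a single child; "
                    "unary nodes are not allowed"
                )
        if not self.leaf_index:
            raise SpeciesTreeError("species tree has no leaves")

    # -- queries -----------------------------------------------------------

    @property
    def species(self) -> set[str]:
        return set(self.leaf_index)

    def leaf(self, code: str) -> SpeciesNode:
        try:
            return self.leaf_index[code]
        except KeyError:
            raise SpeciesTreeError(f"unknown species code {code!r}") from None

    def mrca(self, species: Iterable[str]) -> SpeciesNode:
        """Most recent common ancestor of a set of species codes.

        The MRCA of a single species is that leaf itself.
        """
        codes = list(species)
        if not codes:
            raise SpeciesTreeError("mrca of an empty species set is undefined")
        node = self.leaf(codes[0])
        for code in codes[1:]:
            other = self.leaf(code)
            while node.depth > other.depth:
                node = node.parent
            while other.depth > node.depth:
                other = other.parent
            while node is not other:
                node = node.parent
                other = other.parent
        return node

    def is_ancestor_or_self(self, a: SpeciesNode, b: SpeciesNode) -> bool:
        """True iff ``a`` equals ``b`` or is an ancestor of ``b``."""
        while b is not None and b.depth > a.depth:
            b = b.parent
        return a is b

    def span_within(self, span_a: Iterable[str], span_b: Iterable[str]) -> bool:
        """True iff the phylogenetic span of ``span_b`` fits within ``span_a``.

        Spans are compared by MRCA containment: span B <= span A iff mrca(B)
        is mrca(A) or a descendant of it.
        """
        return self.is_ancestor_or_self(self.mrca(span_a), self.mrca(span_b))

    def clade_species(self, node: SpeciesNode) -> set[str]:
        """Species codes of the leaves under ``node`` (inclusive)."""
        out: set[str] = set()
        stack = [node]
        while stack:
            cur = stack.pop()
            if cur.is_leaf:
                out.add(cur.label)
            else:
                stack.extend(cur.children)
        return out

    # -- serialization -----------------------------------------------------

    def to_newick(self, internal_labels: bool = True) -> str:
        def fmt(node: SpeciesNode) -> str:
            if node.is_leaf:
                return _quote(node.label)
            inner = ",".join(fmt(c) for c in node.children)
            lab = _quote(node.label) if internal_labels else ""
            return f"({inner}){lab}"

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"SpeciesTree({len(self.leaf_index)} species)"


_NEWICK_SAFE = set(
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789_.-|/"
)


def _quote(label: str) -> str:
    if label and set(label) <= _NEWICK_SAFE:
        return label
    return "'" + label.replace("'", "''") + "'"


def parse_species_tree(text: str) -> SpeciesTree:
    """Parse a rooted newick species tree.

    Branch lengths and comments are accepted and ignored; quoted labels are
    supported; multifurcations are preserved. Unary internal chains (as
    produced by some exporters) are suppressed.
    """
    if not text or not text.strip():
        raise SpeciesTreeError("empty newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise SpeciesTreeError(f"malformed newick: {exc}") from exc

    def convert(dnode, parent: Optional[SpeciesNode]) -> SpeciesNode:
        children = dnode.child_nodes()
        # suppress unary chains from the input
        while len(children) == 1:
            dnode = children[0]
            children = dnode.child_nodes()
        if dnode.taxon is not None:
            label = dnode.taxon.label or ""
        else:
            label = dnode.label or ""
        node = SpeciesNode(label, parent)
        for child in children:
            node.children.append(convert(child, node))
        return node

    root = convert(dtree.seed_node, None)
    if root.is_leaf and not root.label:
        raise SpeciesTreeError("newick contains no taxa")
    for node in _preorder(root):
        if node.is_leaf and not node.label:
            raise SpeciesTreeError("leaf with empty label")
    return SpeciesTree(root)


def _preorder(root: SpeciesNode) -> Iterator[SpeciesNode]:
    stack = [root]
    while stack:
        node = stack.pop()
        yield node
        stack.extend(reversed(node.children))


# Thin functional wrappers matching the module surface -----------------------

def mrca(tree: SpeciesTree, species: Iterable[str]) -> SpeciesNode:
    return tree.mrca(species)


def span_within(tree: SpeciesTree, span_a: Iterable[str], span_b: Iterable[str]) -> bool:
    return tree.span_within(span_a, span_b)
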