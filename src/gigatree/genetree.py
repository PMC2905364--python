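"""Gene trees with event-labeled internal nodes.

Leaves are sequence ids; internal nodes are labeled as speciation events
(mapped to a species-tree node), duplication events (carrying the placement:
the species-tree node immediately below the founding edge), or an unresolved
multifurcating root joining components never connected by any event.
Multifurcations are allowed throughout.
"""

from __future__ import annotations

from typing import Iterator, Optional

import dendropy

__all__ = ["GeneNode", "GeneTree", "GeneTreeError", "parse_gene_tree"]

SPECIATION = "speciation"
DUPLICATION = "duplication"
LEAF = "leaf"
UNRESOLVED = "unresolved"


class GeneTreeError(ValueError):
    pass


class GeneNode:
    __slots__ = ("kind", "label", "species_label", "parent", "children", "length")

    def __init__(
        self,
        kind: str,
        label: str = "",
        species_label: str = "",
        children: Optional[list["GeneNode"]] = None,
    ):
        self.kind = kind  # leaf | speciation | duplication | unresolved
        self.label = label  # sequence id for leaves
        # speciation: species-tree node of the event;
        # duplication: species-tree node below the founding edge (placement)
        self.species_label = species_label
        self.parent: Optional[GeneNode] = None
        self.children: list[GeneNode] = []
        self.length: Optional[float] = None
        for child in children or []:
            self.add_child(child)

    def add_child(self, child: "GeneNode") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return self.kind == LEAF

    def walk(self) -> Iterator["GeneNode"]:
        """Preorder traversal of the subtree rooted here."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["GeneNode"]:
        return [n for n in self.walk() if n.is_leaf]

    def leaf_labels(self) -> set[str]:
        return {n.label for n in self.walk() if n.is_leaf}

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        if self.is_leaf:
            return f"GeneNode(leaf {self.label!r})"
        return f"GeneNode({self.kind}, {len(self.children)} children)"


class GeneTree:
    """A rooted gene tree over sequence ids."""

    def __init__(self, root: GeneNode):
        self.root = root
        labels = [n.label for n in root.walk() if n.is_leaf]
        if len(set(labels)) != len(labels):
            raise GeneTreeError("duplicate leaf labels in gene tree")

    # -- queries -----------------------------------------------------------

    def leaves(self) -> list[GeneNode]:
        return self.root.leaves()

    def leaf_labels(self) -> set[str]:
        return self.root.leaf_labels()

    def internal_nodes(self) -> list[GeneNode]:
        return [n for n in self.root.walk() if not n.is_leaf]

    def mrca(self, labels: set[str]) -> GeneNode:
        """MRCA of a set of leaf labels (smallest subtree containing all)."""
        if not labels:
            raise GeneTreeError("mrca of empty leaf set")
        node = self.root
        while True:
            containing = [
                c for c in node.children if labels & c.leaf_labels()
            ]
            if len(containing) == 1 and labels <= containing[0].leaf_labels():
                node = containing[0]
            else:
                if not labels <= node.leaf_labels():
                    raise GeneTreeError(f"labels {labels} not all present in tree")
                return node

    # -- transforms ----------------------------------------------------------

    def restrict(self, keep: set[str]) -> "GeneTree":
        """Restriction to a subset of leaves, suppressing unary nodes."""
        missing = keep - self.leaf_labels()
        if missing:
            raise GeneTreeError(f"leaves not in tree: {sorted(missing)}")

        def prune(node: GeneNode) -> Optional[GeneNode]:
            if node.is_leaf:
                if node.label in keep:
                    out = GeneNode(LEAF, node.label, node.species_label)
                    out.length = node.length
                    return out
                return None
            kept = [c for c in (prune(ch) for ch in node.children) if c is not None]
            if not kept:
                return None
            if len(kept) == 1:
                return kept[0]
            out = GeneNode(node.kind, node.label, node.species_label, kept)
            out.length = node.length
            return out

        new_root = prune(self.root)
        if new_root is None:
            raise GeneTreeError("restriction removed every leaf")
        new_root.length = None
        return GeneTree(new_root)

    # -- serialization ---------------------------------------------------------

    def to_newick(self, nhx: bool = True, branch_lengths: bool = True) -> str:
        def annot(node: GeneNode) -> str:
            if not nhx or node.is_leaf:
                return ""
            if node.kind == SPECIATION:
                return f"[&&NHX:D=N:S={node.species_label}]"
            if node.kind == DUPLICATION:
                return f"[&&NHX:D=Y:S={node.species_label}]"
            return "[&&NHX:D=U]"

        def fmt(node: GeneNode) -> str:
            if node.is_leaf:
                core = _escape(node.label)
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if branch_lengths and node.length is not None:
                core += f":{node.length:.6f}"
            return core + annot(node)

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"GeneTree({len(self.leaves())} leaves)"


_SAFE = set("ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789_.-|/")


def _escape(label: str) -> str:
    if label and set(label) <= _SAFE:
        return label
    return "'" + label.replace("'", "''") + "'"


def _parse_nhx(comments: list[str]) -> dict[str, str]:
    for comment in comments:
        body = comment.strip("[]")
        if body.startswith("&&NHX"):
            fields = body.split(":")[1:]
            return dict(f.split("=", 1) for f in fields if "=" in f)
    return {}


def parse_gene_tree(text: str) -> GeneTree:
    """Parse a newick gene tree, reading NHX event annotations if present.

    Internal nodes without an NHX ``D`` tag are marked ``unresolved``; such
    trees support topology comparison but not ortholog extraction.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            extract_comment_metadata=False,
        )
    except Exception as exc:
        raise GeneTreeError(f"malformed newick: {exc}") from exc

    def convert(dnode) -> GeneNode:
        children = dnode.child_nodes()
        while len(children) == 1:
            dnode = children[0]
            children = dnode.child_nodes()
        tags = _parse_nhx(dnode.comments or [])
        if not children:
            label = dnode.taxon.label if dnode.taxon is not None else (dnode.label or "")
            node = GeneNode(LEAF, label, tags.get("S", ""))
        else:
            d = tags.get("D", "")
            if d == "Y":
                kind = DUPLICATION
            elif d == "N":
                kind = SPECIATION
            else:
                kind = UNRESOLVED
            node = GeneNode(kind, dnode.label or "", tags.get("S", ""))
            for child in children:
                node.add_child(convert(child))
        if dnode.edge.length is not None:
            node.length = float(dnode.edge.length)
        return node

    return GeneTree(convert(dtree.seed_node))
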