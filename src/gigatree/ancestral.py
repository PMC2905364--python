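"""Approximate ancestral sequences and Jukes-Cantor branch lengths.

Ancestral residues are reconstructed by a local, parsimony-like majority rule
over each node's children, with the node's sibling subtree acting as the
closest outgroup to break ties. Branch lengths are the corrected fraction of
differences between adjacent node sequences; branches descending from a
duplication node use only sites aligned in all of the duplication's
descendants, guarding relative lengths against rate heterogeneity among sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import (
    AMINO_ACIDS,
    GAP_CODE,
    SaturationError,
    TrimmedAlignment,
    jc_distance,
)
from .config import GigaConfig
from .genetree import DUPLICATION, GeneNode, GeneTree

__all__ = ["AncestralStates", "infer_ancestral_states", "branch_lengths"]

# internal state codes: 0..19 residues, GAP, UNK
GAP_STATE = 20
UNK_STATE = 21


@dataclass
class AncestralStates:
    """Reconstructed residue states per node (leaves carry observations)."""

    states: dict[int, np.ndarray]  # id(node) -> int8 array over trimmed columns
    length: int
    warnings: list[str] = field(default_factory=list)

    def of(self, node: GeneNode) -> np.ndarray:
        return self.states[id(node)]

    def sequence(self, node: GeneNode) -> str:
        """Residue string with 'X' for unknown or gap-majority positions."""
        out = []
        for code in self.of(node):
            out.append(AMINO_ACIDS[code] if code < 20 else "X")
        return "".join(out)


def _leaf_states(trimmed: TrimmedAlignment, seq_id: str) -> np.ndarray:
    row = trimmed.row(seq_id).astype(np.int8).copy()
    row[row == GAP_CODE] = GAP_STATE
    return row


def _strict_majority(rows: list[np.ndarray], length: int) -> np.ndarray:
    """Per-column strict majority over non-unknown states, else UNK.

    Gaps count as a state for the vote; unknowns are excluded from the
    denominator.
    """
    out = np.full(length, UNK_STATE, dtype=np.int8)
    if not rows:
        return out
    mat = np.stack(rows)
    known = mat != UNK_STATE
    denom = known.sum(axis=0)
    counts = np.zeros((GAP_STATE + 1, length), dtype=np.int32)
    for state in range(GAP_STATE + 1):
        counts[state] = (mat == state).sum(axis=0)
    best = counts.argmax(axis=0)
    best_count = counts.max(axis=0)
    winner = (denom > 0) & (2 * best_count > denom)
    out[winner] = best[winner]
    return out


def infer_ancestral_states(
    tree: GeneTree, trimmed: TrimmedAlignment
) -> AncestralStates:
    """Reconstruct ancestral residues at every internal node.

    Per site, the strict majority of the children's states wins; on a tied
    vote the sibling subtree's (leaf-majority) residue decides if it matches
    one of the children; otherwise the state is unknown. A gap-majority site
    is reported as unknown rather than as an ancestral gap.
    """
    states: dict[int, np.ndarray] = {}
    length = trimmed.length
    anc = AncestralStates(states, length)

    for leaf in tree.leaves():
        states[id(leaf)] = _leaf_states(trimmed, leaf.label)

    def outgroup_state(node: GeneNode) -> np.ndarray:
        if node.parent is None:
            return np.full(length, UNK_STATE, dtype=np.int8)
        sib_leaves: list[np.ndarray] = []
        for sib in node.parent.children:
            if sib is node:
                continue
            sib_leaves.extend(states[id(lf)] for lf in sib.leaves())
        return _strict_majority(sib_leaves, length)

    def reconstruct(node: GeneNode) -> np.ndarray:
        if node.is_leaf:
            return states[id(node)]
        child_states = [reconstruct(c) for c in node.children]
        result = _strict_majority(child_states, length)
        tied = result == UNK_STATE
        if tied.any():
            out = outgroup_state(node)
            stacked = np.stack(child_states)
            matches = (stacked == out[None, :]).any(axis=0)
            use_out = tied & matches & (out != UNK_STATE)
            result[use_out] = out[use_out]
        # A gap may win the vote (the ancestor plausibly lacked the site) and
        # stays countable further up the tree, but is emitted as 'X' and never
        # counts as a comparable residue for branch lengths.
        states[id(node)] = result
        return result

    reconstruct(tree.root)
    return anc


def branch_lengths(
    tree: GeneTree, anc: AncestralStates, cfg: GigaConfig = GigaConfig()
) -> dict[int, float]:
    """Corrected substitutions per site for each edge (keyed by id(child)).

    p is computed over sites where both endpoint states are known residues;
    for edges below a duplication node, only sites aligned in every leaf
    descendant of that duplication count. Lengths are also stored on each
    node's ``length`` attribute for serialization. Saturated branches are
    capped at ``cfg.max_branch_length`` and flagged in ``anc.warnings``.
    """
    lengths: dict[int, float] = {}
    for node in tree.root.walk():
        dup_mask = None
        if node.kind == DUPLICATION:
            rows = [anc.of(leaf) for leaf in node.leaves()]
            dup_mask = np.all(np.stack(rows) < 20, axis=0)
        for child in node.children:
            a, b = anc.of(node), anc.of(child)
            mask = (a < 20) & (b < 20)
            if dup_mask is not None:
                mask = mask & dup_mask
            n = int(mask.sum())
            if n == 0:
                anc.warnings.append(
                    f"edge above {_describe(child)}: no comparable sites; length 0"
                )
                length = 0.0
            else:
                p = float(((a != b) & mask).sum()) / n
                try:
                    length = jc_distance(p, cfg.alphabet_states)
                except SaturationError:
                    anc.warnings.append(
                        f"edge above {_describe(child)}: saturated (p={p:.3f}); "
                        f"capped at {cfg.max_branch_length}"
                    )
                    length = cfg.max_branch_length
            lengths[id(child)] = length
            child.length = length
    tree.root.length = None
    return lengths


def _describe(node: GeneNode) -> str:
    if node.is_leaf:
        return node.label
    return f"{node.kind}({','.join(sorted(node.leaf_labels())[:3])}...)"
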