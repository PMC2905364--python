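"""Forward simulation of gene families along a species tree.

A single ancestral gene evolves down an ultrametric species tree. On each
edge, each gene lineage may be lost, may duplicate (the new copy is founded
on that edge, matching the way duplications are dated on species-tree edges),
and accumulates substitutions under a uniform 20-state exchange model whose
per-edge probability is proportional to the edge's time span (clock-like).
The founded copy of a duplication evolves its founding edge at an accelerated
rate, emulating the post-duplication rate acceleration commonly seen in real
families. The output is a gap-free alignment (indel evolution is out of
scope), the true event-labeled gene tree, and the true duplication
placements — everything needed to score the inference engine without any
external dataset.
"""

from __future__ import annotations

import itertools
import json
import string
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .alignment import AMINO_ACIDS, FamilyAlignment
from .genetree import DUPLICATION, GeneNode, GeneTree, LEAF, SPECIATION
from .species_tree import SpeciesNode, SpeciesTree, parse_species_tree

__all__ = [
    "SimulationConfig",
    "SimulatedFamily",
    "simulate_family",
    "plant_fragment",
    "random_species_tree",
    "default_heights",
]


def _species_codes(n: int) -> list[str]:
    combos = itertools.product(string.ascii_uppercase, repeat=3)
    return ["SP" + "".join(c) for c, _ in zip(combos, range(n))]


def random_species_tree(
    n_leaves: int, rng: np.random.Generator, height: float = 1.0
) -> tuple[SpeciesTree, dict[str, float]]:
    """Random ultrametric (coalescent-style) species tree.

    Returns the tree plus node heights keyed by node label (leaves at 0,
    total height rescaled to ``height``).
    """
    if n_leaves < 2:
        raise ValueError("need at least two species")
    codes = _species_codes(n_leaves)
    heights: dict[str, float] = {c: 0.0 for c in codes}
    items: list[str] = list(codes)
    newick_of: dict[str, str] = {c: c for c in codes}
    h = 0.0
    counter = 0
    while len(items) > 1:
        k = len(items)
        h += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        label = f"N{counter}"
        counter += 1
        merged = f"({newick_of[items[i]]},{newick_of[items[j]]}){label}"
        heights[label] = h
        newick_of[label] = merged
        items[i] = label
        del items[j]
    scale = height / h if h > 0 else 1.0
    heights = {k_: v * scale for k_, v in heights.items()}
    tree = parse_species_tree(newick_of[items[0]] + ";")
    return tree, heights


def default_heights(tree: SpeciesTree) -> dict[str, float]:
    """Unit-edge heights for a tree without timing information, max height 1."""
    heights: dict[str, float] = {}

    def fill(node: SpeciesNode) -> float:
        if node.is_leaf:
            heights[node.label] = 0.0
            return 0.0
        h = 1.0 + max(fill(c) for c in node.children)
        heights[node.label] = h
        return h

    top = fill(tree.root)
    if top > 0:
        heights = {k: v / top for k, v in heights.items()}
    return heights


@dataclass
class SimulationConfig:
    """Parameters of the forward simulation.

    duplication_rate
        Expected duplication events per gene lineage per species-tree edge
        (Poisson-distributed count; the new copy is founded at the top of
        the edge).
    loss_probability
        Probability that a gene lineage dies on an edge.
    substitution_rate
        Per-site substitution probability per unit of tree height, so equal
        time spans accumulate equal expected divergence (molecular clock).
    post_duplication_multiplier
        Rate multiplier (>= 1) applied to the founded copy on its founding
        edge, emulating post-duplication acceleration.
    forced_duplications
        Labels of species-tree nodes; one duplication is planted on the edge
        entering each named node, on the first gene lineage traversing it.
    fragment_probability / truncation_fraction
        Each extant sequence is independently truncated (trailing fraction of
        columns replaced by gaps) with this probability.
    """

    species_tree: SpeciesTree
    heights: Optional[dict[str, float]] = None
    duplication_rate: float = 0.0
    loss_probability: float = 0.0
    sequence_length: int = 300
    substitution_rate: float = 0.4
    post_duplication_multiplier: float = 1.5
    forced_duplications: tuple[str, ...] = ()
    fragment_probability: float = 0.0
    truncation_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("loss_probability", "fragment_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.sequence_length < 1:
            raise ValueError("sequence_length must be >= 1")
        if self.post_duplication_multiplier < 1.0:
            raise ValueError("post_duplication_multiplier must be >= 1")
        if not 0.0 < self.truncation_fraction < 1.0:
            raise ValueError("truncation_fraction must lie in (0, 1)")


@dataclass
class SimulatedFamily:
    """A simulated family: alignment, true labeled tree, and ground truth."""

    alignment: FamilyAlignment
    true_tree: GeneTree
    true_placements: list[str]  # species-tree node labels below each dup edge
    fragments: list[str] = field(default_factory=list)

    def manifest(self) -> dict:
        return {
            "n_sequences": self.alignment.n_sequences,
            "length": self.alignment.length,
            "true_tree": self.true_tree.to_newick(branch_lengths=False),
            "true_duplication_placements": self.true_placements,
            "fragments": self.fragments,
        }

    def manifest_json(self) -> str:
        return json.dumps(self.manifest(), indent=2, sort_keys=True) + "\n"


class _Simulator:
    def __init__(self, cfg: SimulationConfig):
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.heights = (
            dict(cfg.heights)
            if cfg.heights is not None
            else default_heights(cfg.species_tree)
        )
        self.forced_pending = set(cfg.forced_duplications)
        unknown = self.forced_pending - {n.label for n in cfg.species_tree.nodes}
        if unknown:
            raise ValueError(f"forced duplication on unknown nodes: {sorted(unknown)}")
        self.placements: list[str] = []
        self.leaf_seqs: list[tuple[GeneNode, np.ndarray]] = []

    def mutate(self, seq: np.ndarray, q: float) -> np.ndarray:
        q = min(q, 0.9)
        hit = self.rng.random(seq.size) < q
        out = seq.copy()
        if hit.any():
            shift = self.rng.integers(1, 20, size=int(hit.sum()))
            out[hit] = (out[hit] + shift) % 20
        return out

    def evolve_edge(
        self, child_sp: SpeciesNode, seq: np.ndarray, accelerated: bool
    ) -> Optional[GeneNode]:
        cfg = self.cfg
        dh = self.heights[child_sp.parent.label] - self.heights[child_sp.label]
        n_dup = (
            int(self.rng.poisson(cfg.duplication_rate)) if cfg.duplication_rate else 0
        )
        if child_sp.label in self.forced_pending:
            self.forced_pending.discard(child_sp.label)
            n_dup += 1
        survivors: list[GeneNode] = []
        for idx in range(1 + n_dup):
            copy_accel = accelerated if idx == 0 else True
            if cfg.loss_probability and self.rng.random() < cfg.loss_probability:
                continue
            q = cfg.substitution_rate * dh
            if copy_accel:
                q *= cfg.post_duplication_multiplier
            mutated = self.mutate(seq, q)
            sub = self.evolve_node(child_sp, mutated)
            if sub is not None:
                survivors.append(sub)
        if not survivors:
            return None
        if len(survivors) == 1:
            return survivors[0]
        return GeneNode(
            DUPLICATION, species_label=child_sp.label, children=survivors
        )

    def evolve_node(self, sp_node: SpeciesNode, seq: np.ndarray) -> Optional[GeneNode]:
        if sp_node.is_leaf:
            leaf = GeneNode(LEAF, species_label=sp_node.label)
            self.leaf_seqs.append((leaf, seq))
            return leaf
        kids = []
        for child in sp_node.children:
            sub = self.evolve_edge(child, seq, accelerated=False)
            if sub is not None:
                kids.append(sub)
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        return GeneNode(SPECIATION, species_label=sp_node.label, children=kids)

    def run(self) -> SimulatedFamily:
        cfg = self.cfg
        root_seq = self.rng.integers(0, 20, size=cfg.sequence_length)
        root = self.evolve_node(cfg.species_tree.root, root_seq)
        if root is None or not self.leaf_seqs:
            raise ValueError("all gene lineages were lost; empty family")
        # name leaves in creation (traversal) order, per-species counters
        counts: dict[str, int] = {}
        ids, species, seqs = [], [], []
        for leaf, seq in self.leaf_seqs:
            sp = leaf.species_label
            counts[sp] = counts.get(sp, 0) + 1
            leaf.label = f"g{counts[sp]}_{sp}"
            ids.append(leaf.label)
            species.append(sp)
            seqs.append("".join(AMINO_ACIDS[c] for c in seq))
        tree = GeneTree(root)
        placements = sorted(
            n.species_label for n in tree.internal_nodes() if n.kind == DUPLICATION
        )
        aln = FamilyAlignment(ids, species, seqs)
        fam = SimulatedFamily(aln, tree, placements)
        if cfg.fragment_probability:
            for sid in list(aln.ids):
                if self.rng.random() < cfg.fragment_probability:
                    fam = plant_fragment(fam, sid, cfg.truncation_fraction)
        return fam


def simulate_family(cfg: SimulationConfig) -> SimulatedFamily:
    """Simulate one gene family; deterministic under a fixed seed."""
    return _Simulator(cfg).run()


def plant_fragment(
    fam: SimulatedFamily, seq_id: str, truncation_fraction: float
) -> SimulatedFamily:
    """Replace the trailing fraction of one sequence's columns with gaps."""
    if seq_id not in fam.alignment.ids:
        raise ValueError(f"unknown sequence id {seq_id!r}")
    if not 0.0 < truncation_fraction < 1.0:
        raise ValueError("truncation fraction must lie in (0, 1)")
    idx = fam.alignment.ids.index(seq_id)
    seqs = list(fam.alignment.sequences)
    length = len(seqs[idx])
    cut = length - int(round(truncation_fraction * length))
    seqs[idx] = seqs[idx][:cut] + "-" * (length - cut)
    aln = FamilyAlignment(
        list(fam.alignment.ids), list(fam.alignment.species), seqs
    )
    return SimulatedFamily(
        aln, fam.true_tree, list(fam.true_placements), fam.fragments + [seq_id]
    )
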