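"""End-to-end inference: alignment in, labeled gene tree out."""

from __future__ import annotations

from .alignment import (
    FamilyAlignment,
    compute_weights,
    pairwise_distances,
    trim_alignment,
)
from .ancestral import branch_lengths, infer_ancestral_states
from .config import GigaConfig
from .core import GigaResult, run_giga
from .species_tree import SpeciesTree

__all__ = ["infer_gene_tree"]


def infer_gene_tree(
    aln: FamilyAlignment,
    sptree: SpeciesTree,
    cfg: GigaConfig = GigaConfig(),
    with_branch_lengths: bool = True,
) -> GigaResult:
    """Run the full procedure: weight, trim, distance, agglomerate, and
    (optionally) reconstruct ancestral states for corrected branch lengths."""
    weights = compute_weights(aln)
    trimmed = trim_alignment(aln, weights, cfg)
    dm = pairwise_distances(trimmed)
    result = run_giga(trimmed, dm, sptree, cfg)
    if with_branch_lengths and result.tree.leaves():
        states = infer_ancestral_states(result.tree, trimmed)
        branch_lengths(result.tree, states, cfg)
    return result
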