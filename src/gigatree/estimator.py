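"""Estimator-style front end to the inference engine.

``GigaTreeEstimator`` wraps the full pipeline behind the scikit-learn
estimator protocol (``get_params``/``set_params``, ``fit``, trailing-underscore
fitted attributes), so configurations can be cloned and grid-searched with
sklearn tooling. The input is an aligned protein family rather than a feature
matrix, so the estimator composes with parameter-handling utilities, not with
numeric transformers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

from sklearn.base import BaseEstimator

from .alignment import FamilyAlignment, read_fasta_alignment
from .config import GigaConfig
from .metrics import extract_ortholog_pairs
from .pipeline import infer_gene_tree
from .species_tree import SpeciesTree, parse_species_tree

__all__ = ["GigaTreeEstimator"]

AlignmentLike = Union[FamilyAlignment, str, Path, Iterable[tuple[str, str]]]


class GigaTreeEstimator(BaseEstimator):
    """Species-tree-constrained agglomerative gene-tree inference.

    Parameters mirror :class:`~gigatree.config.GigaConfig`; ``species_tree``
    may be a newick string or a parsed :class:`SpeciesTree`.

    Fitted attributes
    -----------------
    tree_ : GeneTree
        The inferred gene tree with speciation/duplication node labels.
    events_ : list
        The replayable event log of the agglomeration.
    quarantined_, discarded_ : list[str]
        Fragment bookkeeping (quarantined during the main pass; discarded if
        the single re-insertion attempt failed).
    ortholog_pairs_ : set[frozenset[str]]
        Leaf pairs whose MRCA is a speciation node.
    """

    def __init__(
        self,
        species_tree: Union[str, SpeciesTree, None] = None,
        gap_threshold: float = 0.15,
        fragment_coverage: float = 0.5,
        fragment_exempt_os_size: int = 3,
        ortholog_sd_multiplier: float = 1.5,
        paralog_sd_multiplier: float = 0.5,
        revision_literal_sign: bool = False,
        compute_branch_lengths: bool = True,
    ):
        self.species_tree = species_tree
        self.gap_threshold = gap_threshold
        self.fragment_coverage = fragment_coverage
        self.fragment_exempt_os_size = fragment_exempt_os_size
        self.ortholog_sd_multiplier = ortholog_sd_multiplier
        self.paralog_sd_multiplier = paralog_sd_multiplier
        self.revision_literal_sign = revision_literal_sign
        self.compute_branch_lengths = compute_branch_lengths

    # -- helpers -----------------------------------------------------------

    def _config(self) -> GigaConfig:
        return GigaConfig(
            gap_threshold=self.gap_threshold,
            fragment_coverage=self.fragment_coverage,
            fragment_exempt_os_size=self.fragment_exempt_os_size,
            ortholog_sd_multiplier=self.ortholog_sd_multiplier,
            paralog_sd_multiplier=self.paralog_sd_multiplier,
            revision_literal_sign=self.revision_literal_sign,
        )

    def _species_tree(self) -> SpeciesTree:
        if self.species_tree is None:
            raise ValueError("species_tree parameter is required")
        if isinstance(self.species_tree, SpeciesTree):
            return self.species_tree
        return parse_species_tree(str(self.species_tree))

    @staticmethod
    def _alignment(
        X: AlignmentLike, species_map: Optional[Mapping[str, str]]
    ) -> FamilyAlignment:
        if isinstance(X, FamilyAlignment):
            return X
        if isinstance(X, (str, Path)):
            return read_fasta_alignment(X, species_map)
        return FamilyAlignment.from_records(X, species_map)

    # -- estimator API ------------------------------------------------------

    def fit(
        self,
        X: AlignmentLike,
        y=None,
        species_map: Optional[Mapping[str, str]] = None,
    ) -> "GigaTreeEstimator":
        """Infer the gene tree for an aligned family.

        ``X`` may be a FamilyAlignment, a FASTA path, or (id, sequence)
        records; species default to the suffix after the final '_' in ids.
        """
        aln = self._alignment(X, species_map)
        result = infer_gene_tree(
            aln,
            self._species_tree(),
            self._config(),
            with_branch_lengths=self.compute_branch_lengths,
        )
        self.result_ = result
        self.tree_ = result.tree
        self.events_ = result.events
        self.quarantined_ = result.quarantined
        self.discarded_ = result.discarded
        self.ortholog_pairs_ = extract_ortholog_pairs(result.tree)
        self.n_leaves_ = len(result.tree.leaves())
        return self

    def fit_predict(
        self,
        X: AlignmentLike,
        y=None,
        species_map: Optional[Mapping[str, str]] = None,
    ) -> str:
        """Fit and return the inferred tree as an NHX-annotated newick string."""
        self.fit(X, species_map=species_map)
        return self.tree_.to_newick()
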