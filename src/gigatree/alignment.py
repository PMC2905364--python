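"""Family alignments: weighting, column trimming, and raw p-distances.

The inference engine consumes only a trimmed alignment and the pairwise
fraction of amino-acid differences computed from it; distances are computed
once and never updated during agglomeration. The Jukes-Cantor closed forms
(generalized to an s-state alphabet, s = 20 for proteins) supply corrected
branch lengths and the distance standard deviation used by the revision rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio import SeqIO

from .config import GigaConfig

__all__ = [
    "AMINO_ACIDS",
    "AlignmentError",
    "SaturationError",
    "FamilyAlignment",
    "SequenceWeights",
    "TrimmedAlignment",
    "DistanceMatrix",
    "read_fasta_alignment",
    "read_species_map",
    "species_from_id",
    "compute_weights",
    "trim_alignment",
    "pairwise_distances",
    "jc_distance",
    "jc_stddev",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_CODE = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
GAP_CODE = -1
# Ambiguity characters carry no usable residue information: treated as gaps
# for both trimming and distance computation.
_GAP_CHARS = set("-.XBZJUO*")


class AlignmentError(ValueError):
    """Invalid alignment input."""


class SaturationError(ValueError):
    """p-distance at or beyond the Jukes-Cantor saturation bound."""


def species_from_id(seq_id: str) -> str:
    """Extract the species code from a sequence id.

    Default convention: the suffix after the final underscore, as in the
    UniProt five-letter style (``MTHFR_HUMAN`` -> ``HUMAN``).
    """
    if "_" not in seq_id:
        raise AlignmentError(
            f"cannot derive species from id {seq_id!r}: no '_' separator; "
            "provide an explicit id-to-species mapping"
        )
    return seq_id.rsplit("_", 1)[1]


@dataclass
class FamilyAlignment:
    """An aligned protein family: ordered (id, species, residues) records."""

    ids: list[str]
    species: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if not self.ids:
            raise AlignmentError("alignment has no sequences")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("sequence ids are not unique")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError(
                f"aligned sequences have unequal lengths: {sorted(lengths)}"
            )
        if len(self.species) != len(self.ids) or len(self.sequences) != len(self.ids):
            raise AlignmentError("ids, species and sequences must align")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    def encoded(self) -> np.ndarray:
        """Residues as an (n_sequences, length) int8 matrix; gaps/unknowns = -1."""
        mat = np.full((self.n_sequences, self.length), GAP_CODE, dtype=np.int8)
        for i, seq in enumerate(self.sequences):
            for j, ch in enumerate(seq.upper()):
                code = _CODE.get(ch)
                if code is not None:
                    mat[i, j] = code
                elif ch not in _GAP_CHARS:
                    raise AlignmentError(
                        f"unexpected character {ch!r} in sequence {self.ids[i]!r}"
                    )
        return mat

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, str]],
        species_map: Optional[Mapping[str, str]] = None,
    ) -> "FamilyAlignment":
        ids, species, seqs = [], [], []
        for seq_id, seq in records:
            ids.append(seq_id)
            if species_map is not None:
                try:
                    species.append(species_map[seq_id])
                except KeyError:
                    raise AlignmentError(
                        f"sequence {seq_id!r} missing from the species mapping"
                    ) from None
            else:
                species.append(species_from_id(seq_id))
            seqs.append(seq)
        return cls(ids, species, seqs)


def read_fasta_alignment(
    path: str | Path, species_map: Optional[Mapping[str, str]] = None
) -> FamilyAlignment:
    """Read an aligned FASTA file ('-' gaps) into a FamilyAlignment."""
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise AlignmentError(f"no FASTA records found in {path}")
    return FamilyAlignment.from_records(records, species_map)


def read_species_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping sequence id -> species code."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise AlignmentError(
                f"{path}:{lineno}: expected two tab-separated columns"
            )
        mapping[parts[0]] = parts[1]
    return mapping


@dataclass
class SequenceWeights:
    """Per-sequence weights, normalized to sum to the number of sequences."""

    weights: dict[str, float]

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.weights.values()):
            raise AlignmentError("sequence weights must be positive")
        total = sum(self.weights.values())
        n = len(self.weights)
        if abs(total - n) > 1e-9 * max(n, 1):
            raise AlignmentError(
                f"weights must sum to the sequence count ({n}); got {total}"
            )

    def __getitem__(self, seq_id: str) -> float:
        return self.weights[seq_id]


def compute_weights(aln: FamilyAlignment) -> SequenceWeights:
    """Position-based (Henikoff-style) sequence weights.

    Each column distributes one unit of weight equally among the residue
    types present there, and each type's share equally among the sequences
    carrying it; gapped sequences receive nothing from that column, so
    heavily gapped sequences are down-weighted rather than treated as a rare
    "type". The result down-weights redundant sequences, which is all the
    gap-trimming threshold requires. Weights are normalized to sum to the
    number of sequences.
    """
    mat = aln.encoded()
    n, length = mat.shape
    raw = np.zeros(n)
    for j in range(length):
        col = mat[:, j]
        residue = col != GAP_CODE
        if not residue.any():
            continue
        types, inverse, counts = np.unique(
            col[residue], return_inverse=True, return_counts=True
        )
        raw[residue] += 1.0 / (len(types) * counts[inverse])
    if raw.sum() == 0:  # all-gap alignment; fall back to uniform
        raw[:] = 1.0
    elif (raw == 0).any():  # fully gapped rows still need a positive weight
        raw[raw == 0] = raw[raw > 0].min()
    norm = raw * (n / raw.sum())
    return SequenceWeights(dict(zip(aln.ids, norm)))


@dataclass
class TrimmedAlignment:
    """Alignment restricted to columns passing the weighted-gap filter."""

    alignment: FamilyAlignment
    kept_columns: list[int]
    matrix: np.ndarray = field(repr=False)  # (n_sequences, n_kept) int8

    @property
    def ids(self) -> list[str]:
        return self.alignment.ids

    @property
    def species(self) -> list[str]:
        return self.alignment.species

    @property
    def length(self) -> int:
        return len(self.kept_columns)

    def row(self, seq_id: str) -> np.ndarray:
        return self.matrix[self.alignment.ids.index(seq_id)]


def trim_alignment(
    aln: FamilyAlignment, weights: SequenceWeights, cfg: GigaConfig = GigaConfig()
) -> TrimmedAlignment:
    """Drop columns whose weighted gap fraction exceeds the threshold.

    A column is kept iff (total weight of gapped sequences) / (total weight)
    <= ``cfg.gap_threshold``; original column order is preserved.
    """
    mat = aln.encoded()
    w = np.array([weights[i] for i in aln.ids])
    total = w.sum()
    gapped = mat == GAP_CODE
    frac = (gapped * w[:, None]).sum(axis=0) / total
    kept = [j for j in range(aln.length) if frac[j] <= cfg.gap_threshold + 1e-12]
    return TrimmedAlignment(aln, kept, mat[:, kept])


@dataclass
class DistanceMatrix:
    """Raw pairwise p-distances with comparable-site counts.

    ``p[i, j]`` is the fraction of differing residues over columns where both
    sequences carry a residue; ``n[i, j]`` counts those columns. Pairs with no
    comparable sites get p = 0 and are flagged in ``no_overlap``.
    """

    ids: list[str]
    p: np.ndarray
    n: np.ndarray
    no_overlap: np.ndarray

    def index(self, seq_id: str) -> int:
        return self.ids.index(seq_id)


def pairwise_distances(trimmed: TrimmedAlignment) -> DistanceMatrix:
    mat = trimmed.matrix
    n_seq = mat.shape[0]
    if n_seq < 2:
        raise AlignmentError("need at least two sequences for pairwise distances")
    present = mat != GAP_CODE
    p = np.zeros((n_seq, n_seq))
    counts = np.zeros((n_seq, n_seq), dtype=np.int64)
    flags = np.zeros((n_seq, n_seq), dtype=bool)
    for i in range(n_seq):
        both = present[i] & present[i + 1 :]
        n_sites = both.sum(axis=1)
        diffs = ((mat[i] != mat[i + 1 :]) & both).sum(axis=1)
        for off, j in enumerate(range(i + 1, n_seq)):
            counts[i, j] = counts[j, i] = n_sites[off]
            if n_sites[off] > 0:
                p[i, j] = p[j, i] = diffs[off] / n_sites[off]
            else:
                flags[i, j] = flags[j, i] = True
    return DistanceMatrix(list(trimmed.ids), p, counts, flags)


def jc_distance(p: float, alphabet_states: int = 20) -> float:
    """Jukes-Cantor corrected distance for an s-state alphabet.

    d = -((s-1)/s) * ln(1 - (s/(s-1)) * p).  Raises SaturationError when p is
    at or beyond (s-1)/s, where the correction diverges.
    """
    s = alphabet_states
    if p < 0:
        raise ValueError(f"p-distance must be non-negative; got {p}")
    bound = (s - 1) / s
    if p >= bound:
        raise SaturationError(f"p = {p} at or beyond the saturation bound {bound}")
    return -bound * math.log(1.0 - p / bound) + 0.0  # avoid -0.0


def jc_stddev(p: float, n: int, alphabet_states: int = 20) -> float:
    """Standard deviation of the Jukes-Cantor corrected distance.

    sd = sqrt( p(1-p) / ( n * (1 - (s/(s-1)) p)^2 ) ), the delta-method
    variance of the corrected distance from a binomial p over n sites.
    """
    s = alphabet_states
    if n < 1:
        raise ValueError("site count n must be >= 1 for a defined uncertainty")
    bound = (s - 1) / s
    if p < 0 or p >= bound:
        raise SaturationError(f"p = {p} outside [0, {bound}) for the sd formula")
    return math.sqrt(p * (1.0 - p) / (n * (1.0 - p / bound) ** 2))
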