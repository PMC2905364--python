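"""Algorithm configuration."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class GigaConfig:
    """Tunable constants of the inference procedure.

    gap_threshold
        Maximum weighted fraction of gapped sequences allowed at an alignment
        column for the column to be kept during trimming.
    fragment_coverage
        A merge-driving sequence aligning no more than this fraction of the
        sites expected in its subtree's ancestor is flagged as a fragment.
    fragment_exempt_os_size
        A sequence whose subtree already holds at least this many *other*
        sequences is never flagged as a fragment (it survived earlier tests).
    ortholog_sd_multiplier / paralog_sd_multiplier
        Significance multipliers for revising an already-dated duplication:
        the stricter one applies when the competing hypothesis implies no
        duplication (the joining group might be orthologous to the sibling),
        the looser one when the alternative itself requires a duplication.
    revision_literal_sign
        Orientation of the revision inequality. The default requires the
        joining group to be significantly closer to the group whose
        duplication date would be revised than to that group's sibling;
        flipping reverses the sign of the distance margin.
    max_branch_length
        Cap substituted for a Jukes-Cantor-saturated branch length.
    """

    gap_threshold: float = 0.15
    fragment_coverage: float = 0.5
    fragment_exempt_os_size: int = 3
    ortholog_sd_multiplier: float = 1.5
    paralog_sd_multiplier: float = 0.5
    revision_literal_sign: bool = False
    max_branch_length: float = 10.0
    alphabet_states: int = 20

    def __post_init__(self) -> None:
        for name in ("gap_threshold", "fragment_coverage"):
            value = getattr(self, name)
            if not 0.0 < value < 1.0:
                raise ValueError(f"{name} must lie in (0, 1); got {value}")
        if self.fragment_exempt_os_size < 1:
            raise ValueError("fragment_exempt_os_size must be >= 1")
        for name in ("ortholog_sd_multiplier", "paralog_sd_multiplier"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_branch_length <= 0:
            raise ValueError("max_branch_length must be positive")
        if self.alphabet_states < 2:
            raise ValueError("alphabet_states must be >= 2")
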