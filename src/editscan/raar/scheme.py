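"""Scoring scheme for realignment of variant-supporting reads."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring used to pick each read's best placement.

    An alignment is one or two pure-match blocks.  Two-block alignments
    are separated by exactly one gap: a small indel (affine cost
    ``gap_open + (g - 1) * gap_extend``, length <= ``max_indel``) or a
    reference-only intron gap of length <= ``max_intron`` at the flat
    ``intron_gap`` cost.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0
    intron_gap: float = -3.0
    max_intron: int = 50_000
    near_tie_ratio: float = 0.95
    min_seed: int = 11
    max_indel: int = 10
    #: extra reference context added around a window when searching for a
    #: spliced placement (introns extend beyond the seeded window)
    spliced_extension: int = 400

    def __post_init__(self):
        if not self.match > 0 > self.mismatch:
            raise ValueError("require match > 0 > mismatch")
        if not 0 < self.near_tie_ratio <= 1:
            raise ValueError("near_tie_ratio must be in (0, 1]")
        if self.max_intron < 1:
            raise ValueError("max_intron must be >= 1")

    def gap_cost(self, length: int) -> float:
        if length < 1:
            raise ValueError("gap length must be >= 1")
        return self.gap_open + (length - 1) * self.gap_extend


DEFAULT_SCHEME = ScoringScheme()
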