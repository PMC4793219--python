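"""Seeded genome construction: random DNA with planted gene models and
duplicated (paralog-like) segments."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..core_model.types import ExonAnnotation, ExonRecord, GenomeReference
from .spec import GenomePlan

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class Duplication:
    chrom: str
    source_start0: int
    copy_start0: int
    length: int
    divergence: float

    @property
    def source_interval(self) -> tuple[int, int]:
        return (self.source_start0, self.source_start0 + self.length)

    @property
    def copy_interval(self) -> tuple[int, int]:
        return (self.copy_start0, self.copy_start0 + self.length)


@dataclass
class FixtureLayout:
    """Where planted features live, so downstream generators avoid them."""

    chrom: str
    length: int
    genes: list[ExonRecord] = field(default_factory=list)
    duplications: list[Duplication] = field(default_factory=list)
    free_start0: int = 0
    free_end0: int = 0


def random_dna(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(seq: np.ndarray, rng: np.random.Generator,
            rate: float) -> np.ndarray:
    """Substitute each base independently with probability ``rate``."""
    out = seq.copy()
    hits = np.flatnonzero(rng.random(seq.size) < rate)
    for i in hits:
        choices = _BASES[_BASES != out[i]]
        out[i] = rng.choice(choices)
    return out


def simulate_genome_with_paralogs(plan: GenomePlan, rng: np.random.Generator,
                                  junction_overhang: int = 10,
                                  ) -> tuple[GenomeReference, ExonAnnotation,
                                             FixtureLayout]:
    """Random genome with planted gene models and duplicated segments.

    Features are laid out left to right with unique spacer sequence in
    between; the remainder of the chromosome is the free region used for
    true editing sites.  The first bases of each intron are forced to
    mismatch the downstream exon at >= 3 of the first ``junction_overhang``
    positions, so junction-overhang misalignments always create variants.
    """
    seq = random_dna(rng, plan.length)
    layout = FixtureLayout(chrom=plan.chrom, length=plan.length)
    pos = plan.margin

    for g in range(plan.n_genes):
        e1 = (pos, pos + plan.exon_length)
        intron = (e1[1], e1[1] + plan.intron_length)
        e2 = (intron[1], intron[1] + plan.exon_length)
        pos = e2[1] + plan.spacer
        if pos > plan.length:
            raise ValueError("planted features exceed genome length")
        # guarantee junction-artifact mismatches in the intron overhang
        k = min(junction_overhang, plan.intron_length)
        overhang = slice(intron[0], intron[0] + k)
        exon2_prefix = seq[e2[0]:e2[0] + k]
        mism = np.flatnonzero(seq[overhang] != exon2_prefix)
        need = 3 - mism.size
        if need > 0:
            same = np.flatnonzero(seq[overhang] == exon2_prefix)
            for t in same[:need]:
                choices = _BASES[_BASES != exon2_prefix[t]]
                seq[intron[0] + t] = rng.choice(choices)
        layout.genes.append(ExonRecord(
            chrom=plan.chrom, strand="+", exons=(e1, e2),
            transcript_id=f"tx{g:03d}"))

    for d in range(plan.n_duplications):
        src = (pos, pos + plan.duplication_length)
        pos = src[1] + plan.spacer
        dst = (pos, pos + plan.duplication_length)
        pos = dst[1] + plan.spacer
        if pos > plan.length:
            raise ValueError("planted features exceed genome length")
        copy = seq[src[0]:src[1]].copy()
        if plan.duplication_divergence > 0:
            copy = _mutate(copy, rng, plan.duplication_divergence)
        seq[dst[0]:dst[1]] = copy
        layout.duplications.append(Duplication(
            chrom=plan.chrom, source_start0=src[0], copy_start0=dst[0],
            length=plan.duplication_length,
            divergence=plan.duplication_divergence))

    layout.free_start0 = pos
    layout.free_end0 = plan.length - plan.margin
    if layout.free_end0 - layout.free_start0 < 1000:
        raise ValueError("genome too short: free region under 1 kb")

    genome = GenomeReference({plan.chrom: seq.tobytes().decode()})
    annotation = ExonAnnotation(layout.genes)
    return genome, annotation, layout
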