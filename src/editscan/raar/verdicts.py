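"""Per-read and per-variant adjudication of realignment evidence."""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from ..core_model.types import ExonAnnotation, ReadAlignment, VariantCall
from .realign import RealignmentHit
from .scheme import DEFAULT_SCHEME, ScoringScheme

CONFIRM = "CONFIRM"
REFUTE = "REFUTE"

REASONS = ("best_elsewhere", "near_tie", "spliced_better", "gapped_better",
           "alt_lost", "ok")

STATUS_PASS = "PASS"
STATUS_MULTI = "MULTI_ALIGNMENT"
STATUS_SPLICE = "SPLICE_JUNCTION"
STATUS_INDEL = "INDEL_ARTIFACT"
STATUS_LOWSUPPORT = "LOW_SUPPORT"

#: refuting-reason -> artifact class; ties break in this class order
_REASON_CLASS = {
    "best_elsewhere": STATUS_MULTI,
    "near_tie": STATUS_MULTI,
    "spliced_better": STATUS_SPLICE,
    "gapped_better": STATUS_INDEL,
    "alt_lost": STATUS_LOWSUPPORT,
}
_CLASS_TIE_ORDER = (STATUS_MULTI, STATUS_SPLICE, STATUS_INDEL, STATUS_LOWSUPPORT)


@dataclass(frozen=True)
class ReadVerdict:
    read_id: str
    status: str
    reason: str

    def __post_init__(self):
        if self.status == CONFIRM and self.reason != "ok":
            raise ValueError("CONFIRM implies reason 'ok'")
        if self.reason not in REASONS:
            raise ValueError(f"unknown reason {self.reason!r}")


@dataclass(frozen=True)
class ArtifactVerdict:
    variant: VariantCall
    status: str
    n_supporting: int
    n_confirmed: int

    @property
    def confirmed_fraction(self) -> float:
        return self.n_confirmed / self.n_supporting if self.n_supporting else 0.0


@dataclass
class RaarConfig:
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    min_confirm_frac: float = 0.90
    min_alt_reads: int = 5
    junction_window: int = 4


def extract_supporting_reads(variant: VariantCall,
                             alignments: Iterable[ReadAlignment] | Iterator[ReadAlignment],
                             ) -> list[ReadAlignment]:
    """Reads whose aligned query base at the variant position equals alt.

    Positions falling between blocks (intron/deletion gaps) do not count
    as covered.
    """
    out = []
    for read in alignments:
        if read.chrom != variant.chrom:
            continue
        if read.query_base_at(variant.pos0) == variant.alt_base:
            out.append(read)
    return out


def _nonsupport_reason(hit: RealignmentHit, variant: VariantCall,
                       query: str) -> str:
    """Why a non-supporting hit argues against the variant."""
    if hit.covers(variant.pos0):
        if hit.spliced:
            return "spliced_better"
        if hit.gapped:
            return "gapped_better"
        base = hit.query_base_at(variant.pos0, query)
        if base is not None and base != variant.alt_base:
            return "alt_lost"
    return "best_elsewhere"


def select_best_alignment(hits: list[RealignmentHit], variant: VariantCall,
                          read: ReadAlignment,
                          scheme: ScoringScheme = DEFAULT_SCHEME) -> ReadVerdict:
    """CONFIRM the read iff its best placement still carries the variant
    and no competing placement comes within the near-tie band.

    A non-supporting hit with score >= near_tie_ratio * best supporting
    score refutes the read; the refutation reason comes from the
    strongest such hit (equality counts as a tie).
    """
    if not hits:
        raise ValueError("select_best_alignment requires at least one hit "
                         "(the original locus is always a candidate)")
    query = read.query
    supporting = [h for h in hits
                  if h.supports(variant.pos0, variant.alt_base, query)]
    nonsupporting = [h for h in hits if h not in supporting]

    def first(seq):  # score descending, ties by (chrom, start0) ascending
        return sorted(seq, key=lambda h: (-h.score, h.chrom, h.start0))[0]

    if not supporting:
        return ReadVerdict(read.read_id, REFUTE,
                           _nonsupport_reason(first(hits), variant, query))

    best_sup = max(h.score for h in supporting)
    threshold = scheme.near_tie_ratio * best_sup
    violators = [h for h in nonsupporting if h.score >= threshold]
    if not violators:
        return ReadVerdict(read.read_id, CONFIRM, "ok")
    top = first(violators)
    reason = _nonsupport_reason(top, variant, query)
    if reason == "best_elsewhere" and top.score <= best_sup:
        reason = "near_tie"
    return ReadVerdict(read.read_id, REFUTE, reason)


def adjudicate_variant(variant: VariantCall, verdicts: list[ReadVerdict],
                       config: RaarConfig | None = None) -> ArtifactVerdict:
    """Variant-level pass/artifact call from its reads' verdicts."""
    config = config or RaarConfig()
    n_sup = len(verdicts)
    n_conf = sum(1 for v in verdicts if v.status == CONFIRM)
    if n_sup and (n_conf / n_sup) >= config.min_confirm_frac \
            and n_conf >= config.min_alt_reads:
        return ArtifactVerdict(variant, STATUS_PASS, n_sup, n_conf)
    classes = Counter(_REASON_CLASS[v.reason] for v in verdicts
                      if v.status == REFUTE)
    if not classes:
        return ArtifactVerdict(variant, STATUS_LOWSUPPORT, n_sup, n_conf)
    top_count = max(classes.values())
    for cls in _CLASS_TIE_ORDER:
        if classes.get(cls) == top_count:
            return ArtifactVerdict(variant, cls, n_sup, n_conf)
    raise AssertionError("unreachable")


def junction_proximity(variant: VariantCall,
                       annotation: ExonAnnotation | None) -> float:
    """Minimum absolute distance from the variant to any annotated
    exon boundary; +inf when the chromosome is unannotated."""
    if annotation is None:
        return math.inf
    boundaries = annotation.boundaries(variant.chrom)
    if not boundaries:
        return math.inf
    return min(abs(variant.pos0 - b) for b in boundaries)
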