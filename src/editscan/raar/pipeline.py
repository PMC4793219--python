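"""End-to-end artifact removal: VCF + alignments in, filtered VCF out."""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

from ..core_model.bedio import parse_interval_records
from ..core_model.samio import parse_alignment_records
from ..core_model.types import (
    ExonAnnotation,
    ExonRecord,
    GenomeReference,
    ReadAlignment,
    VariantCall,
)
from ..core_model.vcfio import parse_variant_records, write_variant_records
from .realign import KmerIndex, generate_candidate_loci, realign_read
from .verdicts import (
    STATUS_INDEL,
    STATUS_LOWSUPPORT,
    STATUS_MULTI,
    STATUS_PASS,
    STATUS_SPLICE,
    ArtifactVerdict,
    RaarConfig,
    adjudicate_variant,
    extract_supporting_reads,
    junction_proximity,
    select_best_alignment,
)

FILTER_NAMES = {
    STATUS_PASS: "PASS",
    STATUS_MULTI: "raar_multi",
    STATUS_SPLICE: "raar_splice",
    STATUS_INDEL: "raar_indel",
    STATUS_LOWSUPPORT: "raar_lowsupport",
}


@dataclass
class RaarReport:
    counts: dict[str, int] = field(default_factory=lambda: {
        name: 0 for name in FILTER_NAMES.values()})

    def tally(self, verdict: ArtifactVerdict) -> None:
        self.counts[FILTER_NAMES[verdict.status]] += 1

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_tsv(self, handle) -> None:
        close = False
        if isinstance(handle, str):
            handle, close = open(handle, "w"), True
        try:
            handle.write("filter\tn_variants\n")
            for name in FILTER_NAMES.values():
                handle.write(f"{name}\t{self.counts[name]}\n")
        finally:
            if close:
                handle.close()


class _ReadLookup:
    """Overlap queries on an in-memory read set (no index files needed)."""

    def __init__(self, reads: list[ReadAlignment]):
        self._by_chrom: dict[str, list[ReadAlignment]] = {}
        self._starts: dict[str, list[int]] = {}
        self._max_span = 0
        for read in reads:
            self._by_chrom.setdefault(read.chrom, []).append(read)
            self._max_span = max(self._max_span, read.end0 - read.start0)
        for chrom, chrom_reads in self._by_chrom.items():
            chrom_reads.sort(key=lambda r: (r.start0, r.read_id))
            self._starts[chrom] = [r.start0 for r in chrom_reads]

    def overlapping(self, chrom: str, pos0: int) -> list[ReadAlignment]:
        reads = self._by_chrom.get(chrom, [])
        if not reads:
            return []
        starts = self._starts[chrom]
        lo = bisect.bisect_left(starts, pos0 - self._max_span)
        hi = bisect.bisect_right(starts, pos0)
        return [r for r in reads[lo:hi] if r.start0 <= pos0 < r.end0]


def annotation_from_bed(path: str) -> ExonAnnotation:
    """Exon BED (one exon per line, name = transcript id) -> annotation."""
    by_tx: dict[tuple[str, str, str], list[tuple[int, int]]] = {}
    for rec in parse_interval_records(path):
        by_tx.setdefault((rec.chrom, rec.strand, rec.name), []).append(
            (rec.start0, rec.end0))
    records = []
    for (chrom, strand, name), exons in sorted(by_tx.items()):
        records.append(ExonRecord(chrom=chrom, strand=strand,
                                  exons=tuple(sorted(exons)),
                                  transcript_id=name))
    return ExonAnnotation(records)


def adjudicate_all(variants: list[VariantCall], reads: list[ReadAlignment],
                   reference: GenomeReference,
                   annotation: ExonAnnotation | None = None,
                   psl_hits: dict | None = None,
                   config: RaarConfig | None = None,
                   ) -> list[ArtifactVerdict]:
    """Adjudicate every variant against its supporting reads."""
    config = config or RaarConfig()
    scheme = config.scheme
    for read in reads:
        if read.chrom not in reference:
            raise ValueError(
                f"alignment chromosome {read.chrom!r} absent from reference")
    for variant in variants:
        if variant.chrom not in reference:
            raise ValueError(
                f"variant chromosome {variant.chrom!r} absent from reference")
    lookup = _ReadLookup(reads)
    index = KmerIndex(reference, scheme.min_seed)
    verdicts_out: list[ArtifactVerdict] = []
    hit_cache: dict[tuple[str, bool], list] = {}
    for variant in variants:
        candidates = lookup.overlapping(variant.chrom, variant.pos0)
        supporting = extract_supporting_reads(variant, candidates)
        force = junction_proximity(variant, annotation) <= config.junction_window
        read_verdicts = []
        for read in supporting:
            if psl_hits is not None and read.read_id in psl_hits:
                hits = psl_hits[read.read_id]
            else:
                cache_key = (read.read_id, force)
                hits = hit_cache.get(cache_key)
                if hits is None:
                    windows = generate_candidate_loci(
                        read, reference, scheme, index=index)
                    hits = realign_read(read, windows, reference, scheme,
                                        keep_all_modes=force)
                    hit_cache[cache_key] = hits
            read_verdicts.append(select_best_alignment(
                hits, variant, read, scheme))
        verdicts_out.append(adjudicate_variant(variant, read_verdicts, config))
    return verdicts_out


def run_raar(vcf_in: str, alignments: str, reference: GenomeReference,
             annotation: ExonAnnotation | None = None,
             psl: str | None = None,
             config: RaarConfig | None = None,
             vcf_out: str | None = None,
             report_out: str | None = None,
             sample_id: str = "SAMPLE",
             ) -> tuple[list[ArtifactVerdict], RaarReport]:
    """Run the full artifact-removal pipeline on files.

    Every input variant reappears in ``vcf_out`` with FILTER set to PASS
    or one of the raar_* artifact classes; the report counts variants per
    class.  Deterministic: identical inputs and config give byte-identical
    outputs.
    """
    from .psl import parse_psl

    config = config or RaarConfig()
    parsed = parse_variant_records(vcf_in, sample_id=sample_id)
    reads = list(parse_alignment_records(alignments))
    psl_hits = parse_psl(psl, config.scheme) if psl else None
    verdicts = adjudicate_all(parsed.calls, reads, reference, annotation,
                              psl_hits, config)
    report = RaarReport()
    filters: dict[tuple, str] = {}
    for verdict in verdicts:
        report.tally(verdict)
        filters[verdict.variant.key] = FILTER_NAMES[verdict.status]
    if vcf_out is not None:
        write_variant_records(vcf_out, parsed.calls, filters=filters,
                              contigs=reference.lengths, sample_id=sample_id)
    if report_out is not None:
        report.to_tsv(report_out)
    return verdicts, report
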