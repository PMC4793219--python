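"""Read/variant generator: true editing plus deliberately misaligned
artifact reads (paralog, splice-junction overhang, unmodeled indel).

Artifact reads are emitted pre-misaligned: the generator itself writes
the wrong ungapped alignment, because the object under test is the
artifact-removal logic, not an aligner.
"""

from __future__ import annotations

import numpy as np
import pysam

from ..core_model.types import (
    DNA_BASES,
    ExonAnnotation,
    GenomeReference,
    ReadAlignment,
    VariantCall,
)
from ..core_model.vcfio import write_variant_records
from .genome import FixtureLayout
from .spec import FixtureSpec, TruthTable

LABEL_TRUE = "true_editing"
LABEL_MULTI = "MULTI_ALIGNMENT"
LABEL_SPLICE = "SPLICE_JUNCTION"
LABEL_INDEL = "INDEL_ARTIFACT"


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = sorted(DNA_BASES - {base})
    return choices[rng.integers(0, len(choices))]


def _apply_errors(query: list[str], rng: np.random.Generator,
                  rate: float) -> None:
    if rate <= 0:
        return
    for i in np.flatnonzero(rng.random(len(query)) < rate):
        query[i] = _other_base(rng, query[i])


def _ungapped_read(read_id: str, chrom: str, start0: int, query: str,
                   ) -> ReadAlignment:
    return ReadAlignment(
        read_id=read_id, chrom=chrom, start0=start0,
        blocks=((start0, start0 + len(query), 0, len(query)),),
        strand="+", query=query, mapping_quality=60)


def _covering_start(rng: np.random.Generator, pos0: int, read_len: int,
                    margin: int) -> int:
    """Read start so that pos0 sits >= margin bases from both read ends."""
    lo = pos0 - (read_len - 1 - margin)
    hi = pos0 - margin
    return int(rng.integers(lo, hi + 1))


def simulate_reads_with_artifacts(genome: GenomeReference,
                                  annotation: ExonAnnotation,
                                  layout: FixtureLayout,
                                  spec: FixtureSpec,
                                  rng: np.random.Generator,
                                  ) -> tuple[list[ReadAlignment],
                                             list[VariantCall], TruthTable]:
    chrom = layout.chrom
    seq = genome.sequences[chrom]
    L = spec.reads.read_length
    margin = spec.reads.site_margin
    reads: list[ReadAlignment] = []
    variants: list[VariantCall] = []
    truth = TruthTable()

    # ---- true editing sites in the free region -------------------------
    step = 2 * L + 20
    cursor = layout.free_start0 + L
    mix = sorted(spec.editing.substitution_mix.items())
    subs = [s for s, _ in mix]
    probs = np.array([p for _, p in mix])
    for s in range(spec.editing.n_sites):
        sub = subs[rng.choice(len(subs), p=probs)] if subs else "A>G"
        ref_base, alt_base = sub.split(">")
        pos0 = None
        for probe in range(cursor, cursor + step - 2 * L):
            if seq[probe] == ref_base:
                pos0 = probe
                break
        cursor += step
        if pos0 is None:
            continue  # no matching base in the slot; skip (rare)
        depth = spec.editing.depth
        n_alt = int(rng.binomial(depth, spec.editing.level))
        if spec.editing.min_alt_guarantee is not None:
            n_alt = max(n_alt, spec.editing.min_alt_guarantee)
        for i in range(depth):
            start0 = _covering_start(rng, pos0, L, margin)
            query = list(seq[start0:start0 + L])
            if i < n_alt:
                query[pos0 - start0] = alt_base
            _apply_errors(query, rng, spec.reads.error_rate)
            reads.append(_ungapped_read(f"true{s:03d}_{i:03d}", chrom,
                                        start0, "".join(query)))
        variants.append(VariantCall(chrom, pos0, ref_base, alt_base,
                                    total_depth=depth, alt_depth=n_alt))
        truth.variant_labels[(chrom, pos0, ref_base, alt_base)] = LABEL_TRUE
        truth.site_levels.setdefault(
            f"{chrom}:{pos0}:{ref_base}>{alt_base}",
            {})["sample"] = spec.editing.level

    # ---- paralog (multi-alignment) artifacts ---------------------------
    # variants planted inside an exactly duplicated segment; every
    # supporting read fits entirely within the segment, so realignment
    # finds an equally good placement at the other copy
    n_paralog = spec.artifacts.n_paralog
    if n_paralog:
        if not layout.duplications:
            raise ValueError("paralog artifacts need a planted duplication")
        dup = layout.duplications[0]
        usable = dup.length - 2 * L
        if usable < n_paralog:
            raise ValueError("duplication too short for paralog plan")
        pstep = usable // n_paralog
        for a in range(n_paralog):
            pos0 = dup.source_start0 + L + a * pstep
            ref_base = seq[pos0]
            alt_base = _other_base(rng, ref_base)
            depth = spec.artifacts.depth
            for i in range(depth):
                lo = max(pos0 - (L - 1 - margin), dup.source_start0)
                hi = min(pos0 - margin, dup.source_start0 + dup.length - L)
                start0 = int(rng.integers(lo, hi + 1))
                query = list(seq[start0:start0 + L])
                query[pos0 - start0] = alt_base
                _apply_errors(query, rng, spec.reads.error_rate)
                reads.append(_ungapped_read(f"para{a:03d}_{i:03d}", chrom,
                                            start0, "".join(query)))
            variants.append(VariantCall(chrom, pos0, ref_base, alt_base,
                                        total_depth=depth, alt_depth=depth))
            truth.variant_labels[(chrom, pos0, ref_base, alt_base)] = LABEL_MULTI

    # ---- splice-junction overhang artifacts ----------------------------
    # junction-spanning reads recorded ungapped, overhanging into the
    # intron; intron bases that differ from the exon2 prefix become
    # false variants
    n_junction = spec.artifacts.n_junction
    if n_junction > len(layout.genes):
        raise ValueError("more junction artifacts than planted genes")
    h = spec.artifacts.junction_overhang
    for j in range(n_junction):
        gene = layout.genes[j]
        e1_end = gene.exons[0][1]
        e2_start = gene.exons[1][0]
        start0 = e1_end - (L - h)
        query = seq[start0:e1_end] + seq[e2_start:e2_start + h]
        for i in range(spec.artifacts.depth):
            q = list(query)
            _apply_errors(q, rng, spec.reads.error_rate)
            reads.append(_ungapped_read(f"junc{j:03d}_{i:03d}", chrom,
                                        start0, "".join(q)))
        for t in range(h):
            ref_base = seq[e1_end + t]
            alt_base = seq[e2_start + t]
            if ref_base == alt_base:
                continue
            pos0 = e1_end + t
            variants.append(VariantCall(
                chrom, pos0, ref_base, alt_base,
                total_depth=spec.artifacts.depth,
                alt_depth=spec.artifacts.depth))
            truth.variant_labels[(chrom, pos0, ref_base, alt_base)] = LABEL_SPLICE

    # ---- indel-adjacent artifacts --------------------------------------
    # reads from a deletion haplotype recorded ungapped; the frameshifted
    # tail creates false mismatch variants
    g = spec.artifacts.indel_length
    upstream = 20
    for d in range(spec.artifacts.n_indel):
        a = cursor
        cursor += step
        q_del = a + upstream  # deletion removes ref[q_del : q_del + g]
        query = seq[a:q_del] + seq[q_del + g:a + L + g]
        first_var: tuple[int, str, str] | None = None
        for t in range(upstream, L - margin):
            ref_base = seq[a + t]
            obs = query[t]
            if ref_base != obs:
                first_var = (a + t, ref_base, obs)
                break
        if first_var is None:
            continue  # tail happens to match; skip this artifact (rare)
        for i in range(spec.artifacts.depth):
            q = list(query)
            _apply_errors(q, rng, spec.reads.error_rate)
            reads.append(_ungapped_read(f"del{d:03d}_{i:03d}", chrom,
                                        a, "".join(q)))
        pos0, ref_base, alt_base = first_var
        variants.append(VariantCall(chrom, pos0, ref_base, alt_base,
                                    total_depth=spec.artifacts.depth,
                                    alt_depth=spec.artifacts.depth))
        truth.variant_labels[(chrom, pos0, ref_base, alt_base)] = LABEL_INDEL

    variants.sort(key=lambda v: (v.chrom, v.pos0, v.alt_base))
    reads.sort(key=lambda r: (r.chrom, r.start0, r.read_id))
    return reads, variants, truth


def _cigar_from_blocks(read: ReadAlignment) -> str:
    parts = []
    prev = None
    for r0, r1, q0, q1 in read.blocks:
        if prev is not None:
            pr1, pq1 = prev
            if q0 > pq1:
                parts.append(f"{q0 - pq1}I")
            if r0 > pr1:
                gap = r0 - pr1
                parts.append(f"{gap}N" if gap > 30 else f"{gap}D")
        parts.append(f"{r1 - r0}M")
        prev = (r1, q1)
    return "".join(parts)


def write_sam(path: str, reads: list[ReadAlignment],
              genome: GenomeReference) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length}
               for name, length in genome.lengths.items()],
    }
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        tid = {name: i for i, name in enumerate(genome.lengths)}
        for read in reads:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = read.read_id
            rec.query_sequence = read.query
            rec.reference_id = tid[read.chrom]
            rec.reference_start = read.start0
            rec.mapping_quality = read.mapping_quality
            rec.cigarstring = _cigar_from_blocks(read)
            rec.flag = 16 if read.strand == "-" else 0
            out.write(rec)


def write_vcf(path: str, variants: list[VariantCall],
              genome: GenomeReference, sample_id: str = "SAMPLE") -> None:
    write_variant_records(path, variants, contigs=genome.lengths,
                          sample_id=sample_id)
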