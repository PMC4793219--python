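"""SAM/BAM reading via pysam, normalized to ReadAlignment blocks."""

from __future__ import annotations

from typing import Iterator

import pysam

from .types import ReadAlignment

# CIGAR operation codes (pysam numeric encoding)
_OP_M, _OP_I, _OP_D, _OP_N, _OP_S, _OP_H, _OP_P, _OP_EQ, _OP_X = range(9)

_CONSUMES_QUERY = {_OP_M, _OP_I, _OP_S, _OP_EQ, _OP_X}
_CONSUMES_REF = {_OP_M, _OP_D, _OP_N, _OP_EQ, _OP_X}
_ALIGNED = {_OP_M, _OP_EQ, _OP_X}


class SamRecordError(ValueError):
    pass


def blocks_from_cigar(cigar: list[tuple[int, int]], start0: int,
                      query_length: int) -> tuple[tuple[int, int, int, int], ...]:
    """Convert a CIGAR into pure-match blocks.

    M/=/X runs become blocks; I/D/N/S consume only their own coordinate;
    H/P consume neither.  Adjacent aligned runs merge.
    """
    blocks: list[list[int]] = []
    rpos, qpos = start0, 0
    for op, length in cigar:
        if op in _ALIGNED:
            if blocks and blocks[-1][1] == rpos and blocks[-1][3] == qpos:
                blocks[-1][1] += length
                blocks[-1][3] += length
            else:
                blocks.append([rpos, rpos + length, qpos, qpos + length])
        if op in _CONSUMES_REF:
            rpos += length
        if op in _CONSUMES_QUERY:
            qpos += length
    if qpos != query_length:
        raise SamRecordError(
            f"CIGAR consumes {qpos} query bases but sequence has {query_length}")
    return tuple(tuple(b) for b in blocks)


def parse_alignment_records(path: str, region: tuple[str, int, int] | None = None,
                            ) -> Iterator[ReadAlignment]:
    """Iterate mapped, non-duplicate reads as ReadAlignment records.

    ``region`` is an optional (chrom, start0, end0) filter applied by
    overlap of the read's reference span (no index required, so plain
    text SAM works).
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_duplicate or rec.is_secondary \
                    or rec.is_supplementary:
                continue
            seq = rec.query_sequence
            if seq is None or rec.cigartuples is None:
                continue
            if region is not None:
                chrom, start0, end0 = region
                if rec.reference_name != chrom:
                    continue
                if rec.reference_end <= start0 or rec.reference_start >= end0:
                    continue
            blocks = blocks_from_cigar(rec.cigartuples, rec.reference_start,
                                       len(seq))
            yield ReadAlignment(
                read_id=rec.query_name,
                chrom=rec.reference_name,
                start0=rec.reference_start,
                blocks=blocks,
                strand="-" if rec.is_reverse else "+",
                query=seq.upper(),
                mapping_quality=rec.mapping_quality,
            )
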