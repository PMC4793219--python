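"""Blat PSL (21-column) import: external realignments override the
internal realigner for reads present in the file."""

from __future__ import annotations

from typing import IO

from .realign import RealignmentHit
from .scheme import DEFAULT_SCHEME, ScoringScheme


class PslRecordError(ValueError):
    pass


def _score_from_blocks(matches: int, mismatches: int, ref_gaps: list[int],
                       query_gaps: list[int], scheme: ScoringScheme) -> float:
    score = matches * scheme.match + mismatches * scheme.mismatch
    for g in ref_gaps:
        if g > scheme.max_indel:
            score += scheme.intron_gap
        else:
            score += scheme.gap_cost(g)
    for g in query_gaps:
        score += scheme.gap_cost(g)
    return score


def parse_psl(stream: IO[str] | str,
              scheme: ScoringScheme = DEFAULT_SCHEME,
              ) -> dict[str, list[RealignmentHit]]:
    """Parse PSL text into per-read RealignmentHit lists.

    Scores are recomputed under the scoring scheme so external hits are
    comparable with internal ones.  Header lines (psLayout banner) are
    skipped.
    """
    close = False
    if isinstance(stream, str):
        stream, close = open(stream), True
    hits: dict[str, list[RealignmentHit]] = {}
    try:
        for lineno, raw in enumerate(stream, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if not fields[0].isdigit():
                continue  # header / banner
            if len(fields) < 21:
                raise PslRecordError(f"line {lineno}: expected 21 columns")
            matches = int(fields[0])
            mismatches = int(fields[1])
            strand = fields[8]
            qname = fields[9]
            tname = fields[13]
            block_sizes = [int(x) for x in fields[18].rstrip(",").split(",")]
            q_starts = [int(x) for x in fields[19].rstrip(",").split(",")]
            t_starts = [int(x) for x in fields[20].rstrip(",").split(",")]
            blocks = tuple(
                (t, t + size, q, q + size)
                for size, q, t in zip(block_sizes, q_starts, t_starts))
            ref_gaps, query_gaps = [], []
            for (_, r1, _, q1), (r0n, _, q0n, _) in zip(blocks, blocks[1:]):
                if r0n > r1:
                    ref_gaps.append(r0n - r1)
                if q0n > q1:
                    query_gaps.append(q0n - q1)
            score = _score_from_blocks(matches, mismatches, ref_gaps,
                                       query_gaps, scheme)
            aligned = sum(b[1] - b[0] for b in blocks)
            hits.setdefault(qname, []).append(RealignmentHit(
                chrom=tname, start0=blocks[0][0], end0=blocks[-1][1],
                strand=strand[0], blocks=blocks, score=score,
                identity=matches / aligned if aligned else 0.0,
                spliced=any(g > scheme.max_indel for g in ref_gaps),
                gapped=any(g <= scheme.max_indel for g in ref_gaps)
                or bool(query_gaps),
            ))
    finally:
        if close:
            stream.close()
    for read_hits in hits.values():
        read_hits.sort(key=lambda h: (-h.score, h.chrom, h.start0))
    return hits
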