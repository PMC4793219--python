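"""Realignment of variant-supporting reads.

Replaces an external whole-genome realigner: candidate loci come from
exact k-mer seeding against the reference, and each candidate window is
scored with a vectorized local dynamic program in three modes (ungapped,
one small indel, one intron gap).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core_model.types import GenomeReference, ReadAlignment
from .scheme import DEFAULT_SCHEME, ScoringScheme

NEG = -1e18


@dataclass(frozen=True)
class RealignmentHit:
    """A scored placement of one read."""

    chrom: str
    start0: int
    end0: int
    strand: str
    blocks: tuple[tuple[int, int, int, int], ...]
    score: float
    identity: float
    spliced: bool = False
    gapped: bool = False

    def covers(self, pos0: int) -> bool:
        return self.start0 <= pos0 < self.end0

    def query_base_at(self, pos0: int, query: str) -> str | None:
        for r0, r1, q0, _q1 in self.blocks:
            if r0 <= pos0 < r1:
                return query[q0 + (pos0 - r0)]
        return None

    def supports(self, pos0: int, alt_base: str, query: str) -> bool:
        return self.query_base_at(pos0, query) == alt_base


class KmerIndex:
    """Exact-match k-mer lookup over a reference genome."""

    def __init__(self, genome: GenomeReference, k: int):
        self.k = k
        self.genome = genome
        self._index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in genome.sequences.items():
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos:pos + k]
                if "N" in kmer:
                    continue
                self._index.setdefault(kmer, []).append((chrom, pos))

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, [])


def generate_candidate_loci(read: ReadAlignment, reference: GenomeReference,
                            scheme: ScoringScheme = DEFAULT_SCHEME,
                            index: KmerIndex | None = None,
                            diagonal_tolerance: int = 8,
                            ) -> list[tuple[str, int, int]]:
    """Candidate windows that may harbor a better placement of the read.

    Seeds are all ``min_seed``-mers of the query; hits cluster by
    (chromosome, diagonal); each cluster becomes a window padded by the
    read length.  The read's original locus is always included.
    """
    n = len(read.query)
    pad = n
    windows: list[tuple[str, int, int]] = []

    def clip(chrom: str, lo: int, hi: int) -> tuple[str, int, int]:
        return (chrom, max(0, lo), min(reference.lengths[chrom], hi))

    if read.chrom in reference:
        windows.append(clip(read.chrom, read.start0 - pad, read.end0 + pad))

    k = scheme.min_seed
    if n >= k:
        if index is None:
            index = KmerIndex(reference, k)
        seeds: list[tuple[str, int, int]] = []  # (chrom, diagonal, qpos)
        for qpos in range(n - k + 1):
            for chrom, pos in index.lookup(read.query[qpos:qpos + k]):
                seeds.append((chrom, pos - qpos, qpos))
        seeds.sort()
        cluster: list[tuple[str, int, int]] = []
        for seed in seeds + [("\xff", 1 << 60, 0)]:  # sentinel flushes last
            if cluster and (seed[0] != cluster[-1][0]
                            or seed[1] - cluster[-1][1] > diagonal_tolerance):
                diags = [d for _, d, _ in cluster]
                chrom = cluster[0][0]
                windows.append(clip(chrom, min(diags) - pad, max(diags) + n + pad))
                cluster = []
            if seed[0] != "\xff":
                cluster.append(seed)

    # merge overlapping windows per chromosome
    windows.sort()
    merged: list[tuple[str, int, int]] = []
    for chrom, lo, hi in windows:
        if merged and merged[-1][0] == chrom and lo <= merged[-1][2]:
            merged[-1] = (chrom, merged[-1][1], max(merged[-1][2], hi))
        else:
            merged.append((chrom, lo, hi))
    return [tuple(w) for w in merged]


def _block_stats(query: str, ref: str, blocks, ref_offset: int) -> tuple[float, int]:
    """(matches, aligned columns) over blocks; ref coords are genome-absolute."""
    matches = 0
    cols = 0
    for r0, r1, q0, q1 in blocks:
        for i in range(r1 - r0):
            cols += 1
            if query[q0 + i] == ref[r0 - ref_offset + i]:
                matches += 1
    return matches, cols


def _ending_blocks(q: np.ndarray, w: np.ndarray, match: float, mismatch: float):
    """Kadane-style DP: best single block ending exactly at each (qi, ri).

    Returns (E, Eq, Er) where E[qi, ri] is the best score of a block whose
    query end is qi and ref end is ri (both exclusive), and (Eq, Er) are
    the block's start coordinates.
    """
    n, m = len(q), len(w)
    E = np.full((n + 1, m + 1), NEG)
    Eq = np.zeros((n + 1, m + 1), dtype=np.int64)
    Er = np.zeros((n + 1, m + 1), dtype=np.int64)
    for i in range(1, n + 1):
        s = np.where(q[i - 1] == w, match, mismatch)  # length m
        prev = E[i - 1, :-1]
        extend = prev > 0
        E[i, 1:] = s + np.where(extend, prev, 0.0)
        Eq[i, 1:] = np.where(extend, Eq[i - 1, :-1], i - 1)
        Er[i, 1:] = np.where(extend, Er[i - 1, :-1], np.arange(m))
    return E, Eq, Er


def _starting_blocks(q: np.ndarray, w: np.ndarray, match: float, mismatch: float):
    """Mirror of _ending_blocks: best block starting exactly at (qi, ri),
    with (Sq, Sr) the block's end coordinates (exclusive)."""
    n, m = len(q), len(w)
    S = np.full((n + 1, m + 1), NEG)
    Sq = np.zeros((n + 1, m + 1), dtype=np.int64)
    Sr = np.zeros((n + 1, m + 1), dtype=np.int64)
    for i in range(n - 1, -1, -1):
        s = np.where(q[i] == w, match, mismatch)  # length m
        nxt = S[i + 1, 1:]
        extend = nxt > 0
        S[i, :-1] = s + np.where(extend, nxt, 0.0)
        Sq[i, :-1] = np.where(extend, Sq[i + 1, 1:], i + 1)
        Sr[i, :-1] = np.where(extend, Sr[i + 1, 1:], np.arange(1, m + 1))
    return S, Sq, Sr


def _best_window_alignments(query: str, window_seq: str, scheme: ScoringScheme):
    """Best alignment per mode within one window.

    Returns dict mode -> (score, blocks) with window-relative ref
    coordinates, or None when no alignment of that mode exists.
    """
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    w = np.frombuffer(window_seq.encode(), dtype=np.uint8)
    n, m = len(q), len(w)
    out: dict[str, tuple[float, tuple] | None] = {
        "ungapped": None, "gapped": None, "spliced": None}
    if n == 0 or m == 0:
        return out
    E, Eq, Er = _ending_blocks(q, w, scheme.match, scheme.mismatch)
    S, Sq, Sr = _starting_blocks(q, w, scheme.match, scheme.mismatch)

    # ungapped: single block
    flat = int(np.argmax(E))
    qi, ri = divmod(flat, m + 1)
    if E[qi, ri] > NEG / 2:
        blocks = ((int(Er[qi, ri]), ri, int(Eq[qi, ri]), qi),)
        out["ungapped"] = (float(E[qi, ri]), blocks)

    def two_block(left_qi, left_ri, right_qi, right_ri, extra):
        lb = (int(Er[left_qi, left_ri]), left_ri, int(Eq[left_qi, left_ri]), left_qi)
        rb = (right_ri, int(Sr[right_qi, right_ri]), right_qi,
              int(Sq[right_qi, right_ri]))
        return (float(E[left_qi, left_ri] + S[right_qi, right_ri] + extra),
                (lb, rb))

    # gapped: one indel between two blocks
    best_gapped = None
    for qi in range(1, n):
        erow = E[qi]
        # deletion: query contiguous at qi, ref gap g
        for g in range(1, min(scheme.max_indel, m - 1) + 1):
            srow = S[qi]
            # left ends at ref ri (1..m-g-? ), right starts at ref ri+g
            vec = erow[1:m + 1 - g] + srow[1 + g:m + 1]
            j = int(np.argmax(vec))
            val = vec[j] + scheme.gap_cost(g)
            if val > NEG / 2 and (best_gapped is None or val > best_gapped[0]):
                best_gapped = (val, qi, j + 1, qi, j + 1 + g, g, "del")
        # insertion: ref contiguous, query gap g
        for g in range(1, min(scheme.max_indel, n - qi - 1) + 1):
            srow = S[qi + g]
            vec = erow[1:m] + srow[1:m]
            j = int(np.argmax(vec))
            val = vec[j] + scheme.gap_cost(g)
            if val > NEG / 2 and (best_gapped is None or val > best_gapped[0]):
                best_gapped = (val, qi, j + 1, qi + g, j + 1, g, "ins")
    if best_gapped is not None:
        val, lqi, lri, rqi, rri, g, kind = best_gapped
        score, blocks = two_block(lqi, lri, rqi, rri,
                                  scheme.gap_cost(g))
        out["gapped"] = (score, blocks)

    # spliced: one reference-only gap of any length >= 1 (flat cost);
    # max_intron never binds at window scale
    best_spliced = None
    for qi in range(1, n):
        erow = E[qi]
        pref = np.maximum.accumulate(erow)          # max over ri' <= ri
        pref_arg = np.maximum.accumulate(
            np.where(erow == pref, np.arange(m + 1), 0))
        srow = S[qi]
        # right block starts at ref rj = r + 1; left ends at ri <= rj - 1 = r
        cand = pref[:m] + srow[1:m + 1] + scheme.intron_gap
        r = int(np.argmax(cand))
        val = cand[r]
        ri = int(pref_arg[r])
        if val > NEG / 2 and ri >= 1 and (best_spliced is None
                                          or val > best_spliced[0]):
            best_spliced = (val, qi, ri, qi, r + 1)
    if best_spliced is not None:
        val, lqi, lri, rqi, rri = best_spliced
        score, blocks = two_block(lqi, lri, rqi, rri, scheme.intron_gap)
        out["spliced"] = (score, blocks)
    return out


def realign_read(read: ReadAlignment, windows: list[tuple[str, int, int]],
                 reference: GenomeReference,
                 scheme: ScoringScheme = DEFAULT_SCHEME,
                 keep_all_modes: bool = False) -> list[RealignmentHit]:
    """Best local placement of the read in each candidate window.

    Per window the single highest-scoring mode survives (ties prefer
    ungapped, then gapped, then spliced) unless ``keep_all_modes`` is
    set, in which case every mode's best hit is reported.  Hits are
    sorted by score descending, ties by (chrom, start0) ascending.
    """
    query = read.query
    hits: list[RealignmentHit] = []
    for chrom, w0, w1 in windows:
        ext0 = max(0, w0 - scheme.spliced_extension)
        ext1 = min(reference.lengths[chrom], w1 + scheme.spliced_extension)
        window_seq = reference.fetch(chrom, ext0, ext1)
        per_mode = _best_window_alignments(query, window_seq, scheme)

        def make_hit(mode: str, score: float, blocks) -> RealignmentHit:
            abs_blocks = tuple((r0 + ext0, r1 + ext0, q0, q1)
                               for r0, r1, q0, q1 in blocks)
            matches, cols = _block_stats(query, window_seq,
                                         abs_blocks, ext0)
            return RealignmentHit(
                chrom=chrom, start0=abs_blocks[0][0], end0=abs_blocks[-1][1],
                strand="+", blocks=abs_blocks, score=score,
                identity=matches / cols if cols else 0.0,
                spliced=(mode == "spliced"), gapped=(mode == "gapped"))

        mode_hits = {mode: res for mode, res in per_mode.items()
                     if res is not None}
        if not mode_hits:
            continue
        if keep_all_modes:
            for mode, (score, blocks) in mode_hits.items():
                hits.append(make_hit(mode, score, blocks))
        else:
            order = {"ungapped": 0, "gapped": 1, "spliced": 2}
            best_mode = min(mode_hits,
                            key=lambda mo: (-mode_hits[mo][0], order[mo]))
            score, blocks = mode_hits[best_mode]
            hits.append(make_hit(best_mode, score, blocks))
    hits.sort(key=lambda h: (-h.score, h.chrom, h.start0))
    return hits
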