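"""Independent alignment oracle for realignment equivalence tests.

Two routes, neither sharing code with the package DP:

* ``brute_best``: literal enumeration of every one- and two-block local
  alignment (loops over all block coordinates) — feasible only for tiny
  inputs, used to certify the oracle itself.
* ``oracle_best``: exhaustive max over the same alignment space computed
  from per-diagonal cumulative sums (block score = difference of two
  cumsum entries) combined across explicit gap geometries.
"""

from __future__ import annotations

import numpy as np

NEG = -1e15


def brute_best(q: str, w: str, scheme) -> dict[str, float | None]:
    n, m = len(q), len(w)

    def seg(qs, rs, L):
        return sum(scheme.match if q[qs + i] == w[rs + i] else scheme.mismatch
                   for i in range(L))

    best: dict[str, float | None] = {"ungapped": None, "gapped": None,
                                     "spliced": None}

    def upd(mode, val):
        if best[mode] is None or val > best[mode]:
            best[mode] = val

    for qs in range(n):
        for rs in range(m):
            for L in range(1, min(n - qs, m - rs) + 1):
                upd("ungapped", seg(qs, rs, L))
    for qs in range(n):
        for rs in range(m):
            for L1 in range(1, min(n - qs, m - rs) + 1):
                qe, re_ = qs + L1, rs + L1
                left = seg(qs, rs, L1)
                for g in range(1, m - re_):
                    for L2 in range(1, min(n - qe, m - re_ - g) + 1):
                        right = seg(qe, re_ + g, L2)
                        if g <= scheme.max_indel:
                            upd("gapped", left + right + scheme.gap_cost(g))
                        upd("spliced", left + right + scheme.intron_gap)
                for g in range(1, min(scheme.max_indel, n - qe - 1) + 1):
                    for L2 in range(1, min(n - qe - g, m - re_) + 1):
                        upd("gapped",
                            left + seg(qe + g, re_, L2) + scheme.gap_cost(g))
    return best


def _block_tables(q: str, w: str, scheme) -> tuple[np.ndarray, np.ndarray]:
    """END[qi, ri]: best single block with query end qi / ref end ri
    (exclusive); START[qi, ri]: best block starting at (qi, ri).

    Built per diagonal from cumulative sums: a block from offset a to b
    scores c[b] - c[a], so the best block ending at b is
    c[b] - min(c[:b]) and the best starting at a is max(c[a:]) - c[a].
    """
    n, m = len(q), len(w)
    qa = np.frombuffer(q.encode(), dtype=np.uint8)
    wa = np.frombuffer(w.encode(), dtype=np.uint8)
    END = np.full((n + 1, m + 1), NEG)
    START = np.full((n + 1, m + 1), NEG)
    for d in range(-(n - 1), m):
        qs = max(0, -d)
        rs = max(0, d)
        L = min(n - qs, m - rs)
        if L <= 0:
            continue
        s = np.where(qa[qs:qs + L] == wa[rs:rs + L],
                     scheme.match, scheme.mismatch)
        c = np.concatenate(([0.0], np.cumsum(s)))
        run_min = np.minimum.accumulate(c[:-1])
        run_max = np.maximum.accumulate(c[::-1])[::-1][1:]
        ends = c[1:] - run_min
        starts = run_max - c[:-1]
        idx = np.arange(L)
        END[qs + 1 + idx, rs + 1 + idx] = ends
        START[qs + idx, rs + idx] = starts
    return END, START


def oracle_best(q: str, w: str, scheme) -> dict[str, float | None]:
    n, m = len(q), len(w)
    if n == 0 or m == 0:
        return {"ungapped": None, "gapped": None, "spliced": None}
    END, START = _block_tables(q, w, scheme)

    def opt(val):
        return None if val < NEG / 2 else float(val)

    ungapped = END.max()

    gapped = NEG
    for qi in range(1, n):
        for g in range(1, scheme.max_indel + 1):
            if g < m:  # deletion: ref gap g at query boundary qi
                vals = END[qi, 1:m + 1 - g] + START[qi, 1 + g:m + 1] \
                    + scheme.gap_cost(g)
                gapped = max(gapped, vals.max(initial=NEG))
            if qi + g < n:  # insertion: query gap g, ref contiguous
                vals = END[qi, 1:m] + START[qi + g, 1:m] + scheme.gap_cost(g)
                gapped = max(gapped, vals.max(initial=NEG))

    spliced = NEG
    for qi in range(1, n):
        pref = np.maximum.accumulate(END[qi])
        vals = pref[1:m] + START[qi, 2:m + 1] + scheme.intron_gap
        if vals.size:
            spliced = max(spliced, vals.max())

    return {"ungapped": opt(ungapped), "gapped": opt(gapped),
            "spliced": opt(spliced)}
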