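"""Editing site/event/level quantification.

Implements the two-step detection scheme: a stringent per-sample site
call (>= 5 supporting reads and >= 5% allele frequency, both inclusive),
then a relaxed re-retrieval of events at those sites requiring only
>= 10 reads of total coverage (zero-level events retained).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core_model.types import (
    SUBSTITUTION_TYPES,
    EditingEvent,
    EditingMatrix,
    EditingSite,
    ReadAlignment,
    VariantCall,
)


@dataclass(frozen=True)
class CallThresholds:
    min_alt_reads: int = 5
    min_af: float = 0.05
    dna_af_cut: float = 0.05
    relaxed_min_depth: int = 10

    def __post_init__(self):
        if self.min_alt_reads < 0 or self.relaxed_min_depth < 0:
            raise ValueError("read thresholds must be non-negative")
        if not (0 <= self.min_af <= 1 and 0 <= self.dna_af_cut <= 1):
            raise ValueError("fraction thresholds must be in [0, 1]")


DEFAULT_THRESHOLDS = CallThresholds()


@dataclass(frozen=True)
class SpectrumTable:
    """Counts and frequencies over the 12 substitution types."""

    counts: dict[str, int]
    total: int

    @property
    def frequencies(self) -> dict[str, float]:
        if self.total == 0:
            return {t: float("nan") for t in SUBSTITUTION_TYPES}
        return {t: self.counts[t] / self.total for t in SUBSTITUTION_TYPES}

    @property
    def empty(self) -> bool:
        return self.total == 0


@dataclass(frozen=True)
class LevelHistogram:
    """Editing-level distribution in 5-percentage-point bins with a
    centered window-3 moving average (2-term means at the edges)."""

    bin_edges: tuple[float, ...]
    raw: tuple[float, ...]
    smoothed: tuple[float, ...]


def apply_dna_filter(rna_variants: Sequence[VariantCall],
                     dna_variants: Sequence[VariantCall],
                     thresholds: CallThresholds = DEFAULT_THRESHOLDS,
                     ) -> tuple[list[VariantCall], list[VariantCall]]:
    """Drop RNA variants whose paired-DNA allele frequency is >= the cut
    (inclusive).  Variants with no DNA record at the position are kept
    and flagged "dna_uncovered"."""
    dna_by_key = {(v.chrom, v.pos0, v.alt_base): v for v in dna_variants}
    dna_positions = {(v.chrom, v.pos0) for v in dna_variants}
    kept, removed = [], []
    for rna in rna_variants:
        dna = dna_by_key.get((rna.chrom, rna.pos0, rna.alt_base))
        if dna is not None and dna.allele_frequency >= thresholds.dna_af_cut:
            removed.append(rna)
        elif (rna.chrom, rna.pos0) not in dna_positions:
            kept.append(rna.with_flags("dna_uncovered"))
        else:
            kept.append(rna)
    return kept, removed


def call_editing_sites(variants_by_sample: Mapping[str, Sequence[VariantCall]],
                       thresholds: CallThresholds = DEFAULT_THRESHOLDS,
                       ) -> list[EditingSite]:
    """Stringent site calls: a substitution is a site iff some sample has
    alt reads >= min_alt_reads AND allele frequency >= min_af (both
    inclusive)."""
    sites: dict[tuple, EditingSite] = {}
    for variants in variants_by_sample.values():
        for v in variants:
            if v.alt_depth >= thresholds.min_alt_reads \
                    and v.allele_frequency >= thresholds.min_af:
                sites.setdefault(v.key, EditingSite(
                    chrom=v.chrom, pos0=v.pos0,
                    ref_base=v.ref_base, alt_base=v.alt_base))
    return [sites[k] for k in sorted(sites)]


def substitution_spectrum(events: Iterable[EditingEvent | VariantCall],
                          ) -> SpectrumTable:
    """Pooled frequency of substitution types, as stored on the +
    reference strand (unstranded view)."""
    counts = Counter()
    for ev in events:
        if isinstance(ev, EditingEvent):
            ref, alt = ev.site.ref_base, ev.site.alt_base
        else:
            ref, alt = ev.ref_base, ev.alt_base
        counts[f"{ref}>{alt}"] += 1
    full = {t: counts.get(t, 0) for t in SUBSTITUTION_TYPES}
    return SpectrumTable(counts=full, total=sum(full.values()))


def moving_average3(values: Sequence[float]) -> list[float]:
    """Centered window-3 mean; the two edge positions use the mean of the
    two available terms."""
    v = list(values)
    if len(v) <= 2:
        return [float(np.mean(v))] * len(v) if v else []
    out = [(v[0] + v[1]) / 2.0]
    for i in range(1, len(v) - 1):
        out.append((v[i - 1] + v[i] + v[i + 1]) / 3.0)
    out.append((v[-2] + v[-1]) / 2.0)
    return out


def level_histogram(events: Iterable[EditingEvent],
                    bin_width: float = 5.0,
                    smooth_window: int = 3) -> LevelHistogram:
    """Histogram of editing levels (x in percent, [k*w, (k+1)*w) bins,
    last bin closed at 100)."""
    if smooth_window != 3:
        raise ValueError("only the window-3 moving average is supported")
    levels = np.array([ev.level * 100.0 for ev in events], dtype=float)
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    counts, _ = np.histogram(levels, bins=edges)  # np.histogram closes last bin
    total = counts.sum()
    raw = counts / total if total else np.zeros_like(counts, dtype=float)
    return LevelHistogram(bin_edges=tuple(edges), raw=tuple(raw),
                          smoothed=tuple(moving_average3(raw)))


def pileup_counts(reads: Iterable[ReadAlignment],
                  sites: Sequence[EditingSite],
                  ) -> dict[str, tuple[int, int]]:
    """Minimal pileup for fixtures: (depth, alt reads) per site key over
    an in-memory read set.  A read covers a site only via an aligned
    block."""
    out = {s.key: [0, 0] for s in sites}
    by_chrom: dict[str, list[EditingSite]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s)
    for read in reads:
        for site in by_chrom.get(read.chrom, []):
            base = read.query_base_at(site.pos0)
            if base is None:
                continue
            cell = out[site.key]
            cell[0] += 1
            if base == site.alt_base:
                cell[1] += 1
    return {k: (d, a) for k, (d, a) in out.items()}


def relaxed_retrieval(sites: Sequence[EditingSite],
                      pileups: Mapping[str, Mapping[str, tuple[int, int]]],
                      thresholds: CallThresholds = DEFAULT_THRESHOLDS,
                      ) -> EditingMatrix:
    """Re-examine confident sites in every sample at a relaxed threshold.

    ``pileups`` maps sample -> site key -> (depth, alt reads).  A cell is
    kept iff depth >= relaxed_min_depth (strict "lower than" discard), so
    zero-level events are retained; everything else is MISSING.
    """
    samples = list(pileups)
    keys = [s.key for s in sites]
    matrix = EditingMatrix.empty(keys, samples)
    for j, sample in enumerate(samples):
        per_site = pileups[sample]
        for i, key in enumerate(keys):
            if key not in per_site:
                continue
            depth, alt = per_site[key]
            if depth >= thresholds.relaxed_min_depth:
                matrix.set_cell(i, j, depth, alt / depth)
    return matrix
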