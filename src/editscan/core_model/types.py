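"""Domain types shared across the toolkit.

All genomic coordinates are 0-based half-open internally.  1-based
conventions (VCF POS, catalog positions) exist only at the I/O boundary.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

DNA_BASES = frozenset("ACGT")
DNA_ALPHABET = frozenset("ACGTN")

#: the 12 possible single-base substitutions, in fixed display order
SUBSTITUTION_TYPES = tuple(
    f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a
)

REGION_LABELS = frozenset({"coding", "3UTR", "5UTR", "intron", "intergenic", "unknown"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


class GenomeReference:
    """In-memory reference genome: uppercase A/C/G/T/N strings per chromosome."""

    def __init__(self, sequences: Mapping[str, str]):
        self.sequences: dict[str, str] = {}
        for name, seq in sequences.items():
            if name in self.sequences:
                raise ValueError(f"duplicate chromosome name: {name}")
            seq = seq.upper()
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise ValueError(
                    f"chromosome {name} contains non-DNA characters: {sorted(bad)}"
                )
            self.sequences[name] = seq
        self.lengths = {name: len(seq) for name, seq in self.sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def fetch(self, chrom: str, start0: int, end0: int) -> str:
        """Subsequence in 0-based half-open coordinates, clipped to bounds."""
        seq = self.sequences[chrom]
        return seq[max(0, start0):max(0, end0)]

    def base(self, chrom: str, pos0: int) -> str:
        return self.sequences[chrom][pos0]

    @property
    def chromosomes(self) -> list[str]:
        return list(self.sequences)


@dataclass(frozen=True)
class ExonRecord:
    """One transcript: ordered, disjoint exon intervals on one strand."""

    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    transcript_id: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"empty exon ({s},{e}) in {self.transcript_id}")
            if prev_end is not None and s <= prev_end:
                # adjacency (s == prev_end) would mean a zero-length intron
                raise ValueError(
                    f"exons not sorted/disjoint with intron >=1 in {self.transcript_id}"
                )
            prev_end = e

    @property
    def boundaries(self) -> list[int]:
        out = []
        for s, e in self.exons:
            out.extend((s, e))
        return out


class ExonAnnotation:
    """Exon-intron structure, indexed by chromosome."""

    def __init__(self, records: Iterable[ExonRecord]):
        self.records = list(records)
        self._by_chrom: dict[str, list[ExonRecord]] = {}
        for rec in self.records:
            self._by_chrom.setdefault(rec.chrom, []).append(rec)

    def for_chrom(self, chrom: str) -> list[ExonRecord]:
        return self._by_chrom.get(chrom, [])

    def boundaries(self, chrom: str) -> list[int]:
        out: list[int] = []
        for rec in self.for_chrom(chrom):
            out.extend(rec.boundaries)
        return sorted(set(out))


@dataclass(frozen=True)
class VariantCall:
    """A candidate single-base substitution in one sample."""

    chrom: str
    pos0: int
    ref_base: str
    alt_base: str
    total_depth: int
    alt_depth: int
    sample_id: str = ""
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        if self.ref_base not in DNA_BASES or self.alt_base not in DNA_BASES:
            raise ValueError(f"bases must be A/C/G/T: {self.ref_base}>{self.alt_base}")
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt bases are identical")
        if self.total_depth <= 0:
            raise ValueError("total_depth must be positive")
        if not 0 <= self.alt_depth <= self.total_depth:
            raise ValueError("alt_depth outside [0, total_depth]")

    @property
    def allele_frequency(self) -> float:
        return self.alt_depth / self.total_depth

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos0, self.ref_base, self.alt_base)

    def with_flags(self, *flags: str) -> "VariantCall":
        return VariantCall(
            self.chrom, self.pos0, self.ref_base, self.alt_base,
            self.total_depth, self.alt_depth, self.sample_id,
            self.flags + tuple(flags),
        )


@dataclass(frozen=True)
class ReadAlignment:
    """Normal form of one aligned read.

    ``blocks`` are pure-match/mismatch runs as
    (ref_start0, ref_end0, query_start0, query_end0); indels and introns
    appear only between blocks.
    """

    read_id: str
    chrom: str
    start0: int
    blocks: tuple[tuple[int, int, int, int], ...]
    strand: str
    query: str
    mapping_quality: int = 0

    def __post_init__(self):
        prev_r = prev_q = -1
        for r0, r1, q0, q1 in self.blocks:
            if r1 - r0 != q1 - q0:
                raise ValueError("block reference and query spans differ")
            if r1 <= r0:
                raise ValueError("empty block")
            if r0 < prev_r or q0 < prev_q:
                raise ValueError("blocks overlap or are unsorted")
            if q1 > len(self.query):
                raise ValueError("block query coordinates exceed sequence length")
            prev_r, prev_q = r1, q1

    @property
    def end0(self) -> int:
        return self.blocks[-1][1] if self.blocks else self.start0

    def query_base_at(self, pos0: int) -> str | None:
        """Query base aligned to reference pos0, or None if pos0 is not
        inside an aligned block (e.g. falls in an intron gap)."""
        for r0, r1, q0, _q1 in self.blocks:
            if r0 <= pos0 < r1:
                return self.query[q0 + (pos0 - r0)]
        return None


@dataclass(frozen=True)
class EditingSite:
    chrom: str
    pos0: int
    strand: str = "+"
    ref_base: str = "A"
    alt_base: str = "G"
    region: str = "unknown"
    gene: str | None = None

    def __post_init__(self):
        if self.region not in REGION_LABELS:
            raise ValueError(f"unknown region label {self.region!r}")
        if self.ref_base not in DNA_BASES or self.alt_base not in DNA_BASES:
            raise ValueError("bases must be A/C/G/T")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos0}:{self.ref_base}>{self.alt_base}"


@dataclass(frozen=True)
class EditingEvent:
    """One sample's observation of editing at one site."""

    site: EditingSite
    sample_id: str
    depth: int
    edited_reads: int

    def __post_init__(self):
        if not 0 <= self.edited_reads <= self.depth:
            raise ValueError("edited_reads outside [0, depth]")

    @property
    def level(self) -> float:
        return self.edited_reads / self.depth if self.depth else 0.0


class EditingMatrix:
    """Sites x samples grid of (depth, editing level) with a MISSING mask.

    Internally depth -1 marks MISSING; levels are NaN there.  TSV form:
    rows keyed "chrom:pos0:ref>alt", cells "depth,level" or "NA".
    """

    MISSING_DEPTH = -1

    def __init__(self, site_keys: Sequence[str], samples: Sequence[str],
                 depth: np.ndarray, level: np.ndarray):
        depth = np.asarray(depth, dtype=np.int64)
        level = np.asarray(level, dtype=float)
        if depth.shape != (len(site_keys), len(samples)):
            raise ValueError("depth shape does not match sites x samples")
        if level.shape != depth.shape:
            raise ValueError("level shape does not match depth shape")
        if np.any(depth < -1):
            raise ValueError("negative depths")
        self.site_keys = list(site_keys)
        self.samples = list(samples)
        self.depth = depth
        self.level = np.where(depth < 0, np.nan, level)

    @property
    def missing(self) -> np.ndarray:
        return self.depth < 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.depth.shape

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def column(self, sample: str) -> tuple[np.ndarray, np.ndarray]:
        j = self.sample_index(sample)
        return self.depth[:, j], self.level[:, j]

    @classmethod
    def empty(cls, site_keys: Sequence[str], samples: Sequence[str]) -> "EditingMatrix":
        n, m = len(site_keys), len(samples)
        return cls(site_keys, samples,
                   np.full((n, m), cls.MISSING_DEPTH, dtype=np.int64),
                   np.full((n, m), np.nan))

    def set_cell(self, i: int, j: int, depth: int, level: float) -> None:
        if depth < 0:
            raise ValueError("negative depth")
        self.depth[i, j] = depth
        self.level[i, j] = level

    def to_tsv(self, handle) -> None:
        close = False
        if isinstance(handle, str):
            handle, close = open(handle, "w"), True
        try:
            handle.write("site\t" + "\t".join(self.samples) + "\n")
            for i, key in enumerate(self.site_keys):
                cells = []
                for j in range(len(self.samples)):
                    d = int(self.depth[i, j])
                    if d < 0:
                        cells.append("NA")
                    else:
                        cells.append(f"{d},{self.level[i, j]:.6g}")
                handle.write(key + "\t" + "\t".join(cells) + "\n")
        finally:
            if close:
                handle.close()

    @classmethod
    def from_tsv(cls, handle) -> "EditingMatrix":
        close = False
        if isinstance(handle, str):
            handle, close = open(handle), True
        try:
            header = handle.readline().rstrip("\n").split("\t")
            samples = header[1:]
            keys, depths, levels = [], [], []
            for line in handle:
                parts = line.rstrip("\n").split("\t")
                keys.append(parts[0])
                drow, lrow = [], []
                for cell in parts[1:]:
                    if cell == "NA":
                        drow.append(cls.MISSING_DEPTH)
                        lrow.append(np.nan)
                    else:
                        d, lv = cell.split(",")
                        drow.append(int(d))
                        lrow.append(float(lv))
                depths.append(drow)
                levels.append(lrow)
            n = len(keys)
            depth = np.array(depths, dtype=np.int64).reshape(n, len(samples))
            level = np.array(levels, dtype=float).reshape(n, len(samples))
            return cls(keys, samples, depth, level)
        finally:
            if close:
                handle.close()

    def to_string(self) -> str:
        buf = io.StringIO()
        self.to_tsv(buf)
        return buf.getvalue()


def parse_site_key(key: str) -> tuple[str, int, str, str]:
    """Invert EditingSite.key: "chrom:pos0:ref>alt" -> tuple."""
    chrom, pos0, sub = key.rsplit(":", 2)
    ref, alt = sub.split(">")
    return chrom, int(pos0), ref, alt
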