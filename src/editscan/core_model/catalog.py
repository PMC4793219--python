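"""Known-editing-site catalog (RADAR-style TSV) reading."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO

from .types import EditingSite, complement_base

log = logging.getLogger(__name__)

_REGION_SYNONYMS = {
    "coding": "coding", "cds": "coding", "exonic": "coding", "exon": "coding",
    "3utr": "3UTR", "3'utr": "3UTR", "utr3": "3UTR", "three_prime_utr": "3UTR",
    "5utr": "5UTR", "5'utr": "5UTR", "utr5": "5UTR", "five_prime_utr": "5UTR",
    "intron": "intron", "intronic": "intron",
    "intergenic": "intergenic",
}


@dataclass
class CatalogColumns:
    """1-based-position TSV column mapping (0-based column indices)."""

    chrom: int = 0
    position: int = 1  # 1-based in the file
    gene: int = 2
    region: int = 3
    strand: int = 4
    has_header: bool = True


def normalize_region(label: str) -> str:
    norm = _REGION_SYNONYMS.get(label.strip().lower())
    if norm is None:
        log.warning("unknown region label %r mapped to 'unknown'", label)
        return "unknown"
    return norm


def parse_catalog_records(stream: IO[str] | str,
                          columns: CatalogColumns | None = None) -> list[EditingSite]:
    """Parse a catalog of A-to-I sites.

    Sites on the minus strand are stored as T>C on the plus reference
    strand, with the original strand recorded.
    """
    columns = columns or CatalogColumns()
    close = False
    if isinstance(stream, str):
        stream, close = open(stream), True
    sites = []
    try:
        for lineno, raw in enumerate(stream, start=1):
            if columns.has_header and lineno == 1:
                continue
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            chrom = fields[columns.chrom]
            pos0 = int(fields[columns.position]) - 1
            gene = fields[columns.gene] if columns.gene < len(fields) else None
            region = normalize_region(fields[columns.region]) \
                if columns.region < len(fields) else "unknown"
            strand = fields[columns.strand] \
                if columns.strand < len(fields) else "+"
            ref, alt = "A", "G"
            if strand == "-":
                ref, alt = complement_base(ref), complement_base(alt)
            sites.append(EditingSite(
                chrom=chrom, pos0=pos0, strand=strand,
                ref_base=ref, alt_base=alt, region=region,
                gene=gene or None))
    finally:
        if close:
            stream.close()
    return sites
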