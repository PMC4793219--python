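"""VCF reading/writing.

The reader targets VarScan-style FORMAT fields (DP/RD/AD/FREQ) by default
with a fallback to GATK-style DP + allelic AD; the field mapping is a
configuration table, not hard-coded logic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable

from .types import DNA_BASES, VariantCall

log = logging.getLogger(__name__)

VCF_FILTERS = {
    "PASS": "All filters passed",
    "raar_multi": "Refuted by realignment: multi-alignment artifact",
    "raar_splice": "Refuted by realignment: splice-junction artifact",
    "raar_indel": "Refuted by realignment: indel-adjacent artifact",
    "raar_lowsupport": "Insufficient confirmed supporting reads",
}


class VcfParseError(ValueError):
    """Malformed VCF content; carries the offending 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass
class VcfDialect:
    """How to recover depth and alt-supporting reads from a record.

    Each entry of ``format_priority`` names a strategy tried in order:
      - "varscan": FORMAT RD (ref reads) + AD (alt reads), DP if present
      - "dp_ad":   FORMAT DP + allelic AD tuple
      - "info_dp4": INFO DP4=ref_fwd,ref_rev,alt_fwd,alt_rev
    """

    format_priority: tuple[str, ...] = ("varscan", "dp_ad", "info_dp4")
    on_missing_depth: str = "skip"  # "skip" or "fail"


DEFAULT_DIALECT = VcfDialect()


@dataclass
class VcfParseResult:
    calls: list[VariantCall]
    skipped_non_snv: int = 0
    skipped_no_depth: int = 0


def _split_info(info: str) -> dict[str, str]:
    out = {}
    for item in info.split(";"):
        if not item or item == ".":
            continue
        if "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
        else:
            out[item] = ""
    return out


def _extract_counts(dialect: VcfDialect, info: dict[str, str],
                    fmt: dict[str, str], alt_index: int,
                    n_alts: int) -> tuple[int, int] | None:
    """(total_depth, alt_depth) under the first applicable strategy."""
    for strategy in dialect.format_priority:
        if strategy == "varscan" and "RD" in fmt and "AD" in fmt:
            ad_fields = fmt["AD"].split(",")
            # VarScan emits a scalar AD for the single alt allele
            if len(ad_fields) == n_alts:
                alt = int(ad_fields[alt_index])
            else:
                alt = int(ad_fields[0])
            rd = int(fmt["RD"])
            depth = int(fmt["DP"]) if "DP" in fmt else rd + alt
            return depth, alt
        if strategy == "dp_ad" and "AD" in fmt:
            ad_fields = fmt["AD"].split(",")
            if len(ad_fields) >= n_alts + 1:
                alt = int(ad_fields[1 + alt_index])
                depth = int(fmt["DP"]) if "DP" in fmt else sum(
                    int(x) for x in ad_fields)
                return depth, alt
        if strategy == "info_dp4" and "DP4" in info:
            rf, rr, af, ar = (int(x) for x in info["DP4"].split(","))
            return rf + rr + af + ar, af + ar
    return None


def parse_variant_records(stream: IO[str] | str, sample_id: str = "",
                          dialect: VcfDialect = DEFAULT_DIALECT) -> VcfParseResult:
    """Parse VCF 4.x text into VariantCall records.

    1-based POS becomes pos0 = POS - 1.  Multi-allelic SNV records are
    split into one call per alternate allele; non-SNV alleles are skipped
    and counted.
    """
    close = False
    if isinstance(stream, str):
        stream, close = open(stream), True
    result = VcfParseResult(calls=[])
    saw_header = False
    try:
        for lineno, raw in enumerate(stream, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if cols[:8] != ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL",
                                "FILTER", "INFO"]:
                    raise VcfParseError("malformed #CHROM header", lineno)
                saw_header = True
                continue
            if line.startswith("#"):
                continue
            if not saw_header:
                raise VcfParseError("data line before #CHROM header", lineno)
            fields = line.split("\t")
            if len(fields) < 8:
                raise VcfParseError(f"expected >=8 columns, got {len(fields)}",
                                    lineno)
            chrom, pos_s, _id, ref, alt_s = fields[:5]
            try:
                pos = int(pos_s)
            except ValueError:
                raise VcfParseError(f"non-integer POS {pos_s!r}", lineno) from None
            info = _split_info(fields[7])
            fmt: dict[str, str] = {}
            if len(fields) >= 10:
                keys = fields[8].split(":")
                vals = fields[9].split(":")
                fmt = dict(zip(keys, vals))
            alts = alt_s.split(",")
            ref = ref.upper()
            for alt_index, alt in enumerate(alts):
                alt = alt.upper()
                if len(ref) != 1 or len(alt) != 1 or ref not in DNA_BASES \
                        or alt not in DNA_BASES:
                    result.skipped_non_snv += 1
                    continue
                counts = _extract_counts(dialect, info, fmt, alt_index, len(alts))
                if counts is None:
                    if dialect.on_missing_depth == "fail":
                        raise VcfParseError(
                            "no depth fields under configured dialect", lineno)
                    result.skipped_no_depth += 1
                    continue
                depth, alt_reads = counts
                result.calls.append(VariantCall(
                    chrom=chrom, pos0=pos - 1, ref_base=ref, alt_base=alt,
                    total_depth=depth, alt_depth=alt_reads,
                    sample_id=sample_id))
    finally:
        if close:
            stream.close()
    if result.skipped_non_snv:
        log.info("skipped %d non-SNV alleles", result.skipped_non_snv)
    return result


def write_variant_records(handle, calls: Iterable[VariantCall],
                          filters: dict[tuple, str] | None = None,
                          contigs: dict[str, int] | None = None,
                          sample_id: str = "SAMPLE") -> None:
    """Write calls as VarScan-dialect VCF 4.2.

    ``filters`` optionally maps VariantCall.key -> FILTER string (one of
    VCF_FILTERS); unmapped calls get ".".
    """
    close = False
    if isinstance(handle, str):
        handle, close = open(handle, "w"), True
    try:
        handle.write("##fileformat=VCFv4.2\n")
        if contigs:
            for name, length in contigs.items():
                handle.write(f"##contig=<ID={name},length={length}>\n")
        for name, desc in VCF_FILTERS.items():
            if name == "PASS":
                continue
            handle.write(f'##FILTER=<ID={name},Description="{desc}">\n')
        handle.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        handle.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        handle.write('##FORMAT=<ID=RD,Number=1,Type=Integer,Description="Reference supporting reads">\n')
        handle.write('##FORMAT=<ID=AD,Number=1,Type=Integer,Description="Variant supporting reads">\n')
        handle.write('##FORMAT=<ID=FREQ,Number=1,Type=String,Description="Variant allele frequency">\n')
        handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + sample_id + "\n")
        for call in calls:
            filt = (filters or {}).get(call.key, ".")
            rd = call.total_depth - call.alt_depth
            freq = f"{call.allele_frequency * 100:.2f}%"
            handle.write("\t".join([
                call.chrom, str(call.pos0 + 1), ".", call.ref_base,
                call.alt_base, ".", filt, ".",
                "GT:DP:RD:AD:FREQ",
                f"0/1:{call.total_depth}:{rd}:{call.alt_depth}:{freq}",
            ]) + "\n")
    finally:
        if close:
            handle.close()
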