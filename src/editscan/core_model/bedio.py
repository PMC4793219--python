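"""BED3-6 interval reading/writing (0-based half-open)."""

from __future__ import annotations

from typing import IO, Iterable, NamedTuple


class BedRecord(NamedTuple):
    chrom: str
    start0: int
    end0: int
    name: str = "."
    strand: str = "+"


class BedRecordError(ValueError):
    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


def parse_interval_records(stream: IO[str] | str) -> list[BedRecord]:
    """Parse BED text; missing name/strand default to "." / "+"."""
    close = False
    if isinstance(stream, str):
        stream, close = open(stream), True
    records = []
    try:
        for lineno, raw in enumerate(stream, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedRecordError("fewer than 3 columns", lineno)
            chrom = fields[0]
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedRecordError("non-integer interval bounds", lineno) from None
            if start0 >= end0:
                raise BedRecordError(
                    f"empty or inverted interval [{start0},{end0})", lineno)
            name = fields[3] if len(fields) > 3 and fields[3] else "."
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "+"
            records.append(BedRecord(chrom, start0, end0, name, strand))
    finally:
        if close:
            stream.close()
    return records


def write_interval_records(handle, records: Iterable[BedRecord]) -> None:
    close = False
    if isinstance(handle, str):
        handle, close = open(handle, "w"), True
    try:
        for rec in records:
            handle.write(
                f"{rec.chrom}\t{rec.start0}\t{rec.end0}\t{rec.name}\t0\t{rec.strand}\n")
    finally:
        if close:
            handle.close()
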