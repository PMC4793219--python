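"""FASTA reading/writing via Biopython."""

from __future__ import annotations

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import GenomeReference


def read_reference(path: str) -> GenomeReference:
    sequences = {rec.id: str(rec.seq).upper()
                 for rec in SeqIO.parse(path, "fasta")}
    return GenomeReference(sequences)


def write_reference(path: str, genome: GenomeReference, width: int = 70) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in genome.sequences.items()]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)
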