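"""FASTQ/FASTA input and output.

Reads are lightweight ``(id, sequence, quality)`` named tuples; qualities are
Sanger Phred+33 strings. Ground-truth taxon labels emitted by the simulator
live in the read id after the reserved ``;truth=`` delimiter and must never be
consulted by analysis code (tests only).
"""

from __future__ import annotations

import os
from typing import Iterable, NamedTuple

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

TRUTH_DELIMITER = ";truth="


class Read(NamedTuple):
    """A single-end amplicon read."""

    id: str
    sequence: str
    quality: str


def truth_label(read: Read) -> str | None:
    """Return the simulator's ground-truth taxon id, if the header carries one."""
    if TRUTH_DELIMITER in read.id:
        return read.id.rsplit(TRUTH_DELIMITER, 1)[1]
    return None


def read_fastq(path: str | os.PathLike) -> list[Read]:
    """Parse a Sanger FASTQ file into a list of reads.

    Raises ``ValueError`` (from Biopython) on malformed records.
    """
    with open(path) as handle:
        return [Read(title.split()[0] if title else "", seq, qual)
                for title, seq, qual in FastqGeneralIterator(handle)]


def write_fastq(reads: Iterable[Read], path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        for r in reads:
            handle.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")


def write_fasta(records: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    """Write ``(header, sequence)`` pairs; headers are emitted verbatim."""
    with open(path, "w") as handle:
        for header, seq in records:
            handle.write(f">{header}\n{seq}\n")


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    with open(path) as handle:
        return list(SimpleFastaParser(handle))
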