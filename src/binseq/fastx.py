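"""FASTQ/FASTA reading and writing helpers (plain or gzip).

Reading goes through Biopython's low-level iterators; gzip is detected by
magic bytes.  FASTQ is the strict 4-line dialect on write; FASTA may be
multi-line on read and is single-line on write.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterator, Optional, Tuple, Union

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import FormatError

FastxRecord = Tuple[str, str, Optional[str]]  # (title, sequence, quality-or-None)


def open_maybe_gzip(path: Union[str, Path], mode: str = "rt") -> IO:
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastx(path: Union[str, Path]) -> Iterator[FastxRecord]:
    """Yield (title, seq, qual) from FASTQ or FASTA; qual is None for FASTA."""
    fh = open_maybe_gzip(path)
    try:
        first = fh.read(1)
        fh.seek(0)
        if first == "@":
            for title, seq, qual in FastqGeneralIterator(fh):
                yield title, seq, qual
        elif first == ">":
            for title, seq in SimpleFastaParser(fh):
                yield title, seq, None
        elif first == "":
            return
        else:
            raise FormatError(f"{path}: not FASTA or FASTQ (starts with {first!r})")
    finally:
        fh.close()


def write_fastq_record(fh: IO[bytes], title: bytes, seq: bytes, qual: bytes) -> None:
    fh.write(b"@" + title + b"\n" + seq + b"\n+\n" + qual + b"\n")


def write_fasta_record(fh: IO[bytes], title: bytes, seq: bytes) -> None:
    fh.write(b">" + title + b"\n" + seq + b"\n")
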