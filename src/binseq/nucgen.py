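"""Deterministic synthetic read generator.

Emulates the benchmark input convention for format evaluation: every base
is drawn i.i.d. uniformly from {A, C, G, T} and every quality line is a
single constant character (default '?'), which collapses the quality
channel so measurements isolate sequence handling.  No error model, length
distribution or reference genome is simulated.  The same spec and seed
always produce identical output bytes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterator, Optional, Tuple, Union

import numpy as np

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)
_CHUNK = 100_000


@dataclass
class GenSpec:
    """Parameters of one synthetic dataset."""

    n_records: int
    length: int
    mate_length: Optional[int] = None  # set for paired-end output
    seed: int = 0
    quality_char: str = "?"

    def __post_init__(self):
        if self.n_records < 0:
            raise ValueError("n_records must be non-negative")
        if self.length < 1 or (self.mate_length is not None and self.mate_length < 1):
            raise ValueError("read lengths must be >= 1")
        if len(self.quality_char) != 1:
            raise ValueError("quality_char must be a single character")


def random_base_matrix(n: int, length: int, rng: np.random.Generator) -> np.ndarray:
    """(n, length) uint8 ASCII matrix of uniform random A/C/G/T."""
    return _ACGT[rng.integers(0, 4, size=(n, length), dtype=np.uint8)]


def iter_reads(spec: GenSpec) -> Iterator[Tuple[bytes, Optional[bytes]]]:
    """Yield (primary, mate-or-None) sequences, chunk-generated for speed."""
    rng = np.random.default_rng(spec.seed)
    done = 0
    while done < spec.n_records:
        n = min(_CHUNK, spec.n_records - done)
        mat = random_base_matrix(n, spec.length, rng)
        mate = (
            random_base_matrix(n, spec.mate_length, rng)
            if spec.mate_length is not None
            else None
        )
        for i in range(n):
            yield mat[i].tobytes(), (mate[i].tobytes() if mate is not None else None)
        done += n


def _fastq_chunk(mat: np.ndarray, start: int, qual: bytes) -> bytes:
    lines = []
    q = qual * mat.shape[1]
    for i in range(mat.shape[0]):
        lines.append(b"@r%d\n%s\n+\n%s\n" % (start + i, mat[i].tobytes(), q))
    return b"".join(lines)


def generate(
    spec: GenSpec,
    out: Union[str, Path, IO[bytes]],
    out2: Union[str, Path, IO[bytes], None] = None,
) -> int:
    """Write the dataset as 4-line FASTQ (two files when paired).

    Read identifiers are ``@r{ordinal}``.  Returns the record count.
    """
    if (spec.mate_length is not None) != (out2 is not None):
        raise ValueError("paired spec requires exactly two outputs")
    own1 = isinstance(out, (str, Path))
    own2 = isinstance(out2, (str, Path))
    fh1 = open(out, "wb") if own1 else out
    fh2 = open(out2, "wb") if own2 else out2
    qual = spec.quality_char.encode()
    rng = np.random.default_rng(spec.seed)
    try:
        done = 0
        while done < spec.n_records:
            n = min(_CHUNK, spec.n_records - done)
            fh1.write(_fastq_chunk(random_base_matrix(n, spec.length, rng), done, qual))
            if fh2 is not None:
                fh2.write(
                    _fastq_chunk(random_base_matrix(n, spec.mate_length, rng), done, qual)
                )
            done += n
    finally:
        if own1:
            fh1.close()
        if own2 and fh2 is not None:
            fh2.close()
    return spec.n_records
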