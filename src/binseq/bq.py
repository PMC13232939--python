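"""BQ container: fixed-size records with closed-form random access.

Layout::

    bytes 0-3    magic  b"BSQ\\x01"
    byte  4      version (1)
    byte  5      encoding (2 = two-bit, 4 = four-bit)
    byte  6      flag_enabled (0 or 1)
    byte  7      reserved (0)
    bytes 8-11   slen, primary sequence length in bases (uint32 LE)
    bytes 12-15  xlen, extended sequence length in bases (uint32 LE, 0 = unpaired)
    bytes 16-31  reserved (zeros)

followed by ``n`` records of identical size

    S = F + 8 * (ceil(slen/B) + ceil(xlen/B))       F in {0, 8}

so record ``i`` starts at byte ``32 + i*S`` and the file size is exactly
``32 + n*S``.  BQ stores no qualities or identifiers by design.
"""

from __future__ import annotations

import os
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional, Union

import numpy as np

from .encoding import (
    WORD_SIZE,
    EncodingScheme,
    InvalidPolicy,
    pack,
    pack_matrix,
    sanitize,
    scheme_for,
    unpack_words,
    words_needed,
)
from .errors import FormatError
from .records import SeqRecord

BQ_MAGIC = b"BSQ\x01"
BQ_VERSION = 1
HEADER_SIZE = 32

_HEADER = struct.Struct("<4sBBBBII16s")
assert _HEADER.size == HEADER_SIZE


@dataclass
class BqHeader:
    """The fixed 32-byte BQ file header."""

    encoding: int
    flag_enabled: bool
    slen: int
    xlen: int = 0
    version: int = BQ_VERSION

    def __post_init__(self):
        if self.encoding not in (2, 4):
            raise ValueError("encoding must be 2 or 4")
        if self.slen < 1:
            raise ValueError("slen must be >= 1")
        if self.xlen < 0:
            raise ValueError("xlen must be >= 0")

    @property
    def scheme(self) -> EncodingScheme:
        return scheme_for(self.encoding)

    @property
    def is_paired(self) -> bool:
        return self.xlen > 0

    @property
    def flag_bytes(self) -> int:
        return 8 if self.flag_enabled else 0

    def record_size(self) -> int:
        """Serialized bytes per record: F + W*(ceil(N/B) [+ ceil(M/B)])."""
        words = words_needed(self.slen, self.scheme)
        if self.xlen:
            words += words_needed(self.xlen, self.scheme)
        return self.flag_bytes + WORD_SIZE * words

    def record_offset(self, i: int) -> int:
        """Byte offset of record i: header size + i * record size."""
        if i < 0:
            raise IndexError("record index must be non-negative")
        return HEADER_SIZE + i * self.record_size()

    def to_bytes(self) -> bytes:
        return _HEADER.pack(
            BQ_MAGIC,
            self.version,
            self.encoding,
            int(self.flag_enabled),
            0,
            self.slen,
            self.xlen,
            b"\x00" * 16,
        )

    @classmethod
    def from_bytes(cls, data: bytes) -> "BqHeader":
        if len(data) < HEADER_SIZE:
            raise FormatError("file too small to hold a BQ header")
        magic, version, encoding, flag, res0, slen, xlen, reserved = _HEADER.unpack(
            data[:HEADER_SIZE]
        )
        if magic != BQ_MAGIC:
            raise FormatError(f"bad BQ magic {magic!r}")
        if version != BQ_VERSION:
            raise FormatError(f"unsupported BQ version {version}")
        if encoding not in (2, 4):
            raise FormatError(f"unsupported encoding byte {encoding}")
        if flag not in (0, 1) or res0 != 0 or reserved != b"\x00" * 16:
            raise FormatError("reserved BQ header bytes are not zero")
        return cls(encoding, bool(flag), slen, xlen, version)


def record_size(header: BqHeader) -> int:
    return header.record_size()


def record_offset(i: int, header: BqHeader) -> int:
    return header.record_offset(i)


def read_bq_header(path: Union[str, Path]) -> BqHeader:
    with open(path, "rb") as fh:
        header = BqHeader.from_bytes(fh.read(HEADER_SIZE))
        size = os.fstat(fh.fileno()).st_size
    if (size - HEADER_SIZE) % header.record_size() != 0:
        raise FormatError(
            f"file size {size} minus header is not a multiple of the "
            f"record size {header.record_size()}"
        )
    return header


class BqWriter:
    """Streaming BQ writer; also offers a vectorized fixed-length batch path.

    A sanitize policy, when given, is applied to every sequence before the
    length check; with the skip policy, records containing invalid bases are
    dropped and counted in ``n_skipped``.
    """

    def __init__(
        self,
        path: Union[str, Path],
        slen: int,
        xlen: int = 0,
        encoding: int = 2,
        flag_enabled: bool = False,
        policy: Optional[InvalidPolicy] = None,
    ):
        self.header = BqHeader(encoding, flag_enabled, slen, xlen)
        self.policy = policy
        self.path = Path(path)
        self._fh = open(path, "wb")
        self._fh.write(self.header.to_bytes())
        self.n_written = 0
        self.n_skipped = 0

    def _prepare(self, seq: bytes, expect: int, which: str, ordinal: int) -> Optional[bytes]:
        if self.policy is not None:
            seq = sanitize(seq, self.policy, self.header.scheme)
            if seq is None:
                return None
        if len(seq) != expect:
            raise FormatError(
                f"{which} sequence of record {ordinal} has length {len(seq)}, "
                f"expected {expect}; BQ requires fixed lengths — use VBQ for "
                f"variable-length records"
            )
        return seq

    def write(self, seq: bytes, ext: Optional[bytes] = None, flag: int = 0) -> bool:
        """Append one record; returns False if the skip policy dropped it."""
        ordinal = self.n_written + self.n_skipped
        if self.header.is_paired and ext is None:
            raise FormatError(f"record {ordinal}: paired file requires an extended sequence")
        primary = self._prepare(seq, self.header.slen, "primary", ordinal)
        extended = (
            self._prepare(ext, self.header.xlen, "extended", ordinal)
            if self.header.is_paired
            else None
        )
        if primary is None or (self.header.is_paired and extended is None):
            self.n_skipped += 1
            return False
        if self.header.flag_enabled:
            self._fh.write(struct.pack("<Q", flag))
        self._fh.write(pack(primary, self.header.scheme).to_bytes())
        if extended is not None:
            self._fh.write(pack(extended, self.header.scheme).to_bytes())
        self.n_written += 1
        return True

    def write_batch(
        self,
        seqs: np.ndarray,
        exts: Optional[np.ndarray] = None,
        flags: Optional[np.ndarray] = None,
    ) -> int:
        """Vectorized append of (n, slen) / (n, xlen) ASCII uint8 matrices.

        Bypasses the sanitize policy: all bases must already be encodable.
        """
        scheme = self.header.scheme
        n = seqs.shape[0]
        if seqs.shape[1] != self.header.slen:
            raise FormatError(f"batch row length {seqs.shape[1]} != slen {self.header.slen}")
        if self.header.is_paired != (exts is not None):
            raise FormatError("batch pairing does not match the header")
        columns = []
        if self.header.flag_enabled:
            fcol = np.zeros(n, dtype=np.uint64) if flags is None else flags.astype(np.uint64)
            columns.append(fcol[:, None])
        columns.append(pack_matrix(seqs, scheme))
        if exts is not None:
            if exts.shape[1] != self.header.xlen:
                raise FormatError(f"batch mate length {exts.shape[1]} != xlen {self.header.xlen}")
            columns.append(pack_matrix(exts, scheme))
        self._fh.write(np.hstack(columns).astype("<u8", copy=False).tobytes())
        self.n_written += n
        return n

    def close(self):
        if self._fh.closed:
            return
        self._fh.flush()
        size = self._fh.tell()
        self._fh.close()
        expected = HEADER_SIZE + self.n_written * self.header.record_size()
        if size != expected:
            raise FormatError(f"BQ size invariant violated: {size} != {expected}")

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


class BqReader:
    """Positional and sequential access to a BQ file.

    ``get_record`` seeks directly to ``32 + i*S``; no preceding record is
    ever parsed.
    """

    def __init__(self, path: Union[str, Path]):
        self.path = Path(path)
        self.header = read_bq_header(path)
        self._rs = self.header.record_size()
        self._fh = open(path, "rb")
        size = os.fstat(self._fh.fileno()).st_size
        self.n_records = (size - HEADER_SIZE) // self._rs

    def _parse(self, raw: bytes) -> SeqRecord:
        h = self.header
        off = 0
        flag = None
        if h.flag_enabled:
            (flag,) = struct.unpack_from("<Q", raw, 0)
            off = 8
        scheme = h.scheme
        nw = words_needed(h.slen, scheme)
        words = np.frombuffer(raw, dtype="<u8", count=nw, offset=off)
        seq = unpack_words(words, h.slen, scheme)
        ext = None
        if h.is_paired:
            xw = words_needed(h.xlen, scheme)
            xwords = np.frombuffer(raw, dtype="<u8", count=xw, offset=off + 8 * nw)
            ext = unpack_words(xwords, h.xlen, scheme)
        return SeqRecord(seq=seq, ext=ext, flag=flag)

    def get_record(self, i: int) -> SeqRecord:
        if not 0 <= i < self.n_records:
            raise IndexError(f"record index {i} out of range [0, {self.n_records})")
        self._fh.seek(self.header.record_offset(i))
        return self._parse(self._fh.read(self._rs))

    def iter_range(self, lo: int, hi: int) -> Iterator[SeqRecord]:
        """Yield records lo..hi-1 with a single seek."""
        if not 0 <= lo <= hi <= self.n_records:
            raise IndexError(f"range [{lo}, {hi}) out of bounds")
        self._fh.seek(self.header.record_offset(lo))
        for _ in range(hi - lo):
            yield self._parse(self._fh.read(self._rs))

    def __iter__(self) -> Iterator[SeqRecord]:
        return self.iter_range(0, self.n_records)

    def __len__(self) -> int:
        return self.n_records

    def close(self):
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()
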