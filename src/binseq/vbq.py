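"""VBQ container: variable-length records in independently compressed blocks.

A VBQ file is::

    32-byte file header
    [ 32-byte block header | block payload ] * n_blocks
    trailing block index

Every block packs as many whole records as fit in ``virtual_block_size``
uncompressed bytes (records never straddle blocks); the payload is
optionally ZSTD-compressed and the stored (post-compression) byte count
plus the record count sit in the preceding block header.  Because block
positions are not derivable when compression is on, a compressed index of
(offset, stored_size, n_records, cumulative_records) ranges is appended
after the last block; it is read first so blocks can be decoded
independently and in parallel.

File header layout (32 bytes)::

    0-3   magic b"VBQ\\x01"
    4     version (1)
    5     encoding (2 or 4)
    6     feature bitfield: 1 quality, 2 compressed, 4 paired, 8 headers,
          16 record flags
    7     reserved
    8-15  virtual_block_size (uint64 LE, payload bytes per block)
    16-31 reserved

Block header (32 bytes): magic b"VBLK", stored_size u64, n_records u64,
12 reserved bytes.  Record fields, in order and present per the feature
bits: flag u64 | slen u64 | xlen u64 | primary words | extended words |
primary quality (slen bytes, Phred+33) | extended quality | primary header
(u16 length prefix) | extended header.

Index: a 32-byte uncompressed index header (magic b"VIDX", ``data_bytes`` =
byte count of the pre-index file region, used to detect a mispaired index),
then the ZSTD-compressed concatenation of 32-byte ranges, then a 16-byte
footer (total index byte count + magic b"VEND").
"""

from __future__ import annotations

import os
import struct
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, List, Optional, Sequence, Union

import numpy as np
from numcodecs.zstd import Zstd

from .encoding import (
    WORD_SIZE,
    InvalidPolicy,
    pack,
    pack_matrix,
    sanitize,
    scheme_for,
    unpack_words,
    words_needed,
)
from .errors import (
    BlockCorruptionError,
    BlockSizeError,
    CorruptIndexError,
    FormatError,
    IndexPairError,
)
from .records import SeqRecord

VBQ_MAGIC = b"VBQ\x01"
VBQ_VERSION = 1
BLOCK_MAGIC = b"VBLK"
INDEX_MAGIC = b"VIDX"
FOOTER_MAGIC = b"VEND"

HEADER_SIZE = 32
BLOCK_HEADER_SIZE = 32
INDEX_HEADER_SIZE = 32
RANGE_SIZE = 32
FOOTER_SIZE = 16

DEFAULT_BLOCK_SIZE = 128 * 1024
DEFAULT_ZSTD_LEVEL = 3

_HEADER = struct.Struct("<4sBBBBQ16s")
_BLOCK_HEADER = struct.Struct("<4sQQ12s")
_INDEX_HEADER = struct.Struct("<4sQ20s")
_RANGE = struct.Struct("<QQQQ")
_FOOTER = struct.Struct("<Q4s4s")
assert _HEADER.size == HEADER_SIZE
assert _BLOCK_HEADER.size == BLOCK_HEADER_SIZE
assert _INDEX_HEADER.size == INDEX_HEADER_SIZE
assert _RANGE.size == RANGE_SIZE
assert _FOOTER.size == FOOTER_SIZE

FLAG_QUALITY = 1
FLAG_COMPRESSED = 2
FLAG_PAIRED = 4
FLAG_HEADERS = 8
FLAG_RECORD_FLAGS = 16


@dataclass
class VbqHeader:
    encoding: int
    has_quality: bool = False
    compressed: bool = True
    paired: bool = False
    has_headers: bool = False
    has_record_flags: bool = False
    virtual_block_size: int = DEFAULT_BLOCK_SIZE
    version: int = VBQ_VERSION

    def __post_init__(self):
        if self.encoding not in (2, 4):
            raise ValueError("encoding must be 2 or 4")
        if self.virtual_block_size < 1:
            raise ValueError("virtual_block_size must be positive")

    @property
    def scheme(self):
        return scheme_for(self.encoding)

    def feature_bits(self) -> int:
        return (
            (FLAG_QUALITY if self.has_quality else 0)
            | (FLAG_COMPRESSED if self.compressed else 0)
            | (FLAG_PAIRED if self.paired else 0)
            | (FLAG_HEADERS if self.has_headers else 0)
            | (FLAG_RECORD_FLAGS if self.has_record_flags else 0)
        )

    def to_bytes(self) -> bytes:
        return _HEADER.pack(
            VBQ_MAGIC,
            self.version,
            self.encoding,
            self.feature_bits(),
            0,
            self.virtual_block_size,
            b"\x00" * 16,
        )

    @classmethod
    def from_bytes(cls, data: bytes) -> "VbqHeader":
        if len(data) < HEADER_SIZE:
            raise FormatError("file too small to hold a VBQ header")
        magic, version, encoding, bits, res0, vbs, reserved = _HEADER.unpack(
            data[:HEADER_SIZE]
        )
        if magic != VBQ_MAGIC:
            raise FormatError(f"bad VBQ magic {magic!r}")
        if version != VBQ_VERSION:
            raise FormatError(f"unsupported VBQ version {version}")
        if encoding not in (2, 4):
            raise FormatError(f"unsupported encoding byte {encoding}")
        if res0 != 0 or reserved != b"\x00" * 16:
            raise FormatError("reserved VBQ header bytes are not zero")
        return cls(
            encoding,
            has_quality=bool(bits & FLAG_QUALITY),
            compressed=bool(bits & FLAG_COMPRESSED),
            paired=bool(bits & FLAG_PAIRED),
            has_headers=bool(bits & FLAG_HEADERS),
            has_record_flags=bool(bits & FLAG_RECORD_FLAGS),
            virtual_block_size=vbs,
            version=version,
        )


@dataclass(frozen=True)
class IndexRange:
    """One block as seen from the trailing index."""

    offset: int  # file position of the 32-byte block header
    stored_size: int  # payload bytes as written (post-compression)
    n_records: int
    cum_records: int  # records preceding this block

    def to_bytes(self) -> bytes:
        return _RANGE.pack(self.offset, self.stored_size, self.n_records, self.cum_records)


@dataclass
class BlockIndex:
    data_bytes: int  # bytes of the pre-index file region
    ranges: List[IndexRange]

    @property
    def n_records(self) -> int:
        return sum(r.n_records for r in self.ranges)


def serialized_record_size(
    slen: int,
    xlen: int = 0,
    encoding: int = 2,
    *,
    has_quality: bool = False,
    has_headers: bool = False,
    has_record_flags: bool = False,
    name_len: int = 0,
    ext_name_len: int = 0,
) -> int:
    """Bytes one record occupies inside an uncompressed block payload."""
    scheme = scheme_for(encoding)
    size = 8 + WORD_SIZE * words_needed(slen, scheme)
    if has_record_flags:
        size += 8
    if xlen:
        size += 8 + WORD_SIZE * words_needed(xlen, scheme)
    if has_quality:
        size += slen + xlen
    if has_headers:
        size += 2 + name_len
        if xlen:
            size += 2 + ext_name_len
    return size


def write_index(ranges: Sequence[IndexRange], data_bytes: int) -> bytes:
    """Serialize the trailing index: header, zstd-compressed ranges, footer."""
    payload = b"".join(r.to_bytes() for r in ranges)
    # zero blocks -> zero-byte range section (an empty zstd frame round-trips badly)
    compressed = Zstd(level=DEFAULT_ZSTD_LEVEL).encode(payload) if payload else b""
    index_bytes = INDEX_HEADER_SIZE + len(compressed) + FOOTER_SIZE
    return (
        _INDEX_HEADER.pack(INDEX_MAGIC, data_bytes, b"\x00" * 20)
        + compressed
        + _FOOTER.pack(index_bytes, FOOTER_MAGIC, b"\x00" * 4)
    )


def load_index(path: Union[str, Path]) -> BlockIndex:
    """Read and validate the trailing block index of a VBQ file."""
    with open(path, "rb") as fh:
        size = os.fstat(fh.fileno()).st_size
        if size < HEADER_SIZE + INDEX_HEADER_SIZE + FOOTER_SIZE:
            raise CorruptIndexError("file too small to hold a VBQ index")
        fh.seek(size - FOOTER_SIZE)
        index_bytes, magic, pad = _FOOTER.unpack(fh.read(FOOTER_SIZE))
        if magic != FOOTER_MAGIC:
            raise CorruptIndexError(f"bad index footer magic {magic!r}")
        if not INDEX_HEADER_SIZE + FOOTER_SIZE <= index_bytes <= size:
            raise CorruptIndexError(f"implausible index size {index_bytes}")
        fh.seek(size - index_bytes)
        imagic, data_bytes, _ = _INDEX_HEADER.unpack(fh.read(INDEX_HEADER_SIZE))
        if imagic != INDEX_MAGIC:
            raise CorruptIndexError(f"bad index header magic {imagic!r}")
        if data_bytes != size - index_bytes:
            raise IndexPairError(
                f"index claims {data_bytes} data bytes but the file holds "
                f"{size - index_bytes}; index and file are not paired"
            )
        comp = fh.read(index_bytes - INDEX_HEADER_SIZE - FOOTER_SIZE)
    if comp:
        try:
            payload = bytes(Zstd().decode(comp))
        except Exception as exc:
            raise CorruptIndexError(f"index ranges fail to decompress: {exc}") from exc
    else:
        payload = b""
    if len(payload) % RANGE_SIZE != 0:
        raise CorruptIndexError("index range section has a partial entry")
    ranges = [
        IndexRange(*_RANGE.unpack_from(payload, off))
        for off in range(0, len(payload), RANGE_SIZE)
    ]
    cum = 0
    prev_end = HEADER_SIZE
    for r in ranges:
        if r.offset < prev_end:
            raise CorruptIndexError("index ranges overlap or are unsorted")
        if r.cum_records != cum:
            raise CorruptIndexError("cumulative record counts are inconsistent")
        cum += r.n_records
        prev_end = r.offset + BLOCK_HEADER_SIZE + r.stored_size
    return BlockIndex(data_bytes=data_bytes, ranges=ranges)


class VbqWriter:
    """Streaming VBQ writer: sanitize -> pack -> block -> index."""

    def __init__(
        self,
        path: Union[str, Path],
        encoding: int = 2,
        *,
        compressed: bool = True,
        paired: bool = False,
        has_quality: bool = False,
        has_headers: bool = False,
        has_record_flags: bool = False,
        virtual_block_size: int = DEFAULT_BLOCK_SIZE,
        zstd_level: int = DEFAULT_ZSTD_LEVEL,
        policy: Optional[InvalidPolicy] = None,
    ):
        self.header = VbqHeader(
            encoding,
            has_quality=has_quality,
            compressed=compressed,
            paired=paired,
            has_headers=has_headers,
            has_record_flags=has_record_flags,
            virtual_block_size=virtual_block_size,
        )
        self.policy = policy
        self.path = Path(path)
        self._codec = Zstd(level=zstd_level)
        self._fh = open(path, "wb")
        self._fh.write(self.header.to_bytes())
        self._pending = bytearray()
        self._pending_records = 0
        self._ranges: List[IndexRange] = []
        self._cum = 0
        self.n_written = 0
        self.n_skipped = 0

    def _serialize(
        self,
        seq: bytes,
        ext: Optional[bytes],
        qual: Optional[bytes],
        ext_qual: Optional[bytes],
        name: Optional[bytes],
        ext_name: Optional[bytes],
        flag: int,
    ) -> bytes:
        h = self.header
        out = bytearray()
        if h.has_record_flags:
            out += struct.pack("<Q", flag)
        out += struct.pack("<Q", len(seq))
        if h.paired:
            out += struct.pack("<Q", len(ext))
        out += pack(seq, h.scheme).to_bytes()
        if h.paired:
            out += pack(ext, h.scheme).to_bytes()
        if h.has_quality:
            if qual is None or len(qual) != len(seq):
                raise FormatError("primary quality length must equal sequence length")
            out += qual
            if h.paired:
                if ext_qual is None or len(ext_qual) != len(ext):
                    raise FormatError("extended quality length must equal sequence length")
                out += ext_qual
        if h.has_headers:
            name = name or b""
            out += struct.pack("<H", len(name)) + name
            if h.paired:
                ext_name = ext_name or b""
                out += struct.pack("<H", len(ext_name)) + ext_name
        return bytes(out)

    def _append_payload(self, payload: bytes, n_records: int):
        if len(payload) > self.header.virtual_block_size:
            raise BlockSizeError(
                f"record of {len(payload)} bytes exceeds the virtual block size "
                f"{self.header.virtual_block_size}; increase the block size"
            )
        if len(self._pending) + len(payload) > self.header.virtual_block_size:
            self._flush_block()
        self._pending += payload
        self._pending_records += n_records

    def write(
        self,
        seq: bytes,
        ext: Optional[bytes] = None,
        *,
        qual: Optional[bytes] = None,
        ext_qual: Optional[bytes] = None,
        name: Optional[bytes] = None,
        ext_name: Optional[bytes] = None,
        flag: int = 0,
    ) -> bool:
        """Append one record; returns False if the skip policy dropped it."""
        if self.header.paired and ext is None:
            raise FormatError("paired VBQ file requires an extended sequence")
        if self.policy is not None:
            seq = sanitize(seq, self.policy, self.header.scheme)
            if self.header.paired and seq is not None:
                ext = sanitize(ext, self.policy, self.header.scheme)
            if seq is None or (self.header.paired and ext is None):
                self.n_skipped += 1
                return False
        self._append_payload(
            self._serialize(seq, ext, qual, ext_qual, name, ext_name, flag), 1
        )
        self.n_written += 1
        return True

    def write_batch(self, seqs: np.ndarray, exts: Optional[np.ndarray] = None) -> int:
        """Vectorized append of fixed-length ASCII matrices.

        Only available for the bare record layout (no qualities, headers or
        record flags); produces byte-identical output to repeated
        :meth:`write` calls.
        """
        h = self.header
        if h.has_quality or h.has_headers or h.has_record_flags:
            raise FormatError("write_batch supports only the bare record layout")
        if h.paired != (exts is not None):
            raise FormatError("batch pairing does not match the header")
        n, slen = seqs.shape
        columns = [np.full(n, slen, dtype=np.uint64)[:, None]]
        if exts is not None:
            columns.append(np.full(n, exts.shape[1], dtype=np.uint64)[:, None])
        columns.append(pack_matrix(seqs, h.scheme))
        if exts is not None:
            columns.append(pack_matrix(exts, h.scheme))
        rows = np.hstack(columns).astype("<u8", copy=False)
        rec_bytes = rows.shape[1] * 8
        per_block = h.virtual_block_size // rec_bytes
        if per_block == 0:
            raise BlockSizeError(
                f"record of {rec_bytes} bytes exceeds the virtual block size "
                f"{h.virtual_block_size}; increase the block size"
            )
        done = 0
        while done < n:
            # honour whatever is already pending before slicing full blocks
            room = (h.virtual_block_size - len(self._pending)) // rec_bytes
            if room == 0:
                self._flush_block()
                continue
            take = min(room, n - done)
            self._pending += rows[done : done + take].tobytes()
            self._pending_records += take
            done += take
        self.n_written += n
        return n

    def _flush_block(self):
        if self._pending_records == 0:
            return
        payload = bytes(self._pending)
        stored = self._codec.encode(payload) if self.header.compressed else payload
        offset = self._fh.tell()
        self._fh.write(
            _BLOCK_HEADER.pack(BLOCK_MAGIC, len(stored), self._pending_records, b"\x00" * 12)
        )
        self._fh.write(stored)
        self._ranges.append(
            IndexRange(offset, len(stored), self._pending_records, self._cum)
        )
        self._cum += self._pending_records
        self._pending = bytearray()
        self._pending_records = 0

    def close(self):
        if self._fh.closed:
            return
        self._flush_block()
        data_bytes = self._fh.tell()
        self._fh.write(write_index(self._ranges, data_bytes))
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


class VbqReader:
    """Index-driven VBQ reader; blocks decode independently."""

    def __init__(self, path: Union[str, Path]):
        self.path = Path(path)
        with open(path, "rb") as fh:
            self.header = VbqHeader.from_bytes(fh.read(HEADER_SIZE))
        self.index = load_index(path)
        self.ranges = self.index.ranges
        self._cum = [r.cum_records for r in self.ranges]
        self.n_records = self.index.n_records
        self._fh = open(path, "rb")
        self._codec = Zstd()

    @property
    def n_blocks(self) -> int:
        return len(self.ranges)

    def _block_payload(self, rng: IndexRange) -> bytes:
        self._fh.seek(rng.offset)
        magic, stored_size, n_records, _ = _BLOCK_HEADER.unpack(
            self._fh.read(BLOCK_HEADER_SIZE)
        )
        if magic != BLOCK_MAGIC:
            raise BlockCorruptionError(f"bad block magic {magic!r} at offset {rng.offset}")
        if stored_size != rng.stored_size or n_records != rng.n_records:
            raise BlockCorruptionError("block header disagrees with the index")
        stored = self._fh.read(stored_size)
        if len(stored) != stored_size:
            raise BlockCorruptionError("truncated block payload")
        payload = bytes(self._codec.decode(stored)) if self.header.compressed else stored
        if len(payload) > self.header.virtual_block_size:
            raise BlockCorruptionError("decompressed payload exceeds the virtual block size")
        return payload

    def read_block(self, rng: IndexRange) -> List[SeqRecord]:
        """Decode one block into its records; validates the record count."""
        payload = self._block_payload(rng)
        h = self.header
        records: List[SeqRecord] = []
        view = memoryview(payload)
        off = 0
        for _ in range(rng.n_records):
            try:
                flag = None
                if h.has_record_flags:
                    (flag,) = struct.unpack_from("<Q", view, off)
                    off += 8
                (slen,) = struct.unpack_from("<Q", view, off)
                off += 8
                xlen = 0
                if h.paired:
                    (xlen,) = struct.unpack_from("<Q", view, off)
                    off += 8
                nw = words_needed(slen, h.scheme)
                words = np.frombuffer(view, dtype="<u8", count=nw, offset=off)
                off += 8 * nw
                seq = unpack_words(words, slen, h.scheme)
                ext = None
                if h.paired:
                    xw = words_needed(xlen, h.scheme)
                    xwords = np.frombuffer(view, dtype="<u8", count=xw, offset=off)
                    off += 8 * xw
                    ext = unpack_words(xwords, xlen, h.scheme)
                qual = ext_qual = None
                if h.has_quality:
                    qual = bytes(view[off : off + slen])
                    off += slen
                    if h.paired:
                        ext_qual = bytes(view[off : off + xlen])
                        off += xlen
                name = ext_name = None
                if h.has_headers:
                    (nlen,) = struct.unpack_from("<H", view, off)
                    off += 2
                    name = bytes(view[off : off + nlen])
                    off += nlen
                    if h.paired:
                        (xnlen,) = struct.unpack_from("<H", view, off)
                        off += 2
                        ext_name = bytes(view[off : off + xnlen])
                        off += xnlen
            except struct.error as exc:
                raise BlockCorruptionError(f"block payload ends mid-record: {exc}") from exc
            records.append(
                SeqRecord(seq, ext, flag, qual, ext_qual, name, ext_name)
            )
        if off != len(payload):
            raise BlockCorruptionError(
                f"{len(payload) - off} trailing bytes after the last record of a block"
            )
        return records

    def __iter__(self) -> Iterator[SeqRecord]:
        for rng in self.ranges:
            yield from self.read_block(rng)

    def get_record(self, i: int) -> SeqRecord:
        """Global record i: binary search on cumulative counts, then in-block scan."""
        if not 0 <= i < self.n_records:
            raise IndexError(f"record index {i} out of range [0, {self.n_records})")
        b = bisect_right(self._cum, i) - 1
        rng = self.ranges[b]
        return self.read_block(rng)[i - rng.cum_records]

    def __len__(self) -> int:
        return self.n_records

    def close(self):
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()
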