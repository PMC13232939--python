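"""Two-bit / four-bit nucleotide packing into little-endian 64-bit words.

Sequences are stored as dense runs of per-base integer codes packed into
unsigned 64-bit words, base 0 in the least-significant bits, so that the
serialized (little-endian) byte stream is position-monotone.  The two-bit
scheme covers {A, C, G, T} (32 bases per word); the four-bit scheme keeps
the same code values in the low bits and additionally encodes N (16 bases
per word).  Code assignments are a package convention:

    A=0  C=1  G=2  T=3  and, in four-bit mode, N=8.

Words not completely filled by the final bases are zero-padded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import CorruptionError, EncodingError

WORD_SIZE = 8  # bytes per packed word

_INVALID = 0xFF


def _make_encode_table(pairs: dict[str, int]) -> np.ndarray:
    table = np.full(256, _INVALID, dtype=np.uint8)
    for base, code in pairs.items():
        table[ord(base)] = code
        table[ord(base.lower())] = code
    return table


_ENCODE_2 = _make_encode_table({"A": 0, "C": 1, "G": 2, "T": 3})
_ENCODE_4 = _make_encode_table({"A": 0, "C": 1, "G": 2, "T": 3, "N": 8})

_DECODE_2 = np.frombuffer(b"ACGT", dtype=np.uint8)
_DECODE_4 = np.full(16, _INVALID, dtype=np.uint8)
for _b, _c in {"A": 0, "C": 1, "G": 2, "T": 3, "N": 8}.items():
    _DECODE_4[_c] = ord(_b)


@dataclass(frozen=True)
class EncodingScheme:
    """Parameters of one packing scheme (bits_per_base * bases_per_word = 64)."""

    mode: str
    bits_per_base: int
    bases_per_word: int

    def __post_init__(self):
        if self.bits_per_base * self.bases_per_word != 64:
            raise ValueError("bits_per_base * bases_per_word must equal 64")

    @property
    def encode_table(self) -> np.ndarray:
        return _ENCODE_2 if self.bits_per_base == 2 else _ENCODE_4

    @property
    def decode_table(self) -> np.ndarray:
        return _DECODE_2 if self.bits_per_base == 2 else _DECODE_4

    @property
    def code_mask(self) -> int:
        return (1 << self.bits_per_base) - 1


TWO_BIT = EncodingScheme("two_bit", 2, 32)
FOUR_BIT = EncodingScheme("four_bit", 4, 16)


def scheme_for(encoding: int) -> EncodingScheme:
    """Map the on-disk encoding byte (2 or 4) to its scheme."""
    if encoding == 2:
        return TWO_BIT
    if encoding == 4:
        return FOUR_BIT
    raise ValueError(f"unsupported encoding {encoding!r}; expected 2 or 4")


def words_needed(n_bases: int, scheme: EncodingScheme) -> int:
    """Number of 64-bit words required to hold ``n_bases`` packed bases."""
    if n_bases < 0:
        raise ValueError("sequence length must be non-negative")
    return -(-n_bases // scheme.bases_per_word)


@dataclass
class PackedBuffer:
    """A length-tagged run of packed bases.

    ``words`` is a little-endian uint64 array of exactly
    ``ceil(n_bases / bases_per_word)`` entries; bit positions beyond the
    final base are zero.
    """

    n_bases: int
    words: np.ndarray

    def to_bytes(self) -> bytes:
        return self.words.astype("<u8", copy=False).tobytes()

    @classmethod
    def from_bytes(cls, data: bytes, n_bases: int) -> "PackedBuffer":
        return cls(n_bases, np.frombuffer(data, dtype="<u8").astype(np.uint64))

    def nbytes(self) -> int:
        return WORD_SIZE * len(self.words)


def _shifts(scheme: EncodingScheme) -> np.ndarray:
    return (np.arange(scheme.bases_per_word) * scheme.bits_per_base).astype(np.uint64)


def _pack_code_matrix(codes: np.ndarray, scheme: EncodingScheme) -> np.ndarray:
    """Pack an (n, L) uint8 code matrix into an (n, ceil(L/B)) uint64 matrix."""
    n, length = codes.shape
    B = scheme.bases_per_word
    nwords = -(-length // B)
    padded = np.zeros((n, nwords * B), dtype=np.uint64)
    padded[:, :length] = codes
    shifted = padded.reshape(n, nwords, B) << _shifts(scheme)
    return np.bitwise_or.reduce(shifted, axis=2)


def pack(seq: bytes, scheme: EncodingScheme = TWO_BIT) -> PackedBuffer:
    """Pack a byte-string of valid bases into 64-bit words.

    Raises :class:`EncodingError` naming the first offending position if a
    byte is not encodable under ``scheme``.
    """
    arr = np.frombuffer(bytes(seq), dtype=np.uint8)
    codes = scheme.encode_table[arr]
    bad = codes == _INVALID
    if bad.any():
        pos = int(np.argmax(bad))
        raise EncodingError(
            f"unencodable byte {chr(arr[pos])!r} at position {pos} "
            f"under {scheme.mode} encoding"
        )
    if codes.size == 0:
        return PackedBuffer(0, np.empty(0, dtype=np.uint64))
    words = _pack_code_matrix(codes[None, :], scheme)[0]
    return PackedBuffer(len(seq), words)


def pack_matrix(seqs: np.ndarray, scheme: EncodingScheme = TWO_BIT) -> np.ndarray:
    """Vectorized fixed-length packing of an (n, L) ASCII uint8 matrix."""
    codes = scheme.encode_table[seqs]
    if (codes == _INVALID).any():
        row, col = np.argwhere(codes == _INVALID)[0]
        raise EncodingError(
            f"unencodable byte {chr(seqs[row, col])!r} in record {row}, "
            f"position {col} under {scheme.mode} encoding"
        )
    return _pack_code_matrix(codes, scheme)


def unpack(buf: PackedBuffer, scheme: EncodingScheme = TWO_BIT) -> bytes:
    """Inverse of :func:`pack`; exact round trip for all valid inputs."""
    return unpack_words(buf.words, buf.n_bases, scheme)


def unpack_words(words: np.ndarray, n_bases: int, scheme: EncodingScheme) -> bytes:
    if n_bases == 0:
        return b""
    mask = np.uint64(scheme.code_mask)
    codes = (
        ((words.astype(np.uint64)[:, None] >> _shifts(scheme)) & mask)
        .astype(np.uint8)
        .reshape(-1)[:n_bases]
    )
    out = scheme.decode_table[codes]
    if scheme.bits_per_base == 4 and (out == _INVALID).any():
        pos = int(np.argmax(out == _INVALID))
        raise CorruptionError(
            f"four-bit code {codes[pos]} at base {pos} is not in the decode table"
        )
    return out.tobytes()


@dataclass
class InvalidPolicy:
    """Policy for bases not encodable under the active scheme.

    ``skip`` drops the whole record (sanitize returns None); ``random_replace``
    substitutes i.i.d. uniform draws from {A,C,G,T} using a generator seeded
    once from ``rng_seed`` (reproducible run-to-run); ``fixed_replace``
    substitutes ``fixed_base``.  Under four-bit encoding N is a valid base and
    is never touched.
    """

    kind: str
    fixed_base: Optional[str] = None
    rng_seed: Optional[int] = None
    _rng: Optional[np.random.Generator] = field(default=None, repr=False)

    def __post_init__(self):
        if self.kind not in ("skip", "random_replace", "fixed_replace"):
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if self.kind == "fixed_replace":
            if self.fixed_base is None or self.fixed_base.upper() not in "ACGT":
                raise ValueError("fixed_replace requires fixed_base in {A,C,G,T}")
            self.fixed_base = self.fixed_base.upper()
        if self.kind == "random_replace":
            if self.rng_seed is None:
                raise ValueError("random_replace requires rng_seed")
            self._rng = np.random.default_rng(self.rng_seed)

    @classmethod
    def skip(cls) -> "InvalidPolicy":
        return cls("skip")

    @classmethod
    def random(cls, seed: int) -> "InvalidPolicy":
        return cls("random_replace", rng_seed=seed)

    @classmethod
    def fixed(cls, base: str) -> "InvalidPolicy":
        return cls("fixed_replace", fixed_base=base)


_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


def sanitize(
    seq: bytes, policy: InvalidPolicy, scheme: EncodingScheme = TWO_BIT
) -> Optional[bytes]:
    """Apply an invalid-base policy; returns None as the skip-signal.

    Input is case-folded to uppercase before table lookup.  U (RNA) is treated
    as invalid and falls under the policy like any other non-encodable byte.
    """
    upper = bytes(seq).upper()
    arr = np.frombuffer(upper, dtype=np.uint8)
    invalid = scheme.encode_table[arr] == _INVALID
    if not invalid.any():
        return upper
    if policy.kind == "skip":
        return None
    out = arr.copy()
    if policy.kind == "fixed_replace":
        out[invalid] = ord(policy.fixed_base)
    else:
        out[invalid] = _ACGT[policy._rng.integers(0, 4, size=int(invalid.sum()))]
    return out.tobytes()
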