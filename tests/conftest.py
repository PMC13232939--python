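import random

import numpy as np
import pytest

# Independent scalar reference for the bit codec: one base at a time,
# shift-or into python ints. Kept deliberately separate from the package's
# vectorized implementation.
_CODES = {2: {"A": 0, "C": 1, "G": 2, "T": 3}, 4: {"A": 0, "C": 1, "G": 2, "T": 3, "N": 8}}


def scalar_pack(seq: bytes, bits: int) -> list[int]:
    codes = _CODES[bits]
    per_word = 64 // bits
    words = [0] * ((len(seq) + per_word - 1) // per_word)
    for i, ch in enumerate(seq.decode()):
        words[i // per_word] |= codes[ch] << (bits * (i % per_word))
    return words


def scalar_unpack(words: list[int], n_bases: int, bits: int) -> bytes:
    inv = {v: k for k, v in _CODES[bits].items()}
    per_word = 64 // bits
    mask = (1 << bits) - 1
    out = []
    for i in range(n_bases):
        code = (words[i // per_word] >> (bits * (i % per_word))) & mask
        out.append(inv[code])
    return "".join(out).encode()


def random_seq(rng: random.Random, length: int, alphabet: bytes = b"ACGT") -> bytes:
    return bytes(rng.choice(alphabet) for _ in range(length))


@pytest.fixture
def rng():
    return random.Random(20240917)


@pytest.fixture
def np_rng():
    return np.random.default_rng(20240917)
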