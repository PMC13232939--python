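import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from binseq import (
    BqHeader,
    BqReader,
    BqWriter,
    FormatError,
    InvalidPolicy,
    read_bq_header,
    record_offset,
    record_size,
)

from conftest import random_seq


@pytest.mark.parametrize(
    "slen,xlen,encoding,flag,expected",
    [
        (100, 0, 2, False, 32),
        (100, 0, 2, True, 40),
        (50, 150, 2, False, 56),
        (100, 0, 4, False, 56),
        (50, 150, 4, False, 112),
        (32, 0, 2, False, 8),
    ],
)
def test_record_size(slen, xlen, encoding, flag, expected):
    assert record_size(BqHeader(encoding, flag, slen, xlen)) == expected


def test_record_offset():
    h100 = BqHeader(2, False, 100)
    assert record_offset(0, h100) == 32
    assert record_offset(10, h100) == 32 + 10 * 32 == 352
    paired = BqHeader(2, False, 50, 150)
    assert record_offset(1, paired) == 88


def test_header_round_trip():
    h = BqHeader(4, True, 151, 49)
    assert len(h.to_bytes()) == 32
    assert BqHeader.from_bytes(h.to_bytes()) == h


@pytest.mark.parametrize(
    "mutation",
    [
        lambda b: b"XXXX" + b[4:],  # bad magic
        lambda b: b[:4] + b"\x09" + b[5:],  # unsupported version
        lambda b: b[:5] + b"\x03" + b[6:],  # bad encoding byte
        lambda b: b[:16] + b"\x01" * 16,  # dirty reserved bytes
    ],
)
def test_header_rejects_malformed(mutation):
    raw = BqHeader(2, False, 100).to_bytes()
    with pytest.raises(FormatError):
        BqHeader.from_bytes(mutation(raw))


def test_file_size_not_multiple_of_record_size(tmp_path):
    p = tmp_path / "t.bq"
    with BqWriter(p, slen=10) as w:
        w.write(b"ACGTACGTAC")
    with open(p, "ab") as fh:
        fh.write(b"\x00")
    with pytest.raises(FormatError):
        read_bq_header(p)


def test_write_read_round_trip_with_flags(tmp_path, rng):
    p = tmp_path / "t.bq"
    seqs = [random_seq(rng, 75) for _ in range(20)]
    with BqWriter(p, slen=75, encoding=2, flag_enabled=True) as w:
        for i, s in enumerate(seqs):
            w.write(s, flag=i * 13)
    with BqReader(p) as r:
        assert r.n_records == 20
        for i, rec in enumerate(r):
            assert rec.seq == seqs[i]
            assert rec.flag == i * 13


def test_paired_round_trip_and_file_size(tmp_path, rng):
    p = tmp_path / "t.bq"
    pairs = [(random_seq(rng, 50), random_seq(rng, 150)) for _ in range(10)]
    with BqWriter(p, slen=50, xlen=150) as w:
        for s, e in pairs:
            w.write(s, e)
    assert p.stat().st_size == 32 + 10 * 56
    with BqReader(p) as r:
        got = [(rec.seq, rec.ext) for rec in r]
    assert got == pairs


def test_length_mismatch_names_record_and_suggests_vbq(tmp_path):
    with BqWriter(tmp_path / "t.bq", slen=5) as w:
        w.write(b"ACGTA")
        with pytest.raises(FormatError, match="record 1.*VBQ"):
            w.write(b"ACGT")


def test_skip_policy_drops_and_counts(tmp_path):
    p = tmp_path / "t.bq"
    with BqWriter(p, slen=4, policy=InvalidPolicy.skip()) as w:
        assert w.write(b"ACGT")
        assert not w.write(b"ACNT")
        assert w.write(b"TTTT")
    assert w.n_written == 2 and w.n_skipped == 1
    with BqReader(p) as r:
        assert [rec.seq for rec in r] == [b"ACGT", b"TTTT"]


@settings(derandomize=True, max_examples=20, deadline=None)
@given(
    n=st.integers(min_value=0, max_value=40),
    slen=st.integers(min_value=1, max_value=70),
    encoding=st.sampled_from([2, 4]),
    flag=st.booleans(),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
)
def test_random_access_equals_sequential(tmp_path_factory, n, slen, encoding, flag, seed):
    """get_record(i) matches the i-th element of iteration at every index."""
    import random

    p = tmp_path_factory.mktemp("bq") / "t.bq"
    r = random.Random(seed)
    seqs = [random_seq(r, slen) for _ in range(n)]
    with BqWriter(p, slen=slen, encoding=encoding, flag_enabled=flag) as w:
        for i, s in enumerate(seqs):
            w.write(s, flag=i)
    assert p.stat().st_size == 32 + n * w.header.record_size()
    with BqReader(p) as reader:
        sequential = list(reader)
        for i in range(n):
            assert reader.get_record(i) == sequential[i]
            assert sequential[i].seq == seqs[i]


def test_get_record_out_of_range(tmp_path):
    p = tmp_path / "t.bq"
    with BqWriter(p, slen=4) as w:
        w.write(b"ACGT")
    with BqReader(p) as r:
        with pytest.raises(IndexError):
            r.get_record(1)
        with pytest.raises(IndexError):
            r.get_record(-1)


def test_stored_pad_bits_zero(tmp_path):
    """Bases beyond slen in the final word of each record are stored as 0."""
    p = tmp_path / "t.bq"
    with BqWriter(p, slen=3) as w:  # 3 bases in a 32-base word
        w.write(b"TTT")
    raw = p.read_bytes()[32:]
    (word,) = np.frombuffer(raw, dtype="<u8")
    assert int(word) == 0b111111  # three T=3 codes, everything above zero


def test_write_batch_matches_scalar_writes(tmp_path, np_rng):
    from binseq import random_base_matrix

    a, b = tmp_path / "a.bq", tmp_path / "b.bq"
    mat = random_base_matrix(50, 33, np_rng)
    ext = random_base_matrix(50, 17, np_rng)
    with BqWriter(a, slen=33, xlen=17, flag_enabled=True) as w:
        w.write_batch(mat, ext, flags=np.arange(50, dtype=np.uint64))
    with BqWriter(b, slen=33, xlen=17, flag_enabled=True) as w:
        for i in range(50):
            w.write(mat[i].tobytes(), ext[i].tobytes(), flag=i)
    assert a.read_bytes() == b.read_bytes()
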