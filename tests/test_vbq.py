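import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from binseq import (
    BlockCorruptionError,
    BlockSizeError,
    BqWriter,
    CorruptIndexError,
    FormatError,
    IndexPairError,
    VbqHeader,
    VbqReader,
    VbqWriter,
    load_index,
    serialized_record_size,
)

from conftest import random_seq


def test_header_round_trip_all_features():
    h = VbqHeader(
        4,
        has_quality=True,
        compressed=False,
        paired=True,
        has_headers=True,
        has_record_flags=True,
        virtual_block_size=4096,
    )
    assert len(h.to_bytes()) == 32
    assert VbqHeader.from_bytes(h.to_bytes()) == h


def test_header_rejects_bad_magic():
    raw = VbqHeader(2).to_bytes()
    with pytest.raises(FormatError):
        VbqHeader.from_bytes(b"NOPE" + raw[4:])


def test_block_packing_is_floor_greedy(tmp_path):
    """As many whole records as fit per block; never split across blocks."""
    rs = serialized_record_size(64)  # 8 + 8*2 = 24 bytes each
    p = tmp_path / "t.vbq"
    with VbqWriter(p, virtual_block_size=2 * rs + 10, compressed=False) as w:
        for _ in range(5):
            w.write(b"A" * 64)
    with VbqReader(p) as r:
        assert [rng.n_records for rng in r.ranges] == [2, 2, 1]


def test_block_boundary_exact_fit(tmp_path):
    rs = serialized_record_size(64)
    p = tmp_path / "t.vbq"
    with VbqWriter(p, virtual_block_size=rs, compressed=False) as w:
        for _ in range(3):
            w.write(b"C" * 64)
    with VbqReader(p) as r:
        assert [rng.n_records for rng in r.ranges] == [1, 1, 1]


def test_oversize_record_is_a_configuration_error(tmp_path):
    rs = serialized_record_size(64)
    with VbqWriter(tmp_path / "t.vbq", virtual_block_size=rs - 1) as w:
        with pytest.raises(BlockSizeError, match="block size"):
            w.write(b"G" * 64)


def test_index_round_trip_ten_blocks(tmp_path):
    p = tmp_path / "t.vbq"
    rs = serialized_record_size(32)
    with VbqWriter(p, virtual_block_size=3 * rs) as w:
        for _ in range(30):
            w.write(b"T" * 32)
    idx = load_index(p)
    assert len(idx.ranges) == 10
    assert sum(r.n_records for r in idx.ranges) == 30
    cum = 0
    for r in idx.ranges:
        assert r.cum_records == cum
        cum += r.n_records


def test_truncated_index_is_corrupt(tmp_path):
    p = tmp_path / "t.vbq"
    with VbqWriter(p) as w:
        w.write(b"ACGT")
    data = p.read_bytes()
    p.write_bytes(data[:-1])
    with pytest.raises(CorruptIndexError):
        load_index(p)


def test_mispaired_index_is_distinguishable(tmp_path):
    """Extra pre-index bytes break the data_bytes quick-check, not the magic."""
    p = tmp_path / "t.vbq"
    with VbqWriter(p) as w:
        w.write(b"ACGT")
    data = p.read_bytes()
    idx_bytes = int.from_bytes(data[-16:-8], "little")
    body, index = data[:-idx_bytes], data[-idx_bytes:]
    p.write_bytes(body + b"\x00" * 8 + index)
    with pytest.raises(IndexPairError):
        load_index(p)


def test_empty_file_has_empty_index(tmp_path):
    p = tmp_path / "t.vbq"
    VbqWriter(p).close()
    idx = load_index(p)
    assert idx.ranges == [] and idx.data_bytes == 32
    with VbqReader(p) as r:
        assert list(r) == [] and r.n_records == 0


def test_block_corruption_detected(tmp_path):
    p = tmp_path / "t.vbq"
    with VbqWriter(p, compressed=False) as w:
        for _ in range(4):
            w.write(b"ACGTACGT")
    with VbqReader(p) as r:
        rng = r.ranges[0]
        bad = type(rng)(rng.offset, rng.stored_size, rng.n_records + 1, rng.cum_records)
        with pytest.raises(BlockCorruptionError):
            r.read_block(bad)


record_configs = st.fixed_dictionaries(
    {
        "encoding": st.sampled_from([2, 4]),
        "compressed": st.booleans(),
        "paired": st.booleans(),
        "has_quality": st.booleans(),
        "has_headers": st.booleans(),
        "has_record_flags": st.booleans(),
        "seed": st.integers(min_value=0, max_value=2**31 - 1),
        "n": st.integers(min_value=0, max_value=30),
    }
)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(cfg=record_configs)
def test_lossless_round_trip_all_configurations(tmp_path_factory, cfg):
    """Write->read preserves sequences, qualities, headers, flags and order."""
    p = tmp_path_factory.mktemp("vbq") / "t.vbq"
    r = random.Random(cfg["seed"])
    alphabet = b"ACGT" if cfg["encoding"] == 2 else b"ACGTN"
    records = []
    for i in range(cfg["n"]):
        slen = r.randint(0, 120)
        xlen = r.randint(0, 120)
        records.append(
            dict(
                seq=random_seq(r, slen, alphabet),
                ext=random_seq(r, xlen, alphabet) if cfg["paired"] else None,
                qual=bytes(r.randint(33, 74) for _ in range(slen))
                if cfg["has_quality"]
                else None,
                ext_qual=bytes(r.randint(33, 74) for _ in range(xlen))
                if cfg["has_quality"] and cfg["paired"]
                else None,
                name=b"read/%d" % i if cfg["has_headers"] else None,
                ext_name=b"mate/%d" % i if cfg["has_headers"] and cfg["paired"] else None,
                flag=r.randint(0, 2**63) if cfg["has_record_flags"] else 0,
            )
        )
    with VbqWriter(
        p,
        encoding=cfg["encoding"],
        compressed=cfg["compressed"],
        paired=cfg["paired"],
        has_quality=cfg["has_quality"],
        has_headers=cfg["has_headers"],
        has_record_flags=cfg["has_record_flags"],
        virtual_block_size=600,
    ) as w:
        for rec in records:
            w.write(
                rec["seq"],
                rec["ext"],
                qual=rec["qual"],
                ext_qual=rec["ext_qual"],
                name=rec["name"],
                ext_name=rec["ext_name"],
                flag=rec["flag"],
            )
    with VbqReader(p) as reader:
        got = list(reader)
        assert len(got) == cfg["n"]
        for i, (rec, out) in enumerate(zip(records, got)):
            assert out.seq == rec["seq"]
            assert out.ext == rec["ext"]
            assert out.qual == rec["qual"]
            assert out.ext_qual == rec["ext_qual"]
            assert out.name == rec["name"]
            assert out.ext_name == rec["ext_name"]
            assert out.flag == (rec["flag"] if cfg["has_record_flags"] else None)
        # global random access agrees with iteration order
        for i in range(cfg["n"]):
            assert reader.get_record(i) == got[i]


def test_decompressed_payload_never_exceeds_virtual_block_size(tmp_path, rng):
    p = tmp_path / "t.vbq"
    vbs = 300
    with VbqWriter(p, virtual_block_size=vbs) as w:
        for _ in range(50):
            w.write(random_seq(rng, rng.randint(1, 80)))
    with VbqReader(p) as r:
        for block_range in r.ranges:
            assert len(r._block_payload(block_range)) <= vbs


def test_compressed_vbq_smaller_than_bq_for_fixed_reads(tmp_path, np_rng):
    """Compression recovers the pad zeros: two-bit VBQ < BQ on 100 bp reads."""
    from binseq import random_base_matrix

    mat = random_base_matrix(20000, 100, np_rng)
    bq, vbq = tmp_path / "t.bq", tmp_path / "t.vbq"
    with BqWriter(bq, slen=100) as w:
        w.write_batch(mat)
    with VbqWriter(vbq, compressed=True) as w:
        w.write_batch(mat)
    assert vbq.stat().st_size < bq.stat().st_size


def test_write_batch_identical_to_scalar_path(tmp_path, np_rng):
    from binseq import random_base_matrix

    mat = random_base_matrix(200, 45, np_rng)
    ext = random_base_matrix(200, 61, np_rng)
    a, b = tmp_path / "a.vbq", tmp_path / "b.vbq"
    with VbqWriter(a, paired=True, virtual_block_size=1000) as w:
        w.write_batch(mat, ext)
    with VbqWriter(b, paired=True, virtual_block_size=1000) as w:
        for i in range(200):
            w.write(mat[i].tobytes(), ext[i].tobytes())
    assert a.read_bytes() == b.read_bytes()
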