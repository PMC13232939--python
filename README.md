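# binseq

Binary containers for nucleotide sequences, built for parallel access.

Modern sequencers emit billions of short reads that are usually stored as
gzip-compressed FASTQ. That format forces single-threaded decompression
and sequential parsing of irregular records, so embarrassingly parallel
workloads (k-mer counting, mapping, assembly) end up I/O-bound. `binseq`
implements two complementary binary formats that remove that bottleneck,
plus the tooling around them:

- **BQ** (`.bq`) — fixed-length reads as fixed-size records. Each base is
  packed at 2 bits (A, C, G, T) or 4 bits (adds N) into little-endian
  64-bit words, so a record with primary length *N* and optional mate
  length *M* occupies

  S = F + 8·(⌈N/B⌉ + ⌈M/B⌉)

  bytes, where *B* is 32 (two-bit) or 16 (four-bit) bases per word and
  *F* ∈ {0, 8} is the optional per-record flag field. Record *i* starts at
  byte 32 + *i*·S: true random access with no index and no decompression.
- **VBQ** (`.vbq`) — variable-length records, optionally with quality
  scores, sequence headers and per-record flags, packed into blocks of a
  fixed uncompressed budget. Each block is independently ZSTD-compressed;
  a compressed index at the end of the file maps every block to its
  offset, stored size, and cumulative record count, so blocks decode in
  parallel.
- a hook-based **map-reduce interface** (`process_record` /
  `on_batch_complete`) that partitions BQ files by record range and VBQ
  files by block,
- a deterministic **uniform-random read generator**,
- a **`binseq` CLI**: `encode`, `decode`, `info`, `generate`, `count`
  (naive parallel k-mer counter), `scan`.

Single- and paired-end reads live unambiguously in one file. Invalid
bases are handled by an explicit policy: skip the record, replace with
random bases (seeded), replace with a fixed base — or keep N via four-bit
encoding.

## Worked example

```sh
$ binseq generate -n 50 -l 100 --seed 3 -o g.fastq   # 50 uniform 100 bp reads
$ binseq encode -i g.fastq -o g.bq
written=50 skipped=0
$ binseq info -i g.bq
format=bq
encoding=2
flag_enabled=0
slen=100
xlen=0
record_size=32
records=50
$ binseq scan -i g.bq
records=50 bases=5000
```

`record_size=32` is the identity above with F=0: 8·⌈100/32⌉ = 32 bytes per
100 bp read, and the file is exactly 32 + 50·32 = 1632 bytes. A lossless
round trip keeps qualities and headers by using VBQ archive mode:

```sh
$ binseq encode -i g.fastq -o g.vbq --archive   # four-bit + qualities + headers
$ binseq decode -i g.vbq -o back.fastq
$ cmp g.fastq back.fastq && echo identical
identical
```

`binseq count -i g.bq -k 8 --threads 4` prints a tab-separated k-mer/count
table; the result is identical for any thread count.

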