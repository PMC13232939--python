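# Methods

## Bit-level encoding

Bases map to small integer codes packed into unsigned 64-bit words,
base 0 in the least-significant bits, words serialized little-endian, so
the byte stream is monotone in base position. The code assignment is a
package convention:

| base | two-bit | four-bit |
|------|---------|----------|
| A    | 0       | 0        |
| C    | 1       | 1        |
| G    | 2       | 2        |
| T    | 3       | 3        |
| N    | —       | 8        |

Four-bit codes keep the two-bit values in the low bits; N sets the fourth
bit. Words not filled by the final bases are zero-padded, which both
fixes the serialized length at `8·⌈n/B⌉` bytes and makes pad bytes
compressible. Files written by this package are internally consistent,
but no bit-compatibility with other BINSEQ implementations is claimed:
their magic constants and exact code tables are not published.

Input is case-folded before lookup. `U` is deliberately *not* mapped to
`T`: RNA input falls under the invalid-base policy so the substitution is
always explicit. The policy itself has three modes — `skip` (drop the
whole record; skipping is record-granular, not per-base), `random_replace`
(i.i.d. uniform A/C/G/T from a generator seeded once at policy creation,
so a fixed seed reproduces byte-identical output), and `fixed_replace`.
Under four-bit encoding N is a first-class base and never triggers the
policy.

The packing kernel is vectorized with numpy (table lookup, per-lane shift,
or-reduction); `pack_matrix` amortizes it over fixed-length batches. The
test suite checks it word-for-word against an independent scalar per-base
reference.

## BQ layout

32-byte header (magic `BSQ\x01`, version, encoding byte, flag switch,
`slen`, `xlen`, zero reserved bytes — reserved bytes are validated on
read), then `n` records of identical size `S = F + 8·(⌈slen/B⌉ +
⌈xlen/B⌉)`. The file-size identity `size = 32 + n·S` is asserted on every
writer close. `get_record(i)` seeks straight to `32 + i·S`; no preceding
record is ever parsed. The optional 64-bit flag (F = 8) defaults to 0 and
is off by default — the published fixed-length storage figures imply
flag-less records, and the CLI follows that default. Paired records store
flag, primary words, extended words, in that order.

BQ stores no qualities or identifiers by design; decoding therefore emits
FASTA with zero-padded ordinal identifiers (`r000000000`, …) unless a
constant fake quality character is requested.

## VBQ layout

Records serialize as `flag? | slen | xlen? | primary words | extended
words | primary qual | extended qual | primary header (u16 length prefix)
| extended header`, with lengths as unsigned 64-bit for uniformity and
qualities as raw Phred+33 bytes. A block accumulates whole records until
the next one would push the uncompressed payload past
`virtual_block_size`; records never straddle blocks, and a single record
larger than the budget is a configuration error that names the remedy.
The final partial block is written as a normal smaller block.
`virtual_block_size` counts payload bytes only (the 32-byte block header
is excluded) and defaults to 128 KiB — large enough that zstd sees
meaningful windows, small enough for fine-grained parallelism; it is
CLI-configurable. Compression is zstd level 3 by default, so stored block
sizes are never part of exact assertions anywhere in the package.

The trailing index is a 32-byte uncompressed header carrying the byte
count of the pre-index region (a quick check that index and file belong
together — a mismatch raises a distinct pairing error, a bad magic a
distinct corruption error), the zstd-compressed run of 32-byte
`(offset, stored_size, n_records, cum_records)` ranges, and a 16-byte
footer with the total index byte count and a closing magic. Start/end
block locations are realized as (offset, stored size) — the end is
derivable, avoiding redundancy. With zero blocks the range section is
written as zero bytes rather than an empty zstd frame (the zstd binding
cannot round-trip an empty frame). The index is embedded at the end of
the file rather than kept as a sidecar, and is read first so blocks can
be fetched and decompressed independently; `get_record(i)` binary-searches
the cumulative record counts and scans inside one block.

## Parallel processing

`process_parallel` implements the map-reduce contract: a user factory
builds one `RecordProcessor` per worker; `process_record` mutates
worker-local state; `on_batch_complete` merges into shared results, called
after every `batch_size` records and once more at drain when a partial
batch remains. Partitions are contiguous record ranges for BQ (random
access makes any range addressable) and whole blocks for VBQ. The worker
model is an execution contract, realized here with threads, each holding
its own file handle; correctness must not depend on scheduling, so
aggregations are expected to be commutative monoids — under that
assumption results are identical for any worker count, which the suite
verifies for 1–8 workers. Throughput scaling is a property of the runtime
and hardware, not of this contract, and is only smoke-tested for
non-degradation.

The k-mer counter is the exemplar: worker-local hashmaps, a locked global
table updated at batch boundaries, literal k-mer strings with no
reverse-complement canonicalization (so four-bit sources can yield k-mers
containing N). The default k of 8 keeps the demonstration in the
low-complexity regime the workload is meant to represent.

## Synthetic data

The generator emulates the format-benchmark input convention: every base
i.i.d. uniform over {A, C, G, T}, every quality line a constant `?`, 4-line
FASTQ with `@r{ordinal}` identifiers, byte-deterministic under a seed.
Standard conditions are 10 million records, 100 bp single-end or 50+150 bp
paired-end. It models none of the structure of real reads — no error or
quality distributions, no genomic repeat structure, no length variation —
so passing tests demonstrate format correctness and exact storage
arithmetic, not compression ratios or throughput on real data. Real-data
behaviour (e.g. quality-heavy archives) will differ chiefly in VBQ
compressed sizes, which are excluded from exact assertions for that
reason. Because the identifier format is a package convention, plain-text
FASTQ/FASTA sizes derived from it are likewise not treated as comparable
quantities.

## Composite format score

For comparing formats the package includes the equal-weight composite
`m_i = (t̄_i + s̄_i)/2`, where time and storage are each min–max normalized
to [0, 1] across the formats compared. It is undefined (an error) when a
metric is constant across entries, and it is a pure function of measured
inputs — the package never asserts specific timing values.

## Problem sizes and numerical choices

The test suite exercises the storage identity with a real 100,000-record
encode per configuration and checks the 10-million-record figures through
the closed-form record-size arithmetic; `scripts/acceptance.py` performs
the full 10-million-record encodes (about four minutes on one core, ~1 GiB
of temporary files, deleted as it goes). Codec equivalence is checked on
10,000 random sequences of lengths 0–1000 under both schemes. Ties and
degenerate inputs: empty sequences pack to zero words; empty files are
valid in both formats (BQ: header only; VBQ: header plus an empty index);
`skip` applies to a pair if either mate contains an invalid base.

## Known limitations

- No SIMD or memory-mapped fast paths; throughput is not a goal here.
- No IUPAC ambiguity codes beyond N; no interleaved FASTQ; no SAM/BAM/
  CRAM conversion; no mid-file appends or concurrent writers.
- Thread-based workers serialize Python-level map work under the GIL;
  the parallel interface guarantees semantics, not speedup.
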