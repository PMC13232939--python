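"""Hook-based map-reduce processing over BQ/VBQ sources.

Each worker owns a :class:`RecordProcessor` built by a user factory and an
independent file handle.  The worker calls ``process_record`` on every
record of its partition and ``on_batch_complete`` after every
``batch_size`` records and again at drain time, so worker-local state is
merged into shared results at predictable points.  Correctness must not
depend on which worker sees which record: aggregations are expected to be
commutative monoids, in which case the merged result is identical for any
worker count or scheduling.

Partitioning follows each format's natural parallel unit: BQ files split
into contiguous record ranges (random access makes any range addressable
in O(1)); VBQ files split by whole blocks, which decompress independently.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from concurrent.futures import ThreadPoolExecutor
from pathlib import Path
from typing import Callable, List, Sequence, Tuple, Union

from .bq import BQ_MAGIC, BqReader
from .errors import FormatError, ParallelError
from .vbq import VBQ_MAGIC, VbqReader

DEFAULT_BATCH_SIZE = 4096


class RecordProcessor(ABC):
    """Map-reduce contract: per-record map, per-batch reduce."""

    @abstractmethod
    def process_record(self, record) -> None:
        """Consume one record, mutating worker-local state only."""

    @abstractmethod
    def on_batch_complete(self) -> None:
        """Merge worker-local state into the shared result (may lock)."""


def _sniff_format(source: Union[str, Path]) -> str:
    with open(source, "rb") as fh:
        magic = fh.read(4)
    if magic == BQ_MAGIC:
        return "bq"
    if magic == VBQ_MAGIC:
        return "vbq"
    raise FormatError(f"{source}: not a BQ or VBQ file (magic {magic!r})")


def _split_ranges(n: int, parts: int) -> List[Tuple[int, int]]:
    """Contiguous near-equal [lo, hi) partitions covering [0, n)."""
    base, extra = divmod(n, parts)
    out, lo = [], 0
    for p in range(parts):
        hi = lo + base + (1 if p < extra else 0)
        out.append((lo, hi))
        lo = hi
    return out


def _run_bq_partition(source, processor, lo, hi, batch_size):
    with BqReader(source) as reader:
        pending = 0
        for rec in reader.iter_range(lo, hi):
            processor.process_record(rec)
            pending += 1
            if pending == batch_size:
                processor.on_batch_complete()
                pending = 0
        if pending:
            processor.on_batch_complete()


def _run_vbq_partition(source, processor, ranges, batch_size):
    with VbqReader(source) as reader:
        pending = 0
        for rng in ranges:
            for rec in reader.read_block(rng):
                processor.process_record(rec)
                pending += 1
                if pending == batch_size:
                    processor.on_batch_complete()
                    pending = 0
        if pending:
            processor.on_batch_complete()


def process_parallel(
    source: Union[str, Path],
    factory: Callable[[], RecordProcessor],
    n_workers: int = 1,
    batch_size: int = DEFAULT_BATCH_SIZE,
) -> List[RecordProcessor]:
    """Process every record of a BQ/VBQ file exactly once across workers.

    Returns the worker processors after all partitions drain; merged results
    live wherever ``on_batch_complete`` put them (typically a shared,
    locked structure closed over by ``factory``).
    """
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    fmt = _sniff_format(source)
    if fmt == "bq":
        with BqReader(source) as reader:
            n = reader.n_records
        partitions: Sequence = _split_ranges(n, min(n_workers, max(n, 1)))
        runner = lambda proc, part: _run_bq_partition(
            source, proc, part[0], part[1], batch_size
        )
    else:
        with VbqReader(source) as reader:
            blocks = list(reader.ranges)
        parts = min(n_workers, max(len(blocks), 1))
        cuts = _split_ranges(len(blocks), parts)
        partitions = [blocks[lo:hi] for lo, hi in cuts]
        runner = lambda proc, part: _run_vbq_partition(source, proc, part, batch_size)

    processors = [factory() for _ in partitions]
    if len(partitions) == 1:
        try:
            runner(processors[0], partitions[0])
        except Exception as exc:
            raise ParallelError(
                f"worker failed on partition {partitions[0]!r}: {exc}",
                partition=partitions[0],
            ) from exc
        return processors

    with ThreadPoolExecutor(max_workers=len(partitions)) as pool:
        futures = [
            pool.submit(runner, proc, part)
            for proc, part in zip(processors, partitions)
        ]
        for fut, part in zip(futures, partitions):
            try:
                fut.result()
            except Exception as exc:
                raise ParallelError(
                    f"worker failed on partition {part!r}: {exc}", partition=part
                ) from exc
    return processors
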