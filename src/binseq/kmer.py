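"""Naive parallel k-mer counting and sequence-access scanning.

The counter is the exemplar of the map-reduce hooks: each worker slides a
window of size k over every decoded sequence and tallies into a
worker-local hashmap; at batch boundaries the shared global table is
locked, updated from the local table, and the local table is cleared.
K-mers are literal strings — no reverse-complement canonicalization — so
under four-bit sources k-mers may contain N.
"""

from __future__ import annotations

import threading
from collections import Counter
from pathlib import Path
from typing import Dict, List, Sequence, Union

from .parallel import DEFAULT_BATCH_SIZE, RecordProcessor, process_parallel


class KmerCounter(RecordProcessor):
    """Worker-local k-mer table merged into a shared dict under a lock."""

    def __init__(self, k: int, shared: Dict[bytes, int], lock: threading.Lock):
        self.k = k
        self.shared = shared
        self.lock = lock
        self.local: Counter = Counter()

    def _count(self, seq: bytes) -> None:
        k = self.k
        local = self.local
        for i in range(len(seq) - k + 1):
            local[seq[i : i + k]] += 1

    def process_record(self, record) -> None:
        self._count(record.seq)
        if record.ext is not None:
            self._count(record.ext)

    def on_batch_complete(self) -> None:
        with self.lock:
            for kmer, n in self.local.items():
                self.shared[kmer] = self.shared.get(kmer, 0) + n
        self.local.clear()


def count_kmers(
    source: Union[str, Path],
    k: int,
    n_workers: int = 1,
    batch_size: int = DEFAULT_BATCH_SIZE,
) -> Dict[bytes, int]:
    """Count every length-k substring of every record in a BQ/VBQ file."""
    if k < 1:
        raise ValueError("k must be >= 1")
    shared: Dict[bytes, int] = {}
    lock = threading.Lock()
    process_parallel(
        source, lambda: KmerCounter(k, shared, lock), n_workers, batch_size
    )
    return shared


class SequenceScanner(RecordProcessor):
    """Tally records and bases; the minimal sequence-access workload."""

    def __init__(self, shared: Dict[str, int], lock: threading.Lock):
        self.shared = shared
        self.lock = lock
        self.records = 0
        self.bases = 0

    def process_record(self, record) -> None:
        self.records += 1
        self.bases += record.total_bases()

    def on_batch_complete(self) -> None:
        with self.lock:
            self.shared["records"] += self.records
            self.shared["bases"] += self.bases
        self.records = 0
        self.bases = 0


def scan_sequences(source: Union[str, Path], n_workers: int = 1) -> Dict[str, int]:
    """Read every sequence, returning total record and base counts."""
    shared = {"records": 0, "bases": 0}
    lock = threading.Lock()
    process_parallel(source, lambda: SequenceScanner(shared, lock), n_workers)
    return shared


def composite_score(times: Sequence[float], sizes: Sequence[float]) -> List[float]:
    """Equal-weight mean of min-max-normalized time and storage.

    For format i, m_i = (t̄_i + s̄_i) / 2 where t̄ and s̄ rescale each metric
    to [0, 1] over the formats compared (0 best, 1 worst).  Requires at
    least two entries and a non-degenerate range in both metrics.
    """
    if len(times) != len(sizes):
        raise ValueError("times and sizes must have equal length")
    if len(times) < 2:
        raise ValueError("composite score needs at least two formats")
    tmin, tmax = min(times), max(times)
    smin, smax = min(sizes), max(sizes)
    if tmax == tmin or smax == smin:
        raise ValueError("degenerate range: min equals max in a metric")
    return [
        ((t - tmin) / (tmax - tmin) + (s - smin) / (smax - smin)) / 2
        for t, s in zip(times, sizes)
    ]
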