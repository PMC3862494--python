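"""Two-phase external-memory compression via prefix partitioning.

When a read collection is too large to sort in memory, it is first
distributed over temporary spill files keyed by the first ``k`` bases
of each (N-substituted) read — the most-significant-digit radix idea.
``k`` is the smallest prefix depth for which the expected partition
payload ``n * L / 4**k`` fits inside the configured memory budget
(scaled by a fill factor that leaves headroom for the trie).  Each
spill file is then loaded, sorted with the burst trie, encoded, and
appended to the container as one independent block, visiting keys in
lexicographic order so the concatenation of blocks is globally sorted.

Each block restarts delta coding (its first read is encoded as value+1)
and numbers its N-position G-ordinals locally, so blocks can be encoded
and decoded independently of one another.

A partition that still exceeds the budget — possible under skewed base
composition — is re-split on disk with a one-base-deeper prefix before
loading, recursively.
"""

from __future__ import annotations

import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, BinaryIO, Iterable, Iterator

from . import ambiguity
from .burstsort import DEFAULT_BUCKET_CAPACITY, TrieStats, sort_reads
from .container import BlockRecord, encode_block, write_container
from .errors import InfeasibleBudgetError, UniformLengthError
from .readcodec import ReadBatch
from .seqio import read_sequences

__all__ = [
    "DEFAULT_MEMORY_BUDGET",
    "DEFAULT_FILL_FACTOR",
    "PartitionPlan",
    "CompressionReport",
    "plan_partitions",
    "spill",
    "process_partitions",
    "compress_reads",
    "compress_file",
]

DEFAULT_MEMORY_BUDGET = 1 << 30  # 1 GiB of raw read payload
DEFAULT_FILL_FACTOR = 0.5

_Entry = tuple[str, tuple[int, ...]]


@dataclass
class PartitionPlan:
    """Partitioning decision: prefix depth and the budget it satisfies."""

    prefix_depth: int
    memory_budget: int
    fill_factor: float = DEFAULT_FILL_FACTOR

    @property
    def effective_budget(self) -> float:
        return self.memory_budget * self.fill_factor


@dataclass
class CompressionReport:
    """Summary returned by the compression entry points."""

    read_count: int = 0
    read_length: int = 0
    n_count: int = 0
    block_count: int = 0
    prefix_depth: int = 0
    payload_bytes: int = 0
    container_bytes: int = 0
    trie_nodes: int = 0
    trie_buckets: int = 0
    trie_bursts: int = 0

    @property
    def bits_per_base(self) -> float | None:
        bases = self.read_count * self.read_length
        if not bases:
            return None
        return 8.0 * self.payload_bytes / bases


def plan_partitions(
    read_count: int,
    read_length: int,
    memory_budget: int = DEFAULT_MEMORY_BUDGET,
    fill_factor: float = DEFAULT_FILL_FACTOR,
) -> PartitionPlan:
    """Choose the smallest prefix depth whose expected partition size
    fits in memory.

    Raises :class:`InfeasibleBudgetError` when even one partition per
    full read (depth L) is expected to overflow the budget.
    """
    if read_count < 0 or read_length < 1 or memory_budget <= 0:
        raise ValueError("need read_count >= 0, read_length >= 1, budget > 0")
    if not 0.0 < fill_factor <= 1.0:
        raise ValueError("fill_factor must lie in (0, 1]")
    effective = memory_budget * fill_factor
    k = 0
    while read_count * read_length / 4**k > effective:
        if k == read_length:
            raise InfeasibleBudgetError(
                f"{read_count} reads of length {read_length} cannot be "
                f"partitioned under a budget of {memory_budget} bytes"
            )
        k += 1
    return PartitionPlan(k, memory_budget, fill_factor)


class _SpillSet:
    """Prefix-keyed temp files of substituted reads and their N marks.

    Spill lines are an internal format: the read, then optionally a tab
    and comma-separated 0-based N positions.
    """

    def __init__(self, tmp_dir: Path) -> None:
        self.tmp_dir = tmp_dir
        self.files: dict[str, Path] = {}
        self.counts: dict[str, int] = {}
        self._handles: dict[str, IO[str]] = {}

    def add(self, key: str, entry: _Entry) -> None:
        handle = self._handles.get(key)
        if handle is None:
            path = self.tmp_dir / f"part_{key or 'all'}.tmp"
            handle = open(path, "wt")
            self._handles[key] = handle
            self.files[key] = path
            self.counts[key] = 0
        seq, marks = entry
        if marks:
            handle.write(f"{seq}\t{','.join(map(str, marks))}\n")
        else:
            handle.write(f"{seq}\n")
        self.counts[key] += 1

    def close(self) -> None:
        for handle in self._handles.values():
            handle.close()
        self._handles.clear()

    def load(self, key: str) -> list[_Entry]:
        entries: list[_Entry] = []
        with open(self.files[key], "rt") as handle:
            for line in handle:
                line = line.rstrip("\n")
                if "\t" in line:
                    seq, raw_marks = line.split("\t", 1)
                    marks = tuple(int(p) for p in raw_marks.split(","))
                else:
                    seq, marks = line, ()
                entries.append((seq, marks))
        return entries

    def discard(self, key: str) -> None:
        self.files.pop(key).unlink(missing_ok=True)
        self.counts.pop(key, None)


def spill(
    entries: Iterable[_Entry], plan: PartitionPlan, tmp_dir: Path
) -> _SpillSet:
    """Distribute substituted reads into prefix-keyed temp files."""
    spills = _SpillSet(tmp_dir)
    k = plan.prefix_depth
    try:
        for entry in entries:
            spills.add(entry[0][:k], entry)
    finally:
        spills.close()
    return spills


def _encode_entries(
    entries: list[_Entry],
    read_length: int,
    capacity: int,
    report: CompressionReport,
) -> BlockRecord:
    batch = ReadBatch(
        reads=[seq for seq, _ in entries],
        read_length=read_length,
        n_marks=[marks for _, marks in entries],
    )
    stats = TrieStats()
    sorted_batch = sort_reads(batch, capacity, stats_out=stats)
    report.trie_nodes += stats.nodes
    report.trie_buckets += stats.buckets
    report.trie_bursts += stats.bursts
    return encode_block(sorted_batch)


def process_partitions(
    spills: _SpillSet,
    read_length: int,
    plan: PartitionPlan,
    capacity: int,
    report: CompressionReport,
) -> Iterator[BlockRecord]:
    """Sort and encode every partition in lexicographic key order.

    Spill files are deleted as soon as their block is produced.  A
    partition whose actual payload still exceeds the effective budget
    is re-spilled with a one-base-deeper prefix and processed
    recursively, keeping global key order intact (deeper keys extend
    their parent prefix).
    """
    for key in sorted(spills.files):
        entries = None
        count = spills.counts[key]
        oversized = (
            count * read_length > plan.effective_budget
            and len(key) < read_length
        )
        if oversized:
            entries = spills.load(key)
            spills.discard(key)
            deeper = _SpillSet(spills.tmp_dir)
            try:
                k = len(key) + 1
                for entry in entries:
                    deeper.add(entry[0][:k], entry)
            finally:
                deeper.close()
            del entries
            yield from process_partitions(
                deeper, read_length, plan, capacity, report
            )
        else:
            entries = spills.load(key)
            spills.discard(key)
            yield _encode_entries(entries, read_length, capacity, report)


def compress_reads(
    raw_reads: Iterable[str],
    sink: BinaryIO,
    *,
    bucket_capacity: int = DEFAULT_BUCKET_CAPACITY,
    prefix_depth: int = 0,
    memory_budget: int = DEFAULT_MEMORY_BUDGET,
    tmp_dir: str | Path | None = None,
) -> CompressionReport:
    """Compress an in-memory iterable of raw reads (N allowed).

    ``prefix_depth`` = 0 runs the single-block in-memory path; a
    positive depth exercises the external two-phase path with spill
    files under ``tmp_dir`` (a private temp directory by default).
    """
    report = CompressionReport(prefix_depth=prefix_depth)
    blocks: list[BlockRecord] = []
    if prefix_depth == 0:
        batch = ambiguity.substitute_ns(raw_reads)
        report.read_count = len(batch)
        report.read_length = batch.read_length
        report.n_count = batch.n_count
        if len(batch):
            stats = TrieStats()
            sorted_batch = sort_reads(batch, bucket_capacity, stats_out=stats)
            report.trie_nodes = stats.nodes
            report.trie_buckets = stats.buckets
            report.trie_bursts = stats.bursts
            blocks.append(encode_block(sorted_batch))
    else:
        # stream reads straight into spill files; only one partition is
        # ever resident in memory at a time
        plan = PartitionPlan(prefix_depth, memory_budget)
        scratch = _Scratch(tmp_dir)
        try:
            spills = spill(
                _substituted_stream(raw_reads, report), plan, scratch.path
            )
            if report.read_count:
                blocks.extend(
                    process_partitions(
                        spills, report.read_length, plan, bucket_capacity,
                        report,
                    )
                )
        finally:
            scratch.cleanup()
    report.block_count = len(blocks)
    report.payload_bytes = sum(b.payload_bytes for b in blocks)
    report.container_bytes = write_container(
        blocks, report.read_length, sink
    )
    return report


def _substituted_stream(
    raw_reads: Iterable[str], report: CompressionReport
) -> Iterator[_Entry]:
    for i, raw in enumerate(raw_reads):
        seq, marks = ambiguity.substitute_read(raw)
        if report.read_count == 0:
            report.read_length = len(seq)
        elif len(seq) != report.read_length:
            raise UniformLengthError(
                f"read {i} has length {len(seq)}, "
                f"expected {report.read_length}"
            )
        report.read_count += 1
        report.n_count += len(marks)
        yield seq, marks


class _Scratch:
    """A scratch directory that is always removed, even on failure."""

    def __init__(self, tmp_dir: str | Path | None) -> None:
        base = Path(tmp_dir) if tmp_dir is not None else None
        if base is not None:
            base.mkdir(parents=True, exist_ok=True)
        self.path = Path(tempfile.mkdtemp(prefix="srcomp_", dir=base))

    def cleanup(self) -> None:
        shutil.rmtree(self.path, ignore_errors=True)


def compress_file(
    input_path: str | Path,
    output_path: str | Path,
    *,
    fmt: str | None = None,
    bucket_capacity: int = DEFAULT_BUCKET_CAPACITY,
    memory_budget: int = DEFAULT_MEMORY_BUDGET,
    prefix_depth: int | None = None,
    tmp_dir: str | Path | None = None,
) -> CompressionReport:
    """Compress a FASTQ/FASTA/lines file into an .srcomp container.

    A first cheap pass counts reads and fixes the read length so the
    partition depth can be planned; the second pass substitutes N
    bases and either sorts in memory (depth 0) or spills to temporary
    files.  ``prefix_depth`` overrides the automatic plan.
    """
    read_count = 0
    read_length = 0
    for seq in read_sequences(input_path, fmt):
        read_count += 1
        read_length = len(seq)
    if read_count == 0:
        with open(output_path, "wb") as sink:
            report = CompressionReport()
            report.container_bytes = write_container([], 0, sink)
            return report
    if prefix_depth is None:
        plan = plan_partitions(read_count, read_length, memory_budget)
        prefix_depth = plan.prefix_depth
    with open(output_path, "wb") as sink:
        return compress_reads(
            read_sequences(input_path, fmt),
            sink,
            bucket_capacity=bucket_capacity,
            prefix_depth=prefix_depth,
            memory_budget=memory_budget,
            tmp_dir=tmp_dir,
        )
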