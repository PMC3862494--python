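"""Burst-trie lexicographic sorting of fixed-length read collections.

A burst trie is a trie whose sufficiently small subtrees are collapsed
into bounded-capacity buckets.  Reads are inserted one after another,
walked base by base until they can be dropped into a bucket; a bucket
pushed past its capacity "bursts" into a fresh trie node one level
deeper, redistributing its entries by the next base.  An in-order
traversal (A, C, G, T at every node, each bucket sorted internally)
then yields the whole collection in lexicographic order.

The bucket representation is a growable array (the faster of the two
classic variants).  The in-bucket sort is Python's stable sort keyed on
the suffix past the bucket's shared prefix, so the overall result is a
stable lexicographic sort of the input: duplicates keep their arrival
order, which makes the pipeline deterministic.

All reads must share one length L and use only {A,C,G,T}; ambiguous
bases are expected to have been substituted away beforehand (see
:mod:`srcomp.ambiguity`).  A bucket whose depth reaches L can only hold
copies of one identical read and is exempt from bursting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Iterator

from .errors import InvalidBaseError, UniformLengthError
from .readcodec import ReadBatch

__all__ = ["BurstTrie", "TrieStats", "sort_reads", "sort_strings"]

DEFAULT_BUCKET_CAPACITY = 8192

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


class _Bucket:
    __slots__ = ("entries", "depth")

    def __init__(self, depth: int) -> None:
        self.entries: list[tuple[str, Any]] = []
        self.depth = depth


class _Node:
    __slots__ = ("children", "depth")

    def __init__(self, depth: int) -> None:
        # one slot per base, each None | _Bucket | _Node
        self.children: list[Any] = [None, None, None, None]
        self.depth = depth


@dataclass
class TrieStats:
    """Structural counters: trie nodes (root included), non-empty
    buckets currently alive, and bursts performed."""

    nodes: int = 0
    buckets: int = 0
    bursts: int = 0


class BurstTrie:
    """Burst trie over fixed-length ACGT reads with payload tracking.

    Each entry is a ``(read, payload)`` pair; payloads ride along so a
    caller can sort indices (read "pointers") rather than copying any
    per-read metadata into the trie.
    """

    def __init__(self, capacity: int = DEFAULT_BUCKET_CAPACITY) -> None:
        if capacity < 2:
            raise ValueError("bucket capacity must be at least 2")
        self.capacity = capacity
        self.read_length: int | None = None
        self.root = _Node(0)
        self.stats = TrieStats(nodes=1)
        self._count = 0

    def __len__(self) -> int:
        return self._count

    def insert(self, read: str, payload: Any = None) -> None:
        """Insert one read; bursts the destination bucket if it
        overflows its capacity."""
        if self.read_length is None:
            self.read_length = len(read)
        elif len(read) != self.read_length:
            raise UniformLengthError(
                f"read length {len(read)} != batch length {self.read_length}"
            )
        if read.strip("ACGT"):
            bad = sorted(set(read) - set("ACGT"))
            raise InvalidBaseError(f"non-ACGT base(s) {bad!r} in read")
        node = self.root
        while True:
            try:
                idx = _BASE_INDEX[read[node.depth]]
            except KeyError:
                raise InvalidBaseError(
                    f"non-ACGT base {read[node.depth]!r} in read"
                ) from None
            child = node.children[idx]
            if child is None:
                child = _Bucket(node.depth + 1)
                node.children[idx] = child
                self.stats.buckets += 1
            if isinstance(child, _Bucket):
                child.entries.append((read, payload))
                self._count += 1
                if (
                    len(child.entries) > self.capacity
                    and child.depth < self.read_length
                ):
                    node.children[idx] = self._burst(child)
                return
            node = child

    def _burst(self, bucket: _Bucket) -> _Node:
        """Split an over-capacity bucket into a trie node one level
        deeper, recursing while any child bucket still overflows."""
        assert self.read_length is not None
        node = _Node(bucket.depth)
        self.stats.nodes += 1
        self.stats.bursts += 1
        self.stats.buckets -= 1
        depth = bucket.depth
        for entry in bucket.entries:
            try:
                idx = _BASE_INDEX[entry[0][depth]]
            except KeyError:
                raise InvalidBaseError(
                    f"non-ACGT base {entry[0][depth]!r} in read"
                ) from None
            child = node.children[idx]
            if child is None:
                child = _Bucket(depth + 1)
                node.children[idx] = child
                self.stats.buckets += 1
            child.entries.append(entry)
        for idx, child in enumerate(node.children):
            if (
                isinstance(child, _Bucket)
                and len(child.entries) > self.capacity
                and child.depth < self.read_length
            ):
                node.children[idx] = self._burst(child)
        return node

    def traverse_sorted(self) -> Iterator[tuple[str, Any]]:
        """Yield all entries in lexicographic read order (stable)."""
        yield from self._walk(self.root)

    def _walk(self, node: _Node) -> Iterator[tuple[str, Any]]:
        for child in node.children:
            if child is None:
                continue
            if isinstance(child, _Bucket):
                depth = child.depth
                # shared prefix of length `depth`: compare suffixes only
                yield from sorted(child.entries, key=lambda e: e[0][depth:])
            else:
                yield from self._walk(child)


def sort_strings(
    reads: list[str], capacity: int = DEFAULT_BUCKET_CAPACITY
) -> list[str]:
    """Sort a plain list of same-length ACGT strings lexicographically."""
    trie = BurstTrie(capacity)
    for r in reads:
        trie.insert(r)
    return [read for read, _ in trie.traverse_sorted()]


def sort_reads(
    batch: ReadBatch,
    capacity: int = DEFAULT_BUCKET_CAPACITY,
    stats_out: TrieStats | None = None,
) -> ReadBatch:
    """Return a new :class:`ReadBatch` in lexicographic order.

    Read strings are not copied or mutated: the trie stores references,
    and the N-substitution marks are re-ordered by the same permutation
    so each mark stays attached to its read.
    """
    trie = BurstTrie(capacity)
    for i, r in enumerate(batch.reads):
        trie.insert(r, i)
    order = [payload for _, payload in trie.traverse_sorted()]
    if stats_out is not None:
        stats_out.nodes = trie.stats.nodes
        stats_out.buckets = trie.stats.buckets
        stats_out.bursts = trie.stats.bursts
    return ReadBatch(
        reads=[batch.reads[i] for i in order],
        read_length=batch.read_length,
        n_marks=[batch.n_marks[i] for i in order],
    )
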