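"""Handling of ambiguous bases (N) so compression stays lossless.

Uncalled bases are substituted by the fixed base G before sorting, so
the sorter and codec only ever see {A,C,G,T}.  To undo the substitution
after decompression, every substituted position is tracked through the
sort and then summarised as the sequence P of 1-based ordinals of G
occurrences — counting every G left to right, read by read, across the
*sorted* collection — that were originally N.  P is strictly
increasing, so its successive differences Q (``q_1 = p_1``,
``q_j = p_j - p_{j-1}``) are all >= 1 and can be Elias-omega coded
directly, with no "+1" adjustment.

On decompression the sorted reads are reconstructed first, then the
``p``-th G is turned back into an N for every ordinal in P.

Only N is accepted as an ambiguity code; other IUPAC degeneracy codes
(R, Y, ...) are rejected rather than silently coerced, because coercion
would lose information.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

from .errors import (
    CorruptFileError,
    InvalidBaseError,
    SortednessError,
    UniformLengthError,
)
from .readcodec import ReadBatch

__all__ = [
    "substitute_read",
    "substitute_ns",
    "collect_ordinals",
    "encode_ordinals",
    "decode_ordinals",
    "restore_ns",
]

_RAW_ALPHABET = set("ACGTN")


def substitute_read(raw: str) -> tuple[str, tuple[int, ...]]:
    """Substitute N->G in one read; return (clean read, mark positions).

    Input is uppercased first (lowercase soft-masking is dropped).  Mark
    positions are 0-based indices of the substituted bases.

    >>> substitute_read("ANGN")
    ('AGGG', (1, 3))
    """
    read = raw.upper()
    bad = set(read) - _RAW_ALPHABET
    if bad:
        raise InvalidBaseError(
            f"read contains characters outside ACGTN: {sorted(bad)!r}"
        )
    if "N" not in read:
        return read, ()
    marks = tuple(i for i, c in enumerate(read) if c == "N")
    return read.replace("N", "G"), marks


def substitute_ns(raw_reads: Iterable[str]) -> ReadBatch:
    """Substitute N->G across a collection, enforcing uniform length."""
    reads: list[str] = []
    marks: list[tuple[int, ...]] = []
    length: int | None = None
    for i, raw in enumerate(raw_reads):
        clean, m = substitute_read(raw)
        if length is None:
            length = len(clean)
        elif len(clean) != length:
            raise UniformLengthError(
                f"read {i} has length {len(clean)}, expected {length}"
            )
        reads.append(clean)
        marks.append(m)
    return ReadBatch(reads, length or 0, marks)


def collect_ordinals(sorted_batch: ReadBatch) -> list[int]:
    """Walk the sorted reads and emit the G-ordinal of every mark.

    Gs are numbered 1, 2, 3, ... across the whole collection in read
    order; the output is strictly increasing.

    >>> collect_ordinals(ReadBatch(["AGGG", "GGAA"], 4, [(2, 3), ()]))
    [2, 3]
    """
    ordinals: list[int] = []
    g_count = 0
    for read, marks in zip(sorted_batch.reads, sorted_batch.n_marks):
        if not marks:
            g_count += read.count("G")
            continue
        mark_set = frozenset(marks)
        for pos, base in enumerate(read):
            if base == "G":
                g_count += 1
                if pos in mark_set:
                    ordinals.append(g_count)
            elif pos in mark_set:
                raise CorruptFileError(
                    f"substitution mark at position {pos} of read "
                    f"{read!r} does not point at a G"
                )
    return ordinals


def encode_ordinals(ordinals: Sequence[int]) -> list[int]:
    """Strictly increasing P -> difference sequence Q (all >= 1)."""
    out: list[int] = []
    prev = 0
    for j, p in enumerate(ordinals):
        if p <= prev:
            raise SortednessError(
                f"ordinals not strictly increasing at index {j}: "
                f"{prev} >= {p}"
            )
        out.append(p - prev)
        prev = p
    return out


def decode_ordinals(deltas: Sequence[int]) -> list[int]:
    """Inverse of :func:`encode_ordinals`."""
    out: list[int] = []
    acc = 0
    for j, q in enumerate(deltas):
        if q < 1:
            raise ValueError(f"delta {q} at index {j} is not positive")
        acc += q
        out.append(acc)
    return out


def restore_ns(sorted_reads: Sequence[str], ordinals: Sequence[int]) -> list[str]:
    """Turn the p-th G back into N for every ordinal p, in read order."""
    if not ordinals:
        return list(sorted_reads)
    pending = iter(ordinals)
    target = next(pending)
    out: list[str] = []
    g_count = 0
    for read in sorted_reads:
        here = read.count("G")
        if target is None or target > g_count + here:
            # no restoration lands inside this read
            g_count += here
            out.append(read)
            continue
        chars = list(read)
        for pos, base in enumerate(chars):
            if base != "G":
                continue
            g_count += 1
            if target is not None and g_count == target:
                chars[pos] = "N"
                target = next(pending, None)
        out.append("".join(chars))
    if target is not None:
        raise CorruptFileError(
            f"N-position ordinal {target} exceeds total G count {g_count}"
        )
    return out
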