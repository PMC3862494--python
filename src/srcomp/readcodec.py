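"""Reads <-> integers, and the delta+1 transform on sorted integer runs.

A fixed-length read over {A, C, G, T} is a number written in base 4 with
A=0, C=1, G=2, T=3 and the leftmost base most significant — equivalently
the 2-bit packing A=00, C=01, G=10, T=11 read as one big binary integer.
Because the digit order follows the base order, lexicographic order of
reads coincides exactly with numeric order of their integers, so a
sorted read collection maps to a non-decreasing integer sequence R.

R is then converted to a strictly positive sequence D by taking
successive differences plus one (``d_1 = r_1 + 1``,
``d_i = r_i - r_{i-1} + 1``).  The "+1" exists solely because the Elias
omega code has no codeword for zero; a run of identical reads therefore
produces deltas of exactly 1, each costing a single payload bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Sequence

from .errors import InvalidBaseError, SortednessError, UniformLengthError

__all__ = [
    "ReadBatch",
    "read_to_int",
    "int_to_read",
    "to_deltas",
    "from_deltas",
]

_BASES = "ACGT"
_TO_DIGIT = str.maketrans("ACGT", "0123")
_FROM_DIGIT = {i: b for i, b in enumerate(_BASES)}


@dataclass
class ReadBatch:
    """Same-length reads over {A,C,G,T} plus their N-substitution record.

    ``n_marks[i]`` holds the 0-based positions within ``reads[i]`` where
    the original read carried an ambiguous N (now substituted by G).
    Marks travel with their read through sorting, mirroring a pointer
    array that follows the read wherever it moves.
    """

    reads: list[str]
    read_length: int
    n_marks: list[tuple[int, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.n_marks:
            self.n_marks = [()] * len(self.reads)
        if len(self.n_marks) != len(self.reads):
            raise ValueError("n_marks must parallel reads")

    def __len__(self) -> int:
        return len(self.reads)

    @property
    def n_count(self) -> int:
        return sum(len(m) for m in self.n_marks)


def read_to_int(read: str) -> int:
    """Map a read over {A,C,G,T} to its 2-bit packed integer.

    >>> read_to_int("AAAA")
    0
    >>> read_to_int("CGCA")
    100
    """
    digits = read.translate(_TO_DIGIT)
    try:
        return int(digits, 4) if digits else 0
    except ValueError:
        bad = sorted(set(read) - set(_BASES))
        raise InvalidBaseError(
            f"read contains non-ACGT character(s): {bad!r}"
        ) from None


def int_to_read(value: int, read_length: int) -> str:
    """Inverse of :func:`read_to_int`; left-pads with A (digit 0)."""
    if read_length < 0:
        raise ValueError("read_length must be non-negative")
    if value < 0 or value >= 4**read_length:
        raise ValueError(
            f"value {value} out of range for read length {read_length}"
        )
    out = []
    for _ in range(read_length):
        value, digit = divmod(value, 4)
        out.append(_FROM_DIGIT[digit])
    return "".join(reversed(out))


def to_deltas(sorted_values: Sequence[int]) -> list[int]:
    """Convert a non-decreasing sequence R to the positive sequence D.

    ``d_1 = r_1 + 1`` and ``d_i = r_i - r_{i-1} + 1`` for ``i >= 2``,
    so every element is >= 1 and encodable by the omega code.

    >>> to_deltas([0, 5, 5, 9])
    [1, 6, 1, 5]
    """
    deltas: list[int] = []
    prev = 0  # virtual r_0 = 0 makes d_1 = r_1 + 1 fall out of the formula
    for i, r in enumerate(sorted_values):
        if i and r < prev:
            raise SortednessError(
                f"input not non-decreasing at index {i}: {prev} > {r}"
            )
        if r < 0:
            raise ValueError(f"negative value {r} at index {i}")
        deltas.append(r - prev + 1)
        prev = r
    return deltas


def from_deltas(deltas: Sequence[int]) -> list[int]:
    """Recover the non-decreasing sequence R from its delta sequence D.

    >>> from_deltas([1, 6, 1, 5])
    [0, 5, 5, 9]
    """
    values: list[int] = []
    acc = 0
    for i, d in enumerate(deltas):
        if d < 1:
            raise ValueError(f"delta {d} at index {i} is not positive")
        acc += d - 1
        values.append(acc)
    return values


def batch_from_raw(reads: list[str]) -> ReadBatch:
    """Build a batch from already-substituted ACGT reads, validating
    uniform length and alphabet."""
    if not reads:
        return ReadBatch([], 0)
    length = len(reads[0])
    allowed = set(_BASES)
    for i, r in enumerate(reads):
        if len(r) != length:
            raise UniformLengthError(
                f"read {i} has length {len(r)}, expected {length}"
            )
        if set(r) - allowed:
            raise InvalidBaseError(f"read {i} contains non-ACGT characters")
    return ReadBatch(list(reads), length)
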