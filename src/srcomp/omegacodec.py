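"""Elias omega coding of positive integers over a bit stream.

The Elias omega code is a universal, self-delimiting prefix code: every
codeword ends in a ``0`` terminator bit, small integers get very short
codewords (the integer 1 is a single bit), and no length field or padding
is needed between codewords.  Encoding is recursive: starting from the
terminator bit, the binary representation of the current value is
prefixed to the stream and the recursion continues on the bit length
minus one of that value, until the value reaches 1.

Decoding mirrors the recursion: read one bit; if it is 0 the running
value (initially 1) is the answer, otherwise that bit is the leading
``1`` of a group whose remaining ``value`` bits are read to form the
next, larger running value.

The code is defined for integers ``n >= 1`` only — there is no omega
codeword for zero, which is why the surrounding pipeline applies a
"+1" delta transform before encoding (see :mod:`srcomp.readcodec`).

Integers of arbitrary size are supported: a read of length ``L`` packs
into an integer up to ``4**L - 1``, so codewords routinely span hundreds
of bits for typical read lengths.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

from .errors import TruncationError

__all__ = [
    "BitStream",
    "omega_encode",
    "omega_decode",
    "omega_length",
    "encode_sequence",
    "decode_sequence",
]


class BitStream:
    """An append-only / cursor-readable ordered sequence of bits.

    Bits are most-significant-first: the first bit appended is the first
    bit read back, and when packed to bytes it occupies the highest bit
    of the first byte.  Padding to a byte boundary (zero bits) happens
    only in :meth:`to_bytes`; the in-memory stream is never padded, so
    codewords are always contiguous.
    """

    __slots__ = ("_chunks", "_bits", "_nbits", "_cursor")

    def __init__(self, bits: str = "") -> None:
        if bits and set(bits) - {"0", "1"}:
            raise ValueError("bit string may contain only '0' and '1'")
        self._chunks: list[str] = []
        self._bits: str = bits
        self._nbits: int = len(bits)
        self._cursor: int = 0

    # -- construction ----------------------------------------------------

    @classmethod
    def from_bytes(cls, data: bytes, nbits: int) -> "BitStream":
        """Rebuild a stream from packed bytes and its exact bit count."""
        if nbits < 0 or nbits > 8 * len(data):
            raise ValueError("nbits inconsistent with byte payload")
        if not data:
            return cls()
        # Sentinel byte keeps leading zero bits when round-tripping
        # through an integer.
        as_int = int.from_bytes(b"\x01" + data, "big")
        bits = format(as_int, "b")[1:]
        return cls(bits[:nbits])

    # -- writing ---------------------------------------------------------

    def append(self, bits: str) -> None:
        """Append a codeword (string of '0'/'1') to the end of the stream."""
        self._chunks.append(bits)
        self._nbits += len(bits)

    def _consolidate(self) -> None:
        if self._chunks:
            self._bits += "".join(self._chunks)
            self._chunks.clear()

    # -- reading ---------------------------------------------------------

    @property
    def read_cursor(self) -> int:
        return self._cursor

    @property
    def remaining(self) -> int:
        return self._nbits - self._cursor

    def read_bit(self) -> int:
        if self._cursor >= self._nbits:
            raise TruncationError("read past end of bit stream")
        self._consolidate()
        bit = self._bits[self._cursor]
        self._cursor += 1
        return 1 if bit == "1" else 0

    def read_bits(self, k: int) -> int:
        """Read ``k`` bits and return them as an integer, MSB first."""
        if k < 0:
            raise ValueError("cannot read a negative number of bits")
        if self._cursor + k > self._nbits:
            raise TruncationError(
                f"stream exhausted: wanted {k} bits, "
                f"{self._nbits - self._cursor} remain"
            )
        self._consolidate()
        if k == 0:
            return 0
        chunk = self._bits[self._cursor : self._cursor + k]
        self._cursor += k
        return int(chunk, 2)

    def seek(self, position: int = 0) -> None:
        if not 0 <= position <= self._nbits:
            raise ValueError("cursor out of range")
        self._cursor = position

    # -- serialization ---------------------------------------------------

    def to_bytes(self) -> bytes:
        """Pack to bytes, zero-padding the final partial byte."""
        self._consolidate()
        if not self._nbits:
            return b""
        pad = -self._nbits % 8
        padded = self._bits + "0" * pad
        nbytes = len(padded) // 8
        return int("1" + padded, 2).to_bytes(nbytes + 1, "big")[1:]

    # -- dunder ----------------------------------------------------------

    def __len__(self) -> int:
        return self._nbits

    def __str__(self) -> str:
        self._consolidate()
        return self._bits

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"BitStream({str(self)!r}, cursor={self._cursor})"


def omega_encode(n: int) -> str:
    """Return the Elias omega codeword for ``n >= 1`` as a '0'/'1' string.

    The recursion: start from the terminator ``"0"``; while the value
    exceeds 1, prefix its binary representation and replace the value by
    its bit length minus one (i.e. ``floor(log2(value))``).

    >>> omega_encode(1)
    '0'
    >>> omega_encode(17)
    '10100100010'
    """
    if not isinstance(n, int) or isinstance(n, bool):
        raise TypeError(f"expected an int, got {type(n).__name__}")
    if n < 1:
        raise ValueError(f"no Elias omega code exists for {n} (need n >= 1)")
    parts = ["0"]
    while n > 1:
        b = format(n, "b")
        parts.append(b)
        n = len(b) - 1
    return "".join(reversed(parts))


def omega_length(n: int) -> int:
    """Bit length of the omega codeword for ``n`` without building it."""
    if n < 1:
        raise ValueError(f"no Elias omega code exists for {n} (need n >= 1)")
    total = 1
    while n > 1:
        b = n.bit_length()
        total += b
        n = b - 1
    return total


def omega_decode(stream: BitStream) -> int:
    """Decode one codeword at the stream cursor; advance past it.

    Raises :class:`TruncationError` if the stream ends mid-codeword.
    """
    n = 1
    while stream.read_bit():
        if n > stream.remaining:
            raise TruncationError(
                f"codeword group needs {n} bits but only "
                f"{stream.remaining} remain"
            )
        n = (1 << n) | stream.read_bits(n)
    return n


def encode_sequence(values: Iterable[int]) -> BitStream:
    """Concatenate the codewords of ``values`` into one unpadded stream."""
    stream = BitStream()
    for v in values:
        stream.append(omega_encode(v))
    return stream


def decode_sequence(stream: BitStream, count: int) -> list[int]:
    """Decode exactly ``count`` codewords from the cursor onward."""
    if count < 0:
        raise ValueError("count must be non-negative")
    return [omega_decode(stream) for _ in range(count)]
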