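"""The .srcomp on-disk container: header plus independent blocks.

Layout (all integers little-endian, fixed width; see docs/format.md):

========  =====  ==================================================
offset    width  field
========  =====  ==================================================
0         4      magic ``b"SRCP"``
4         2      format version (currently 1)
6         4      read length L (bases)
10        8      total read count n
18        4      block count B
========  =====  ==================================================

followed by B block records, each::

    read_count   u64   codewords in the read stream
    n_count      u64   codewords in the N-position stream
    read_bits    u64   exact bit length of the read stream
    n_bits       u64   exact bit length of the N-position stream
    read_stream  ceil(read_bits / 8) bytes, zero-padded
    n_stream     ceil(n_bits / 8) bytes, zero-padded

Each block is self-contained: its read stream encodes the delta+1
sequence D of that block's sorted reads (the first read is encoded as
its integer value plus one), and its N stream encodes the difference
sequence Q of G-ordinals counted locally within the block.  Blocks are
stored in ascending order of their partition prefix, so concatenating
decoded blocks yields a globally sorted collection.

Counts live outside the bitstreams because an omega-coded stream is
self-delimiting per codeword but not per sequence — the decoder must be
told how many codewords to read, and never relies on padding.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from typing import BinaryIO, Iterator

from . import ambiguity
from .errors import CorruptFileError, NotSRCompFileError, VersionError
from .omegacodec import BitStream, decode_sequence, encode_sequence
from .readcodec import ReadBatch, from_deltas, int_to_read, read_to_int, to_deltas

__all__ = [
    "MAGIC",
    "FORMAT_VERSION",
    "BlockRecord",
    "CompressedContainer",
    "encode_block",
    "decode_block",
    "write_container",
    "read_container",
    "iter_container_reads",
]

MAGIC = b"SRCP"
FORMAT_VERSION = 1

_HEADER = struct.Struct("<4sHIQI")
_BLOCK_HEADER = struct.Struct("<QQQQ")


@dataclass
class BlockRecord:
    """One independently decodable unit of the container."""

    read_count: int
    n_count: int
    read_bits: int
    n_bits: int
    read_stream: bytes
    n_stream: bytes

    @property
    def payload_bytes(self) -> int:
        return len(self.read_stream) + len(self.n_stream)


@dataclass
class CompressedContainer:
    read_length: int
    total_read_count: int
    blocks: list[BlockRecord]

    @property
    def block_count(self) -> int:
        return len(self.blocks)

    @property
    def n_count(self) -> int:
        return sum(b.n_count for b in self.blocks)

    @property
    def payload_bytes(self) -> int:
        return sum(b.payload_bytes for b in self.blocks)

    def bits_per_base(self) -> float | None:
        """Payload bits divided by total bases; None for an empty file."""
        bases = self.total_read_count * self.read_length
        if not bases:
            return None
        return 8.0 * self.payload_bytes / bases


def encode_block(sorted_batch: ReadBatch) -> BlockRecord:
    """Encode one sorted (N-substituted, marked) batch into a block."""
    values = [read_to_int(r) for r in sorted_batch.reads]
    deltas = to_deltas(values)
    read_stream = encode_sequence(deltas)
    ordinals = ambiguity.collect_ordinals(sorted_batch)
    n_stream = encode_sequence(ambiguity.encode_ordinals(ordinals))
    return BlockRecord(
        read_count=len(values),
        n_count=len(ordinals),
        read_bits=len(read_stream),
        n_bits=len(n_stream),
        read_stream=read_stream.to_bytes(),
        n_stream=n_stream.to_bytes(),
    )


def decode_block(block: BlockRecord, read_length: int) -> list[str]:
    """Decode a block back to its sorted reads with Ns restored."""
    stream = BitStream.from_bytes(block.read_stream, block.read_bits)
    deltas = decode_sequence(stream, block.read_count)
    if stream.remaining:
        raise CorruptFileError(
            f"{stream.remaining} unread bits after the last read codeword"
        )
    reads = [int_to_read(v, read_length) for v in from_deltas(deltas)]
    n_stream = BitStream.from_bytes(block.n_stream, block.n_bits)
    q = decode_sequence(n_stream, block.n_count)
    if n_stream.remaining:
        raise CorruptFileError(
            f"{n_stream.remaining} unread bits after the last N codeword"
        )
    ordinals = ambiguity.decode_ordinals(q)
    return ambiguity.restore_ns(reads, ordinals)


def write_container(
    blocks: list[BlockRecord], read_length: int, sink: BinaryIO
) -> int:
    """Write header + blocks; returns the byte count written.

    The layout is deterministic: identical blocks yield identical bytes.
    """
    total = sum(b.read_count for b in blocks)
    written = sink.write(
        _HEADER.pack(MAGIC, FORMAT_VERSION, read_length, total, len(blocks))
    )
    for b in blocks:
        written += sink.write(
            _BLOCK_HEADER.pack(b.read_count, b.n_count, b.read_bits, b.n_bits)
        )
        written += sink.write(b.read_stream)
        written += sink.write(b.n_stream)
    return written


def _read_exact(source: BinaryIO, n: int, what: str) -> bytes:
    data = source.read(n)
    if len(data) != n:
        raise CorruptFileError(
            f"truncated file: expected {n} bytes for {what}, got {len(data)}"
        )
    return data


def _check_padding(data: bytes, nbits: int, what: str) -> None:
    pad = 8 * len(data) - nbits
    if pad and data and data[-1] & ((1 << pad) - 1):
        raise CorruptFileError(f"nonzero padding bits in {what}")


def read_container(source: BinaryIO) -> CompressedContainer:
    """Parse and structurally validate a container from a byte stream."""
    header = _read_exact(source, _HEADER.size, "header")
    magic, version, read_length, total, block_count = _HEADER.unpack(header)
    if magic != MAGIC:
        raise NotSRCompFileError(
            f"bad magic {magic!r}: not an srcomp container"
        )
    if version != FORMAT_VERSION:
        raise VersionError(f"unsupported format version {version}")
    blocks: list[BlockRecord] = []
    for i in range(block_count):
        bh = _read_exact(source, _BLOCK_HEADER.size, f"block {i} header")
        read_count, n_count, read_bits, n_bits = _BLOCK_HEADER.unpack(bh)
        read_bytes = _read_exact(source, (read_bits + 7) // 8, f"block {i} reads")
        n_bytes = _read_exact(source, (n_bits + 7) // 8, f"block {i} N stream")
        _check_padding(read_bytes, read_bits, f"block {i} read stream")
        _check_padding(n_bytes, n_bits, f"block {i} N stream")
        if read_count and not read_bits:
            raise CorruptFileError(f"block {i}: reads declared but no bits")
        if n_count and not n_bits:
            raise CorruptFileError(f"block {i}: Ns declared but no bits")
        blocks.append(
            BlockRecord(read_count, n_count, read_bits, n_bits, read_bytes, n_bytes)
        )
    trailing = source.read(1)
    if trailing:
        raise CorruptFileError("trailing bytes after the last block")
    if sum(b.read_count for b in blocks) != total:
        raise CorruptFileError(
            "block read counts do not sum to the header total"
        )
    return CompressedContainer(read_length, total, blocks)


def iter_container_reads(container: CompressedContainer) -> Iterator[str]:
    """Yield every read, block by block, in stored (sorted) order."""
    for block in container.blocks:
        yield from decode_block(block, container.read_length)
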