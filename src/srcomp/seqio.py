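"""Read-sequence I/O and the synthetic read-set generator.

Readers yield sequence strings only: FASTQ quality lines, read names
and FASTA headers are discarded, because the compressor stores the read
multiset alone.  All reads in a file must share one length; the first
read fixes it and any deviation is an error.  ``.gz`` inputs are
decompressed transparently.

The generator emulates the redundancy structure of deep shotgun
sequencing: in coverage mode, reads are windows drawn uniformly from a
single random backing sequence, so deeper coverage yields more
duplicate and heavily clustered reads — the property the downstream
delta coding exploits.  It does not emulate sequencing errors, base
quality, strand or paired-end structure.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
from Bio import SeqIO

from .errors import ParseError, UniformLengthError

__all__ = [
    "SyntheticSpec",
    "detect_format",
    "read_sequences",
    "write_sequences",
    "generate_reads",
]

FORMATS = ("fastq", "fasta", "lines")

_EXT_MAP = {
    ".fastq": "fastq",
    ".fq": "fastq",
    ".fasta": "fasta",
    ".fa": "fasta",
    ".fna": "fasta",
    ".txt": "lines",
    ".reads": "lines",
    ".lines": "lines",
}


def detect_format(path: str | Path) -> str:
    """Guess the format from the file extension; default to ``lines``."""
    suffixes = Path(path).suffixes
    if suffixes and suffixes[-1] == ".gz":
        suffixes = suffixes[:-1]
    if suffixes:
        return _EXT_MAP.get(suffixes[-1].lower(), "lines")
    return "lines"


def _open_text(path: str | Path) -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _check_length(seq: str, expected: int | None, where: str) -> int:
    if expected is None:
        return len(seq)
    if len(seq) != expected:
        raise UniformLengthError(
            f"{where}: read length {len(seq)} differs from the "
            f"established length {expected}; variable-length reads are "
            "not supported"
        )
    return expected


def read_sequences(path: str | Path, fmt: str | None = None) -> Iterator[str]:
    """Yield raw read strings from a FASTQ, FASTA or line-per-read file."""
    fmt = fmt or detect_format(path)
    if fmt not in FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {FORMATS}")
    length: int | None = None
    with _open_text(path) as handle:
        if fmt == "lines":
            for lineno, line in enumerate(handle, start=1):
                seq = line.strip()
                if not seq:
                    continue  # tolerate blank (e.g. trailing) lines
                length = _check_length(seq, length, f"{path}:{lineno}")
                yield seq
        else:
            try:
                for record in SeqIO.parse(handle, fmt):
                    seq = str(record.seq)
                    length = _check_length(
                        seq, length, f"{path} record {record.id!r}"
                    )
                    yield seq
            except UniformLengthError:
                raise
            except ValueError as exc:  # malformed record
                raise ParseError(f"{path}: {exc}") from exc


def write_sequences(
    reads: Iterable[str], path: str | Path, fmt: str = "lines"
) -> int:
    """Write reads to ``lines`` or ``fasta`` output; returns the count.

    Original read names are not stored in the container, so FASTA mode
    invents sequential headers ``read_1``, ``read_2``, ...
    """
    if fmt not in ("lines", "fasta"):
        raise ValueError(f"unsupported output format {fmt!r}")
    count = 0
    with open(path, "wt") as handle:
        for seq in reads:
            count += 1
            if fmt == "fasta":
                handle.write(f">read_{count}\n{seq}\n")
            else:
                handle.write(f"{seq}\n")
    return count


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic read set.

    read_length
        L, bases per read (default 36, a common short-read length).
    read_count
        Number of reads to generate.
    n_rate
        Per-base probability of an uncalled base N (default 0).
    duplication_rate
        Probability that a read is an exact copy of an earlier read,
        emulating PCR and enzyme-bias duplicates (default 0).
    genome_length
        If set, reads are windows of one random backing sequence of
        this length (coverage-style sampling); otherwise reads are
        uniform random, which carries essentially no redundancy.
    seed
        RNG seed; generation is fully reproducible from it.
    """

    read_length: int = 36
    read_count: int = 10_000
    n_rate: float = 0.0
    duplication_rate: float = 0.0
    genome_length: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError("read_length must be positive")
        if self.read_count < 0:
            raise ValueError("read_count must be non-negative")
        if not 0.0 <= self.n_rate <= 1.0:
            raise ValueError("n_rate must lie in [0, 1]")
        if not 0.0 <= self.duplication_rate <= 1.0:
            raise ValueError("duplication_rate must lie in [0, 1]")
        if self.genome_length is not None and self.genome_length < self.read_length:
            raise ValueError(
                "genome_length must be at least read_length in coverage mode"
            )


_LETTERS = np.frombuffer(b"ACGT", dtype=np.uint8)


def generate_reads(spec: SyntheticSpec) -> list[str]:
    """Generate a deterministic synthetic read set per ``spec``."""
    rng = np.random.default_rng(spec.seed)
    n, length = spec.read_count, spec.read_length
    if n == 0:
        return []
    genome = None
    if spec.genome_length is not None:
        genome = _LETTERS[rng.integers(0, 4, spec.genome_length)]
    reads: list[str] = []
    for i in range(n):
        if i and rng.random() < spec.duplication_rate:
            reads.append(reads[int(rng.integers(0, i))])
        elif genome is not None:
            start = int(rng.integers(0, spec.genome_length - length + 1))
            reads.append(genome[start : start + length].tobytes().decode())
        else:
            reads.append(_LETTERS[rng.integers(0, 4, length)].tobytes().decode())
    if spec.n_rate > 0.0:
        mask = rng.random((n, length)) < spec.n_rate
        hit_rows = np.flatnonzero(mask.any(axis=1))
        for row in hit_rows:
            chars = bytearray(reads[row], "ascii")
            for pos in np.flatnonzero(mask[row]):
                chars[pos] = ord("N")
            reads[row] = chars.decode()
    return reads
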