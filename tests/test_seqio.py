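"""I/O format handling and synthetic generator statistics."""

import gzip
import math

import pytest

from srcomp.errors import ParseError, UniformLengthError
from srcomp.seqio import (
    SyntheticSpec,
    detect_format,
    generate_reads,
    read_sequences,
    write_sequences,
)

FASTQ = (
    "@r1 some description\nACGTACGT\n+\nIIIIIIII\n"
    "@r2\nTTTTAAAA\n+\n########\n"
)
FASTA_WRAPPED = ">chr1 fragment\nACGT\nACGT\n>chr2\nTTTT\nAAAA\n"


def test_detect_format_by_extension():
    assert detect_format("x.fastq") == "fastq"
    assert detect_format("x.fq.gz") == "fastq"
    assert detect_format("x.fa") == "fasta"
    assert detect_format("x.reads") == "lines"
    assert detect_format("x.unknownext") == "lines"


def test_fastq_reader_yields_sequences_only(tmp_path):
    path = tmp_path / "reads.fastq"
    path.write_text(FASTQ)
    assert list(read_sequences(path)) == ["ACGTACGT", "TTTTAAAA"]


def test_fasta_reader_concatenates_wrapped_lines(tmp_path):
    path = tmp_path / "reads.fasta"
    path.write_text(FASTA_WRAPPED)
    assert list(read_sequences(path)) == ["ACGTACGT", "TTTTAAAA"]


def test_lines_reader_ignores_blank_lines(tmp_path):
    path = tmp_path / "reads.txt"
    path.write_text("ACGT\nTTTT\n\n")
    assert list(read_sequences(path)) == ["ACGT", "TTTT"]


def test_gzip_input_is_transparent(tmp_path):
    path = tmp_path / "reads.txt.gz"
    with gzip.open(path, "wt") as handle:
        handle.write("ACGT\nCCCC\n")
    assert list(read_sequences(path)) == ["ACGT", "CCCC"]


def test_uniform_length_enforced_with_location(tmp_path):
    path = tmp_path / "reads.fasta"
    path.write_text(">a\nACGT\n>bad_record\nACGTT\n")
    with pytest.raises(UniformLengthError, match="bad_record"):
        list(read_sequences(path))


def test_malformed_fastq_raises_parse_error(tmp_path):
    path = tmp_path / "reads.fastq"
    path.write_text("@r1\nACGT\nBROKEN\nIIII\n")
    with pytest.raises(ParseError):
        list(read_sequences(path))


def test_unknown_format_rejected(tmp_path):
    with pytest.raises(ValueError):
        list(read_sequences(tmp_path / "x.txt", fmt="bam"))


def test_write_lines_and_fasta_round_trip(tmp_path):
    reads = ["ACGT", "ANNT", "TTTT"]
    lines_path = tmp_path / "out.txt"
    assert write_sequences(reads, lines_path) == 3
    assert list(read_sequences(lines_path)) == reads
    fasta_path = tmp_path / "out.fasta"
    assert write_sequences(reads, fasta_path, fmt="fasta") == 3
    text = fasta_path.read_text()
    assert text.startswith(">read_1\n")
    assert list(read_sequences(fasta_path)) == reads


def test_write_empty_input(tmp_path):
    path = tmp_path / "empty.txt"
    assert write_sequences([], path) == 0
    assert path.read_text() == ""


def test_generator_deterministic_per_seed():
    spec = SyntheticSpec(read_count=500, n_rate=0.01, duplication_rate=0.2,
                         genome_length=5000, seed=42)
    assert generate_reads(spec) == generate_reads(spec)
    other = SyntheticSpec(read_count=500, n_rate=0.01, duplication_rate=0.2,
                          genome_length=5000, seed=43)
    assert generate_reads(other) != generate_reads(spec)


def test_generator_empty_and_validation():
    assert generate_reads(SyntheticSpec(read_count=0)) == []
    with pytest.raises(ValueError):
        SyntheticSpec(read_length=50, genome_length=49)
    with pytest.raises(ValueError):
        SyntheticSpec(n_rate=1.5)
    with pytest.raises(ValueError):
        SyntheticSpec(duplication_rate=-0.1)


def test_generator_n_rate_statistics():
    """N count is Binomial(n*L, rate); check within 5 standard
    deviations of the mean."""
    n, length, rate = 20_000, 36, 0.01
    reads = generate_reads(
        SyntheticSpec(read_length=length, read_count=n, n_rate=rate, seed=9)
    )
    total = n * length
    observed = sum(r.count("N") for r in reads)
    sd = math.sqrt(total * rate * (1 - rate))
    assert abs(observed - total * rate) < 5 * sd


def test_generator_duplication_produces_repeats():
    reads = generate_reads(
        SyntheticSpec(read_length=30, read_count=5000,
                      duplication_rate=0.5, seed=4)
    )
    distinct = len(set(reads))
    # ~half the reads are copies; allow a generous band
    assert 0.35 * len(reads) < distinct < 0.65 * len(reads)


def test_generator_coverage_mode_reuses_genome_windows():
    spec = SyntheticSpec(read_length=20, read_count=3000,
                         genome_length=500, seed=8)
    reads = generate_reads(spec)
    # only ~481 distinct windows exist, so heavy duplication is forced
    assert len(set(reads)) <= 481
    assert all(len(r) == 20 for r in reads)
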