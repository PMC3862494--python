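import random

import pytest

BASES = "ACGT"

# The ten-read collection from the worked burst-trie illustration:
# with bucket capacity 3 it builds exactly 3 trie nodes and 5 buckets.
FIG1_READS = [
    "CGCA", "CAAG", "TGCT", "CGTG", "CGTT",
    "GACG", "CACT", "TGCT", "CAAT", "CGTG",
]


@pytest.fixture
def fig1_reads() -> list[str]:
    return list(FIG1_READS)


def make_reads(
    rng: random.Random,
    count: int,
    length: int,
    duplication_rate: float = 0.0,
    alphabet: str = BASES,
) -> list[str]:
    """Plain random read generator independent of the package's own
    synthetic module, for use as a neutral test input source."""
    reads: list[str] = []
    for i in range(count):
        if i and rng.random() < duplication_rate:
            reads.append(rng.choice(reads))
        else:
            reads.append("".join(rng.choice(alphabet) for _ in range(length)))
    return reads


@pytest.fixture
def rng() -> random.Random:
    return random.Random(0xC0FFEE)
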