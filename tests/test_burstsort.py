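"""Burst-trie sorting tests: worked structure, oracle equivalence,
stability, and structural invariants."""

import pytest

from srcomp.burstsort import BurstTrie, TrieStats, _Bucket, _Node, sort_reads, sort_strings
from srcomp.errors import InvalidBaseError, UniformLengthError
from srcomp.readcodec import ReadBatch
from .conftest import make_reads


def test_single_insert_creates_one_bucket():
    trie = BurstTrie(capacity=3)
    trie.insert("ACGT")
    assert trie.stats.nodes == 1  # just the root
    assert trie.stats.buckets == 1
    assert list(trie.traverse_sorted()) == [("ACGT", None)]


def test_ten_read_example_builds_three_nodes_and_five_buckets(fig1_reads):
    trie = BurstTrie(capacity=3)
    for r in fig1_reads:
        trie.insert(r)
    assert trie.stats.nodes == 3
    assert trie.stats.buckets == 5
    assert [r for r, _ in trie.traverse_sorted()] == sorted(fig1_reads)


def test_burst_redistributes_by_next_base():
    """A full depth-1 C bucket splits into per-second-base buckets."""
    trie = BurstTrie(capacity=3)
    for r in ["CGCA", "CAAG", "CGTG", "CGTT"]:
        trie.insert(r)
    assert trie.stats.bursts == 1
    assert trie.stats.nodes == 2
    c_node = trie.root.children[1]
    assert isinstance(c_node, _Node)
    a_bucket, _, g_bucket, _ = c_node.children
    assert sorted(e[0] for e in a_bucket.entries) == ["CAAG"]
    assert sorted(e[0] for e in g_bucket.entries) == ["CGCA", "CGTG", "CGTT"]


def test_identical_reads_burst_recursively_until_exhaustion():
    """Copies of one read share every base, so bursting cascades to
    depth L, where the bucket becomes exempt and may grow freely."""
    trie = BurstTrie(capacity=3)
    for _ in range(6):
        trie.insert("GGGG")
    assert trie.stats.bursts == 3  # buckets at depths 1, 2 and 3 burst
    assert trie.stats.nodes == 4  # root plus one node per burst
    assert trie.stats.buckets == 1  # the depth-L bucket is exempt
    assert [r for r, _ in trie.traverse_sorted()] == ["GGGG"] * 6


def _walk_buckets(node):
    for child in node.children:
        if isinstance(child, _Bucket):
            yield child
        elif isinstance(child, _Node):
            yield from _walk_buckets(child)


def test_bucket_bound_and_prefix_invariant(rng):
    reads = make_reads(rng, 3000, 10, duplication_rate=0.4)
    trie = BurstTrie(capacity=16)
    for r in reads:
        trie.insert(r)
    nonempty = 0
    for bucket in _walk_buckets(trie.root):
        nonempty += 1
        assert bucket.entries
        assert len(bucket.entries) <= 16 or bucket.depth == 10
        prefixes = {e[0][: bucket.depth] for e in bucket.entries}
        assert len(prefixes) == 1
    assert nonempty == trie.stats.buckets


@pytest.mark.parametrize("capacity", [2, 3, 64, 8192])
def test_traversal_equals_oracle_sort(rng, capacity):
    reads = make_reads(rng, 5000, 14, duplication_rate=0.5)
    assert sort_strings(reads, capacity) == sorted(reads)


def test_duplicates_preserved_as_multiset(rng):
    reads = make_reads(rng, 2000, 6, duplication_rate=0.7)
    result = sort_strings(reads, 8)
    assert sorted(result) == result
    assert sorted(reads) == result  # multiset equality via total order


def test_sort_is_stable_for_equal_reads():
    batch = ReadBatch(["TTAA", "AAAA", "TTAA", "AAAA"], 4)
    out = sort_reads(batch, capacity=2)
    trie = BurstTrie(capacity=2)
    for i, r in enumerate(batch.reads):
        trie.insert(r, i)
    payloads = [p for r, p in trie.traverse_sorted() if r == "AAAA"]
    assert payloads == sorted(payloads)
    assert out.reads == ["AAAA", "AAAA", "TTAA", "TTAA"]


def test_sort_reads_carries_marks_with_their_read():
    batch = ReadBatch(
        ["TGGG", "AGGG"], 4, n_marks=[(0,), (1, 2)]
    )
    out = sort_reads(batch, capacity=8)
    assert out.reads == ["AGGG", "TGGG"]
    assert out.n_marks == [(1, 2), (0,)]


def test_insert_rejects_bad_input():
    trie = BurstTrie(capacity=4)
    trie.insert("ACGT")
    with pytest.raises(UniformLengthError):
        trie.insert("ACG")
    with pytest.raises(InvalidBaseError):
        trie.insert("ACGN")
    with pytest.raises(ValueError):
        BurstTrie(capacity=1)


def test_empty_trie_traversal():
    assert list(BurstTrie().traverse_sorted()) == []
    assert sort_strings([], 8) == []


def test_stats_out_reports_structure(fig1_reads):
    stats = TrieStats()
    batch = ReadBatch(list(fig1_reads), 4)
    out = sort_reads(batch, capacity=3, stats_out=stats)
    assert (stats.nodes, stats.buckets) == (3, 5)
    assert out.reads == sorted(fig1_reads)
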