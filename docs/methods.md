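# Methods

## Model and assumptions

`srcomp` compresses a collection of DNA short reads under three
assumptions:

1. **Fixed read length.** Every read has the same length `L`. This is
   what makes the read ↔ integer bijection well-defined; variable-length
   reads are rejected, not truncated or padded.
2. **Order is disposable.** The collection is a multiset: decompression
   returns every read exactly (including `N` positions) but in
   lexicographic order, and read names / qualities are not stored at
   all. Pipelines that need pairing or provenance must keep it
   elsewhere.
3. **Constrained read space.** Compression wins come from redundancy:
   when many reads are sampled from a genome that is small relative to
   the read count (deep coverage, PCR duplicates, repeats), sorted
   adjacent reads are close in the 4ᴸ integer space and their deltas
   are small. On reads that are effectively uniform over the 4ᴸ space
   the method degrades toward ~(2·L + O(log L))/L bits per base — the
   cost of omega-coding near-maximal deltas — and a duplicated read
   always costs exactly 1 bit.

The pipeline is: substitute `N→G` (tracking positions) → sort with a
burst trie → pack reads to integers → delta(+1) transform → Elias
omega coding → block container. Each stage is exactly invertible given
the counts stored in the container.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `bucket_capacity` | 8192 entries | burst-trie bucket size before bursting; 8192 suits large collections, smaller values only increase trie overhead |
| `memory_limit` | 1 GiB | approximate raw read payload sorted in memory at once |
| fill factor | 0.5 | fraction of `memory_limit` the planner targets per partition, leaving headroom for trie structures and Python object overhead |
| `prefix_depth` | planned | partition-key length `k`; the smallest `k` with `n·L/4^k ≤ memory_limit · fill_factor`, capped at `L` |

The delta convention is `d₁ = r₁ + 1` and `dᵢ = rᵢ − rᵢ₋₁ + 1`. Adding
one everywhere (not just to ties) keeps every delta strictly positive —
the omega code has no codeword for zero — and makes the transform
invertible without storing `r₁` out of band; the all-`A` read (`r = 0`)
still maps to the 1-bit codeword. The N-ordinal differences
`q₁ = p₁, qⱼ = pⱼ − pⱼ₋₁` need **no** `+1` because the ordinal sequence
is strictly increasing by construction.

`N` is always substituted by the *fixed* base `G`, so the decompressor
knows deterministically which base to convert back. Other IUPAC
degeneracy codes are rejected: silently coercing `R` or `Y` to a
concrete base would make the tool lossy in a way the ordinal mechanism
cannot undo. Lowercase input is uppercased on read-in (soft-masking is
not preserved).

## Design choices that were genuinely open

* **Burst trigger.** A bucket bursts when an insert pushes it *past*
  capacity (insert → check → burst), so a bucket holding exactly
  `capacity` entries persists. With capacity 3, the canonical ten-read
  example builds exactly 3 trie nodes and 5 non-empty buckets, which
  the test suite pins down.
* **Exhausted buckets.** A bucket at depth `L` holds only copies of one
  read (no distinguishing base remains) and is exempt from bursting
  regardless of size.
* **Stable in-bucket sort.** Buckets are sorted with a stable
  comparison keyed on the suffix past the shared prefix. Stability
  makes the whole sort stable, hence compression byte-deterministic.
* **Dynamic-array buckets.** Only the growable-array bucket variant is
  implemented; the linked-list variant has no advantage in Python and
  would double the surface to test.
* **Block-local baselines.** Every partition block restarts delta
  coding at an implicit `r₀ = 0` and numbers its N-ordinals locally.
  This is the only choice that keeps blocks independently decodable
  (and trivially parallelizable); the cost is one full-width first
  codeword per block, negligible beyond a handful of blocks.
* **Counts outside the bitstreams.** Omega codewords are
  self-delimiting but a *sequence* of them is not; the container stores
  fixed-width read/N counts and exact bit lengths per block, and the
  decoder never infers anything from padding.
* **Partition keying after substitution.** Spill files are keyed on
  post-substitution bases, so a read starting with `N` lands in the `G`
  partition and the concatenated blocks stay globally sorted in the
  substituted projection (after `N` restoration, ASCII order may
  locally differ since `G < N < T`).

## Numerical and degenerate-input behaviour

* Integers are arbitrary-precision throughout; `L = 100` reads become
  ~200-bit integers and their codewords ~215 bits. No word-size
  assumption exists anywhere in the codec.
* Empty input yields a valid header-only container; decompressing it
  yields an empty output and a reported bpb of `n/a`.
* A truncated or structurally corrupt container raises a distinct
  corruption error (CLI exit code 4). A decoder that is asked for more
  bits than remain — including via a corrupted length group that would
  imply a huge read — fails with a truncation error *before* allocating
  anything of that size.
* Oversized partitions (possible under skewed base composition) are
  re-spilled one base deeper, recursively, before loading.

## What the synthetic generator does and does not emulate

The generator produces fixed-length reads in two modes: *uniform*
(i.i.d. bases — a worst case with essentially no exploitable
redundancy) and *coverage* (reads are windows of one random backing
sequence, so read-space constraint grows with coverage depth). On top
of either mode it injects exact duplicates at a configurable rate
(emulating PCR/enzyme bias) and i.i.d. `N` bases at a configurable
per-base rate. Generation is fully deterministic given the seed.

It does **not** emulate substitution/indel sequencing errors, quality
dependence of `N` placement, strand sampling, paired ends, or the
repeat structure of real genomes. Passing tests therefore demonstrate
exact losslessness and the delta-skew mechanism, and give a realistic
*shape* for compression ratios at a given coverage — but measured bpb
on real accessions depends on genome repetitiveness and library depth
and will differ from synthetic figures.

Problem sizes used in the test suite — 10⁵ reads for sorting-oracle
equivalence, 1.5–4.3 × 10⁴ reads for end-to-end and bpb checks, a
100 kb backing sequence at 15× coverage for the compression-efficiency
check — were chosen as the smallest collections that exhibit the
deep-coverage regime clearly; all scale linearly if enlarged.

## Known limitations

* Pure-Python throughput is orders of magnitude below what a C
  implementation of the same algorithms achieves; the package
  prioritises a faithful, fully testable specification of the format
  and algorithms.
* No checksum in container version 1: corruption of codeword value
  bits is detected only as a changed multiset, not as an error.
* Long reads (≫ 100 bp) and shallow coverage erode the advantage over
  2-bit packing, because sorted neighbours stop being close in the 4ᴸ
  space. The tool reports bpb so users can see when this happens.
* Single-threaded; blocks are independent, so parallel encode/decode
  is a natural extension but is not implemented.
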