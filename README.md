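# srcomp

Lossless, non-reference compression of **fixed-length DNA short reads**.
`srcomp` targets the situation where compression *speed* matters and no
reference genome is available (metagenomics, *de novo* sequencing,
archiving raw read sets): it compresses the read sequences alone — no
read names, no quality scores — and treats the collection as an
unordered multiset, which is what most downstream assembly and counting
pipelines consume anyway.

## How it works

1. **Ambiguity removal.** Every uncalled base `N` is substituted by `G`;
   the position of each substitution is tracked so it can be undone.
2. **Sorting.** The reads are sorted lexicographically (`A < C < G < T`)
   with a **burst trie** — a cache-friendly trie whose small subtrees
   are bounded-capacity buckets; a bucket that overflows "bursts" into a
   node one level deeper. An in-order traversal emits the sorted reads.
3. **Integer packing.** Each read of length *L* is read as a base-4
   number (`A=00, C=01, G=10, T=11`), giving a **non-decreasing**
   integer sequence *R* = r₁ ≤ r₂ ≤ … ≤ rₙ with rᵢ < 4ᴸ. Lexicographic
   order of reads and numeric order of their integers coincide.
4. **Delta transform.** *R* becomes *D* with d₁ = r₁ + 1 and
   dᵢ = rᵢ − rᵢ₋₁ + 1 — strictly positive, and heavily skewed toward
   small values on deep-coverage data; a duplicated read yields dᵢ = 1.
5. **Elias omega coding.** Each dᵢ is emitted as a self-delimiting
   omega codeword (the value 1 costs a single `0` bit; a *b*-bit value
   costs ~*b* + log₂*b* bits). The ordinals of the substituted `G`s,
   counted across the sorted collection, are difference-coded and
   omega-coded the same way.

Decompression inverts every step exactly: the original read multiset,
`N` positions included, is recovered — in sorted order, since the
original file order is deliberately not stored.

Collections larger than memory are handled by a two-phase scheme:
reads are first spilled to temporary files keyed by their leading bases
(MSD-radix style), then each spill file is sorted and encoded as an
independent block of the output container.

## Worked example

```
$ srcomp generate demo.txt -n 50000 -l 36 --genome-length 120000 \
      --n-rate 0.01 --dup-rate 0.1 --seed 7
reads=50000 length=36 seed=7
$ srcomp compress demo.txt demo.srcomp
reads=50000 length=36 ambiguous=18083 blocks=1 prefix_depth=0 payload_bytes=371285 bpb=1.6502
$ srcomp decompress demo.srcomp restored.txt
reads=50000 length=36 ambiguous=18083 blocks=1
```

The demo draws 50 000 36-mers from a 120 kb random backing sequence
(≈15× coverage) with 1% uncalled bases. The compressed payload is
371 285 bytes for 1 800 000 bases — **1.65 bits per base (bpb)**,
versus 2.0 for trivial 2-bit packing and 8 for the raw text
(1 850 000 bytes → 371 339 bytes on disk including the container
header). `restored.txt` contains exactly the input multiset, sorted,
with every `N` back in place; `sort demo.txt` and `restored.txt` agree
line for line. `srcomp stats demo.srcomp` prints the same figures from
the container header without decoding, plus one line per block.

The deeper the coverage (the more constrained the read space), the
smaller the deltas and the lower the bpb; on long reads sampled from a
large genome the deltas grow and the advantage over 2-bit packing
shrinks — this is a short-read tool by design.

## Library use

```python
import io
from srcomp import compress_reads, read_container, iter_container_reads

buf = io.BytesIO()
report = compress_reads(["ACGTN", "ACGTA", "ACGTA"], buf)
buf.seek(0)
reads = list(iter_container_reads(read_container(buf)))
# ['ACGTA', 'ACGTA', 'ACGTN'] — sorted, N restored
```

## Documentation

* `docs/methods.md` — model, parameters, design choices, limitations.
* `docs/format.md` — the `.srcomp` container layout, bit-exactly.
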