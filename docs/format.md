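# The `.srcomp` container format (version 1)

All multi-byte integers are **little-endian, fixed width**. The file is
a header followed by `B` block records. The format is deterministic:
compressing the same input with the same options twice produces
byte-identical files.

## Header (22 bytes)

| offset | width | type | field |
|-------:|------:|------|-------|
| 0 | 4 | bytes | magic `53 52 43 50` (`"SRCP"`) |
| 4 | 2 | u16 | format version, currently `1` |
| 6 | 4 | u32 | read length `L` in bases |
| 10 | 8 | u64 | total read count `n` (must equal the sum of block read counts) |
| 18 | 4 | u32 | block count `B` |

An empty input produces a header-only file with `L = 0`, `n = 0`,
`B = 0`.

## Block record

| width | type | field |
|------:|------|-------|
| 8 | u64 | `read_count` — omega codewords in the read stream |
| 8 | u64 | `n_count` — omega codewords in the N-position stream |
| 8 | u64 | `read_bits` — exact bit length of the read stream |
| 8 | u64 | `n_bits` — exact bit length of the N-position stream |
| ⌈`read_bits`/8⌉ | bytes | read stream |
| ⌈`n_bits`/8⌉ | bytes | N-position stream |

Within each stream, bits are packed **most-significant-bit first**: the
first bit of the first codeword is bit 7 of the first byte. The final
partial byte of each stream is padded with **zero** bits; a decoder
stops after `read_count` / `n_count` codewords and must never rely on
padding as a terminator (omega streams are self-delimiting per
codeword, not per sequence — hence the explicit counts). Readers reject
nonzero padding bits, counts that do not match the header total, and
any trailing bytes after the last block.

## Stream semantics

* **Read stream**: the Elias omega codewords of the delta sequence
  `d_1 = r_1 + 1`, `d_i = r_i − r_{i−1} + 1`, where `r_i` is the 2-bit
  packing (`A=00, C=01, G=10, T=11`, leftmost base most significant) of
  the `i`-th read of the block in lexicographic order. Delta coding
  **restarts in every block**: `r_0` is implicitly 0, so blocks decode
  independently.
* **N-position stream**: the omega codewords of the difference sequence
  `q_1 = p_1`, `q_j = p_j − p_{j−1}` of the strictly increasing 1-based
  ordinals `p_j` of the `G` occurrences — counted left to right, read
  by read, **within this block's sorted reads only** — that were
  originally an ambiguous base `N`.

Blocks are stored in ascending order of the partition prefix that
produced them, so concatenating decoded blocks yields the whole
collection sorted (in the N→G-substituted projection).

There is no checksum in version 1: a bit flip inside codeword *value*
bits decodes to a different read multiset rather than an error, while
any flip that disturbs codeword *structure*, padding, counts or the
header is rejected.
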