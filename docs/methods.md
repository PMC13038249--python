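# Methods

## The procedure

fapack is a lossless, block-based compressor specialized for FASTA.  The
input is processed in fixed-size blocks of B bytes (default B = 4 MiB;
the last block may be shorter).  Each block is parsed independently:

1. **Boundary context.**  Whether the block starts inside a header line
   is decided by scanning the previous block backwards until an EOL
   (0x0A) or '>' is found — '>' first means "inside a header".  The same
   scan tells whether the block starts at a line boundary, which decides
   whether a leading '>' opens a new header.  The scan is capped at one
   block; a header longer than B degrades gracefully to MIX/RAW content
   and still round-trips.

2. **Layout.**  Header lines ('>' at a line start, through the trailing
   EOL) become RAW records, kept verbatim.  Everything else is sequence:
   its line width is detected once per block as the gap between the first
   two EOLs of the first sequence region.  EOLs that conform to that
   width are removed and counted (`first_span` + k·`line_length`
   positions); a non-conforming EOL — short last line, a mid-sequence
   re-wrap — closes the current SEQ record and is kept verbatim in RAW.
   This makes reconstruction need only three integers per SEQ record.

3. **Case.**  Sequence symbols are uppercased; one bit per symbol records
   whether the original was lowercase (soft-masking).  The bitmask covers
   DNA, NNN and MIX symbols uniformly, so lowercase 'n' runs survive.

4. **Typing.**  The block's concatenated symbols are classified in 8-byte
   words: maximal runs of ACGT-only words become DNA segments, all-'N'
   words become NNN segments, everything else (including the sub-8 tail)
   merges into MIX.  DNA/NNN lengths are therefore always multiples of 8.
   Word classification has word-parallel (SWAR) primitives with naive
   per-byte oracles kept for testing; the bulk path is vectorized with
   numpy to the same semantics.

5. **Encoding.**  DNA is packed to 2 bits/symbol; NNN segments store only
   their lengths; MIX and RAW are verbatim.  The metadata, raw, mix and
   case-flag streams are compressed per block with zstd level 1, long-
   distance matching on, window log 22, with a store-uncompressed escape
   when compression would enlarge a stream.

6. **Adaptive DNA backend.**  The packed DNA stream — dominant for
   genomes — is compressed archive-wide only if a one-time probe on the
   earliest packed DNA shrinks it by at least a factor 1.25 (inclusive).
   A lone genome is essentially incompressible beyond 2-bit packing and
   skips the backend at full speed; redundant collections (viral strain
   sets) clear the threshold and gain multi-fold reductions.  If the
   first block yields < 4 KiB of packed DNA, the probe pools packed DNA
   from subsequent blocks until 4 KiB is reached or input ends (decision
   defaults to off if it never is); the affected blocks are buffered so
   the header is written once.  The decision applies uniformly to every
   block.

Decompression inverts each step per block; every block record decodes
from its own bytes alone, and the per-block CRC32 (on by default)
localizes corruption.  The whole pipeline is total on arbitrary bytes:
non-FASTA input degrades to MIX/RAW content and round-trips bit-exactly.

## Parameters

| parameter         | default | meaning |
|-------------------|---------|---------|
| block size B      | 4 MiB   | parse/compress unit; power of two ≥ 64 KiB |
| threads t         | 4       | scheduling look-back window (see below) |
| probe threshold   | 1.25    | inclusive packed/compressed ratio enabling the DNA backend |
| probe minimum     | 4 KiB   | packed-DNA bytes pooled before probing |
| backend           | zstd level 1, LDM on, window log 22 | side-stream and (when enabled) DNA compression |
| checksum          | on      | per-block CRC32 of the original bytes |

## Scheduling and determinism

The worker model is a contract, not a mechanism: block *i* may not start
before block *i − t* has finished (which guarantees the previous block's
bytes are available for the boundary scan), and records are emitted in
index order.  This implementation executes serially, which satisfies the
contract trivially; consequently archive bytes are a pure function of
(input bytes, configuration) and never depend on t.  The `threads`
parameter is validated and kept in the configuration surface so a
concurrent executor can be swapped in without changing the format.

## Numerical and encoding choices

* Bit orders: 2-bit DNA codes (A=0, C=1, G=2, T=3) and case-flag bits are
  LSB-first.  Arbitrary but fixed; normative in docs/FORMAT.md.
* EOL is strictly 0x0A.  CR (0x0D) is ordinary sequence content; CRLF
  files keep their CR bytes in MIX and round-trip exactly.
* One line width per block.  Mixed-width blocks lose some EOL removal
  (the non-conforming EOLs ride in RAW) but never correctness.
* The probe ratio uses whole zstd frame sizes, and the threshold
  comparison is inclusive (≥ 1.25).
* Degenerate inputs: empty input yields a header-plus-terminator archive
  that decodes to empty output; a '>' mid-line is sequence content, not a
  header; ';' comment lines are treated as sequence-region content.
* Whole-block verbatim escape: if a block's typed encoding (including
  the case-flag stream, which costs 1 bit/symbol) would exceed the
  block's original size, the block is stored as a single verbatim RAW
  record.  This bounds worst-case expansion to per-block constants
  (observed ≤ ~60 bytes per archive on incompressible data) and makes
  the compressor never meaningfully worse than a plain copy.

## Synthetic data

The bundled generator emulates the structural features the compressor
exploits: multi-record FASTA with configurable header lengths and line
widths (fixed, per-record, irregular), GC content, soft-masked runs and
N-runs with geometric lengths, IUPAC ambiguity codes, redundant
collections (n near-identical copies with per-base substitution rates),
a protein alphabet, and adversarial shapes targeting block boundaries
(headers and lines spanning blocks, giant headers, CRLF, all-N, all-EOL,
arbitrary binary).  Generation is a pure function of the spec.

What it does not emulate: real genomic repeat structure, chromosome-scale
long-range correlations, or realistic header grammars.  Passing tests
therefore demonstrate losslessness, determinism and the size accounting
of the format on structurally FASTA-like data — not the compression
ratios achievable on real genomes, which depend on sequence statistics
the generator does not model.

## Problem sizes used in tests

The test battery uses ~1100 corpora of up to a few hundred KiB plus
8 MiB inputs for the packing-bound, N-collapse and redundancy checks, at
block sizes 64 KiB / 1 MiB / 4 MiB; these sizes exercise every block
boundary case while keeping the suite fast.  Lengths beyond 2^32 are
covered at the container level (varint round-trips) rather than with a
multi-GiB end-to-end file.

## Known limitations

* Line-width detection is per block and single-valued; files alternating
  widths rapidly compress worse (never incorrectly).
* The serial executor leaves multi-core speedups on the table; the format
  and scheduling contract already permit a parallel implementation.
* Probe buffering holds prepared blocks in memory while the packed-DNA
  minimum has not been reached, which for DNA-free inputs means until
  end of input.
* No random access below block granularity, no encryption, no
  FASTQ-specific handling (FASTQ still round-trips as generic content).
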