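# fapack archive format, version 1

A fapack archive is a single binary file: one global header, a sequence of
block records in strictly increasing index order, and a terminator.  Every
multi-byte integer is **little-endian**.  Variable-length integers
(`varint`) are unsigned LEB128 — 7 value bits per byte, high bit = more —
capped at 64 bits; a longer encoding is a format error.

## Global header (21 bytes)

| offset | size | field                                                    |
|--------|------|----------------------------------------------------------|
| 0      | 4    | magic `"FAPK"` (0x46 0x41 0x50 0x4B)                     |
| 4      | 2    | format version, u16 (this document: 1)                   |
| 6      | 1    | flags, u8 (see below)                                    |
| 7      | 1    | backend compression level, u8                            |
| 8      | 1    | backend window log, u8                                   |
| 9      | 4    | block size B in bytes, u32 (power of two, ≥ 65536)       |
| 13     | 8    | input size in bytes, u64                                 |

Flags: bit 0 = DNA stream is backend-compressed archive-wide (probe
decision); bit 1 = per-block CRC32 present; bit 2 = backend long-distance
matching enabled.  Remaining bits must be zero.

Input size `0xFFFFFFFFFFFFFFFF` means "unknown at compression time" (the
source was an unseekable stream); the decompressor then validates the
total against the sum of per-block original lengths only.

## Block records

Each block covers exactly B input bytes, except the last, which may be
shorter.  A record decodes independently of all other records.

| field            | type   | notes                                          |
|------------------|--------|------------------------------------------------|
| index            | u32    | 0-based; `0xFFFFFFFF` is the terminator (nothing follows it) |
| original_length  | varint | bytes of input covered by this block           |
| stream_flags     | u16    | presence bit *i*, backend-compressed bit *8+i* |
| crc32            | u32    | CRC32 of the original block bytes; present iff header flag bit 1 |
| streams…         |        | present streams in fixed order, see below      |

Stream order (index *i* in `stream_flags`): 0 metadata, 1 raw, 2 dna,
3 mix, 4 flags.  The metadata stream is always present; the others are
present iff non-empty.  Each present stream is stored as:

    varint  uncompressed_length
    varint  stored_length
    bytes   payload[stored_length]

If the stream's compressed bit is set, the payload is one standard zstd
frame (content size recorded) that must decompress to exactly
`uncompressed_length` bytes; otherwise the payload is the stream verbatim
and `stored_length == uncompressed_length`.

The metadata, raw, mix and flags streams are compressed per block unless
compression would not shrink them (store-uncompressed escape).  The dna
stream's compressed bit always equals header flag bit 0.

## Stream contents

* **metadata** — layout of the block:

      varint line_length            # 0 = no EOLs were removed in this block
      varint n_records
      repeat n_records:
          u8 kind                   # 0 = RAW, 1 = SEQ
          RAW:  varint byte_length
          SEQ:  varint n_symbols, varint first_span, varint n_eols_removed
      varint n_segments
      repeat n_segments:
          u8 type                   # 0 = DNA, 1 = NNN, 2 = MIX
          varint length             # symbols; DNA/NNN are multiples of 8

* **raw** — verbatim bytes of all RAW records, concatenated in record
  order (header lines including their trailing EOL, and EOLs that did not
  conform to the detected line width).

* **dna** — the DNA segments' symbols, 2-bit packed: A=0, C=1, G=2, T=3,
  four symbols per byte, the first symbol of each quartet in the
  least-significant bits.  Uncompressed length = Σ DNA segment lengths / 4.

* **mix** — uppercased symbols of all MIX segments, verbatim, in segment
  order.  NNN segments store nothing; their lengths in the segment list
  fully describe them.

* **flags** — one bit per sequence symbol of the block (across all SEQ
  records in order), 1 = the original byte was a lowercase letter.
  LSB-first within each byte; pad bits of the final byte are zero.

## Reconstruction

Replay the records in order.  A RAW record copies `byte_length` bytes
from the raw stream.  A SEQ record takes `n_symbols` from the segment
streams (DNA unpacked, NNN re-materialized as 'N', MIX copied), restores
case from the flag bits (+32 where flagged), and re-inserts
`n_eols_removed` EOLs: the first after `first_span` symbols, then one
after every `line_length` symbols.  Invariant per block:
Σ RAW byte_length + Σ (SEQ n_symbols + n_eols_removed) = original_length.

A block whose typed encoding would exceed its original size is stored as
a single RAW record covering the whole block (verbatim escape); such a
record has no segments and no flag bits.
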