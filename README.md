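# fapack

Block-based lossless compression for FASTA files — and, by construction,
for any byte stream.

Genome repositories still overwhelmingly ship FASTA as gzip, which knows
nothing about the format: four-letter sequences stored at 8 bits/symbol,
line breaks every 60–80 columns, soft-masking encoded as letter case.
fapack is for people who store, move, or pipeline genome-scale FASTA and
want a compact, fast, verifiable archive format: it parses the structure
out of the text first, then lets a general-purpose backend handle what
actually needs modeling.

## How it works

The input is cut into fixed-size blocks (B = 4 MiB by default).  Each
block is parsed into typed content:

* **DNA** — runs of pure A/C/G/T (in 8-byte words), packed to 2 bits per
  symbol;
* **NNN** — runs of N (assembly gaps), stored as *lengths only*;
* **MIX** — everything else in the sequence (IUPAC ambiguity codes,
  proteins, stray bytes), verbatim;
* **RAW** — header lines and any line break that does not fit the
  detected line width, verbatim.

Regular line breaks are removed and re-derived from three integers per
record; letter case is preserved as a 1-bit-per-symbol mask, so
soft-masked regions survive exactly.  The side streams are compressed
per block with zstd (level 1, long-distance matching, window log 22).
The packed DNA stream is special-cased: a one-time **probe** compresses
the earliest packed DNA and enables the backend archive-wide only if it
shrinks by at least a factor 1.25.  Single genomes — essentially
incompressible beyond 2-bit packing — skip the backend entirely;
redundant collections such as viral strain sets clear the threshold and
compress many-fold.  Every block record decodes independently and
carries a CRC32 of its original bytes.

Decompression inverts the parse bit-exactly: `decompress(compress(x)) == x`
for arbitrary `x`, FASTA or not.

## Worked example

Two synthetic inputs from the bundled generator: a 2 Mb genome-like
record, and a collection of 200 near-identical 20 kb "strains" (0.1%
substitutions per copy):

```
$ fapack compress genome.fa genome.fpk
2033507 -> 499648 bytes (ratio 4.07, 1 blocks, dna_backend=off)

$ fapack compress strains.fa strains.fpk
4095410 -> 26055 bytes (ratio 157.18, 1 blocks, dna_backend=on)

$ fapack decompress strains.fpk restored.fa && cmp strains.fa restored.fa && echo IDENTICAL
restored 4095410 bytes from 1 blocks
IDENTICAL
```

The single genome lands at ratio 4.07 — the ceiling set by 2-bit packing
plus newline removal (61 input bytes per 60 bases → ~15 bytes packed) —
and the probe correctly left the DNA backend off.  The strain collection
triggered the probe (`dna_backend=on`): its packed DNA is highly
redundant across copies, and the archive shrinks 157-fold.
`fapack inspect strains.fpk` shows where the bytes went — for this
archive the 1,000,000 packed DNA bytes stored as 21,844, with metadata,
headers and case flags in their own small streams.  `fapack verify`
decodes an archive against its checksums without writing output.

The library mirrors the CLI: `fapack.compress_file`,
`fapack.decompress_file`, `fapack.inspect_archive`,
`fapack.PipelineConfig`, plus the corpus generator under
`fapack.synthgen`.  The archive layout is specified byte-exactly in
[docs/FORMAT.md](docs/FORMAT.md); design notes live in
[docs/methods.md](docs/methods.md).

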