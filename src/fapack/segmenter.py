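"""Block parsing: layout records, typed segments, case flags — and its inverse.

One raw input block is turned into

* an ordered list of :class:`LayoutRecord` (RAW = bytes kept verbatim,
  SEQ = sequence symbols with end-of-line re-insertion parameters),
* an ordered list of typed :class:`Segment` (DNA / NNN / MIX) covering the
  concatenated sequence symbols of the block,
* three byte payloads (raw, DNA, MIX) plus a per-symbol lowercase flag,

such that :func:`unparse_block` reconstructs the original bytes exactly.
The parse is total: arbitrary binary degrades to MIX/RAW content and still
round-trips.

Conventions: EOL is strictly 0x0A; a header is a line whose first byte is
'>'; one line length per block, measured as the gap between the first two
EOLs of the block's first sequence region.  EOLs that conform to that
width are removed and counted; any non-conforming EOL terminates the
current SEQ record and is kept verbatim in a RAW record.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .errors import CorruptMetadataError

__all__ = [
    "EOL",
    "HEADER_BYTE",
    "SegmentType",
    "RecordKind",
    "RawBlock",
    "BoundaryContext",
    "LayoutRecord",
    "Segment",
    "ParsedBlock",
    "scan_boundary_context",
    "detect_line_length",
    "extract_case_flags",
    "classify_segments",
    "parse_block",
    "unparse_block",
]

EOL = 0x0A
HEADER_BYTE = 0x3E  # '>'
_N = 0x4E  # 'N'

_IS_ACGT = np.zeros(256, dtype=bool)
for _b in b"ACGT":
    _IS_ACGT[_b] = True


class SegmentType(enum.IntEnum):
    DNA = 0
    NNN = 1
    MIX = 2


class RecordKind(enum.IntEnum):
    RAW = 0
    SEQ = 1


@dataclass(frozen=True)
class RawBlock:
    """One fixed-size chunk of original input bytes."""

    index: int
    data: bytes
    is_last: bool = False


@dataclass(frozen=True)
class BoundaryContext:
    """What the previous block's tail implies about this block's first byte.

    ``starts_in_header``: the first byte lies inside a header line opened in
    an earlier block.  ``at_line_start``: the first byte begins a new line
    (the previous block ended with an EOL, or there is no previous block),
    which decides whether a leading '>' opens a header.
    """

    starts_in_header: bool = False
    at_line_start: bool = True


@dataclass(frozen=True)
class LayoutRecord:
    """Unit of byte-exact reconstruction.

    RAW: ``byte_length`` bytes copied verbatim (headers, non-conforming
    EOLs).  SEQ: ``n_symbols`` sequence letters with ``n_eols_removed``
    EOLs re-inserted after ``first_span`` symbols and then after every
    ``line_length`` symbols (the width lives on the block).
    """

    kind: RecordKind
    byte_length: int = 0
    n_symbols: int = 0
    first_span: int = 0
    n_eols_removed: int = 0


@dataclass(frozen=True)
class Segment:
    """A typed run of sequence symbols; DNA/NNN lengths are multiples of 8."""

    type: SegmentType
    length: int


@dataclass
class ParsedBlock:
    index: int
    records: list[LayoutRecord]
    segments: list[Segment]
    line_length: int
    raw_payload: bytes
    dna_payload: bytes  # uppercased ACGT symbols, pre-packing
    mix_payload: bytes  # uppercased symbols
    case_flags: np.ndarray = field(repr=False)  # uint8 0/1, one per SEQ symbol

    @property
    def n_symbols(self) -> int:
        return int(self.case_flags.size)


def scan_boundary_context(prev_tail: bytes) -> BoundaryContext:
    """Derive the boundary context from the previous block's byte suffix.

    Scanning right-to-left, meeting '>' before any EOL means the next block
    starts inside a header line.  With neither present the scan falls back
    to "not in a header" (an over-long header degrades to MIX/RAW content,
    which still round-trips).  Pass ``b""`` for the first block.
    """
    ig = prev_tail.rfind(b">")
    ie = prev_tail.rfind(b"\n")
    in_header = ig > ie  # ig >= 0 implied
    at_line_start = len(prev_tail) == 0 or prev_tail.endswith(b"\n")
    return BoundaryContext(starts_in_header=in_header, at_line_start=at_line_start)


def detect_line_length(block: bytes, start: int) -> int:
    """Line width of the block, from the first two EOLs at/after ``start``.

    ``start`` is the first sequence byte of the block's first sequence
    region.  The width is the symbol count between the first two EOLs; with
    a single EOL (region or block ends first) it is the distance from
    ``start``; with none it is 0, meaning no EOL removal in this block.
    """
    e1 = block.find(b"\n", start)
    if e1 < 0:
        return 0
    # the line after e1 must still be sequence data, not a header
    if block[e1 + 1 : e1 + 2] == b">":
        return e1 - start
    e2 = block.find(b"\n", e1 + 1)
    if e2 < 0:
        return e1 - start
    return e2 - e1 - 1


def extract_case_flags(symbols: bytes):
    """Uppercase ``symbols``; flag bit i = 1 iff byte i was a lowercase letter.

    Non-letter bytes map to themselves with flag 0; length is preserved.
    Returns ``(uppercased: bytes, flags: uint8 array of 0/1)``.
    """
    arr = np.frombuffer(symbols, dtype=np.uint8)
    lower = (arr >= 0x61) & (arr <= 0x7A)
    upper = arr - lower.astype(np.uint8) * 32
    return upper.tobytes(), lower.astype(np.uint8)


def classify_segments(symbols: bytes) -> list[Segment]:
    """Partition uppercased, EOL-free symbols into DNA / NNN / MIX segments.

    Greedy scan in 8-byte words from offset 0: maximal runs of ACGT-only
    words become DNA segments, maximal runs of all-'N' words become NNN
    segments, everything else — including the sub-8 tail — coalesces into
    MIX.  Segment lengths cover the input exactly, in order; DNA and NNN
    lengths are therefore always multiples of 8.
    """
    segments, _ = _classify(np.frombuffer(symbols, dtype=np.uint8))
    return segments


def _classify(upper: np.ndarray):
    """Shared classifier: returns (segments, word_classes or None)."""
    n = upper.size
    nw = n // 8
    segments: list[Segment] = []
    cls = None
    if nw:
        words = upper[: nw * 8].reshape(nw, 8)
        acgt = _IS_ACGT[words].all(axis=1)
        nnn = (words == _N).all(axis=1)
        cls = np.full(nw, int(SegmentType.MIX), dtype=np.int8)
        cls[acgt] = int(SegmentType.DNA)
        cls[nnn] = int(SegmentType.NNN)
        bounds = np.flatnonzero(np.diff(cls)) + 1
        starts = np.concatenate(([0], bounds))
        ends = np.concatenate((bounds, [nw]))
        for s, e in zip(starts, ends):
            segments.append(Segment(SegmentType(int(cls[s])), int(e - s) * 8))
    tail = n - nw * 8
    if tail:
        if segments and segments[-1].type is SegmentType.MIX:
            segments[-1] = Segment(SegmentType.MIX, segments[-1].length + tail)
        else:
            segments.append(Segment(SegmentType.MIX, tail))
    return segments, cls


def _append_raw(records: list, spans: list, s: int, e: int) -> None:
    """Append a RAW record for bytes [s, e), merging with an adjacent RAW."""
    if e <= s:
        return
    if records and records[-1].kind is RecordKind.RAW and spans[-1][1] == s:
        records[-1] = LayoutRecord(RecordKind.RAW, records[-1].byte_length + (e - s))
        spans[-1] = (spans[-1][0], e)
    else:
        records.append(LayoutRecord(RecordKind.RAW, e - s))
        spans.append((s, e))


def _build_region_records(
    records: list,
    raw_spans: list,
    region_start: int,
    region_end: int,
    eols: np.ndarray,
    line_length: int,
) -> None:
    """Emit SEQ/RAW records for one sequence region [region_start, region_end).

    ``eols`` are the EOL positions inside the region.  The first EOL of a
    SEQ record may fall short of the block width (the record can start
    mid-line); afterwards only EOLs at exactly ``line_length`` symbols
    conform.  Non-conforming EOLs close the record and land in RAW.
    """
    m = int(eols.size)
    L = line_length
    if m == 0:
        if region_end > region_start:
            records.append(
                LayoutRecord(RecordKind.SEQ, n_symbols=region_end - region_start)
            )
        return
    # symbol run before each EOL
    ks = np.diff(eols, prepend=region_start - 1) - 1
    ks[0] = eols[0] - region_start
    conform = np.zeros(m, dtype=bool)
    if L > 0:
        conform[ks == L] = True
        for i in np.flatnonzero(ks < L):
            # a short gap conforms only as the first EOL of its record
            if i == 0 or not conform[i - 1]:
                conform[i] = True
    ck = np.concatenate(([0], np.cumsum(ks)))
    prev = 0
    for b in np.flatnonzero(~conform):
        b = int(b)
        n_sym = int(ck[b + 1] - ck[prev])
        n_rem = b - prev
        if n_sym or n_rem:
            records.append(
                LayoutRecord(
                    RecordKind.SEQ,
                    n_symbols=n_sym,
                    first_span=int(ks[prev]) if n_rem else 0,
                    n_eols_removed=n_rem,
                )
            )
        q = int(eols[b])
        _append_raw(records, raw_spans, q, q + 1)
        prev = b + 1
    tail = region_end - (int(eols[m - 1]) + 1)
    n_sym = int(ck[m] - ck[prev]) + tail
    n_rem = m - prev
    if n_sym or n_rem:
        records.append(
            LayoutRecord(
                RecordKind.SEQ,
                n_symbols=n_sym,
                first_span=int(ks[prev]) if n_rem else 0,
                n_eols_removed=n_rem,
            )
        )


def parse_block(raw: RawBlock, ctx: BoundaryContext) -> ParsedBlock:
    """Parse one block into records, segments and typed payloads.

    Total on any byte content; :func:`unparse_block` inverts it exactly.
    """
    data = raw.data
    n = len(data)
    arr = np.frombuffer(data, dtype=np.uint8)
    eol_all = np.flatnonzero(arr == EOL)
    records: list[LayoutRecord] = []
    raw_spans: list[tuple[int, int]] = []
    line_length: int | None = None
    p = 0

    if ctx.starts_in_header and n:
        end = int(eol_all[0]) + 1 if eol_all.size else n
        _append_raw(records, raw_spans, 0, end)
        p = end

    # header starts: '>' at a line start
    if n:
        prev_is_eol = np.empty(n, dtype=bool)
        prev_is_eol[0] = ctx.at_line_start and not ctx.starts_in_header
        prev_is_eol[1:] = arr[:-1] == EOL
        hdr_starts = np.flatnonzero((arr == HEADER_BYTE) & prev_is_eol)
    else:
        hdr_starts = np.empty(0, dtype=np.intp)

    hi = int(np.searchsorted(hdr_starts, p))
    while p < n:
        if hi < hdr_starts.size and int(hdr_starts[hi]) == p:
            j = int(np.searchsorted(eol_all, p))
            end = int(eol_all[j]) + 1 if j < eol_all.size else n
            _append_raw(records, raw_spans, p, end)
            p = end
            hi += 1
            continue
        region_end = int(hdr_starts[hi]) if hi < hdr_starts.size else n
        if line_length is None:
            line_length = detect_line_length(data, p)
        lo = int(np.searchsorted(eol_all, p))
        up = int(np.searchsorted(eol_all, region_end))
        _build_region_records(records, raw_spans, p, region_end, eol_all[lo:up], line_length)
        p = region_end
    if line_length is None:
        line_length = 0

    raw_mask = np.zeros(n, dtype=bool)
    for s, e in raw_spans:
        raw_mask[s:e] = True
    raw_payload = arr[raw_mask].tobytes()

    symbols = arr[~raw_mask & (arr != EOL)]
    lower = (symbols >= 0x61) & (symbols <= 0x7A)
    upper = symbols - lower.astype(np.uint8) * 32

    segments, cls = _classify(upper)
    if cls is not None:
        nw = cls.size
        byte_cls = np.repeat(cls, 8)
        head = upper[: nw * 8]
        dna_payload = head[byte_cls == int(SegmentType.DNA)].tobytes()
        mix_payload = head[byte_cls == int(SegmentType.MIX)].tobytes() + upper[nw * 8 :].tobytes()
    else:
        dna_payload = b""
        mix_payload = upper.tobytes()

    return ParsedBlock(
        index=raw.index,
        records=records,
        segments=segments,
        line_length=line_length,
        raw_payload=raw_payload,
        dna_payload=dna_payload,
        mix_payload=mix_payload,
        case_flags=lower.astype(np.uint8),
    )


def unparse_block(parsed: ParsedBlock) -> bytes:
    """Reconstruct the original block bytes from a parsed block.

    Raises :class:`CorruptMetadataError` on any stream/count mismatch.
    """
    idx = parsed.index
    total_seq = sum(seg.length for seg in parsed.segments)
    total_rec = sum(
        r.n_symbols for r in parsed.records if r.kind is RecordKind.SEQ
    )
    if total_seq != total_rec:
        raise CorruptMetadataError(
            f"segment symbols ({total_seq}) != SEQ record symbols ({total_rec})", idx
        )
    if parsed.case_flags.size != total_seq:
        raise CorruptMetadataError(
            f"case flags ({parsed.case_flags.size}) != symbols ({total_seq})", idx
        )

    out = np.empty(total_seq, dtype=np.uint8)
    dna = np.frombuffer(parsed.dna_payload, dtype=np.uint8)
    mix = np.frombuffer(parsed.mix_payload, dtype=np.uint8)
    pos = dpos = mpos = 0
    for seg in parsed.segments:
        ln = seg.length
        if seg.type is SegmentType.DNA:
            if dpos + ln > dna.size:
                raise CorruptMetadataError("DNA payload exhausted", idx)
            out[pos : pos + ln] = dna[dpos : dpos + ln]
            dpos += ln
        elif seg.type is SegmentType.NNN:
            out[pos : pos + ln] = _N
        else:
            if mpos + ln > mix.size:
                raise CorruptMetadataError("MIX payload exhausted", idx)
            out[pos : pos + ln] = mix[mpos : mpos + ln]
            mpos += ln
        pos += ln
    if dpos != dna.size or mpos != mix.size:
        raise CorruptMetadataError("payload bytes left over after segments", idx)

    # restore case: flagged symbols are uppercase letters -> +32
    out = out + parsed.case_flags * np.uint8(32)

    parts: list[bytes] = []
    raw = parsed.raw_payload
    L = parsed.line_length
    rpos = spos = 0
    for rec in parsed.records:
        if rec.kind is RecordKind.RAW:
            if rpos + rec.byte_length > len(raw):
                raise CorruptMetadataError("RAW payload exhausted", idx)
            parts.append(raw[rpos : rpos + rec.byte_length])
            rpos += rec.byte_length
        else:
            syms = out[spos : spos + rec.n_symbols]
            spos += rec.n_symbols
            if rec.n_eols_removed:
                if L <= 0:
                    raise CorruptMetadataError(
                        "EOLs removed but block line length is 0", idx
                    )
                positions = rec.first_span + L * np.arange(rec.n_eols_removed)
                if positions.size and (
                    positions[-1] > rec.n_symbols or rec.first_span > L
                ):
                    raise CorruptMetadataError("EOL re-insertion out of range", idx)
                syms = np.insert(syms, positions, EOL)
            parts.append(syms.tobytes())
    if rpos != len(raw) or spos != total_seq:
        raise CorruptMetadataError("payload bytes left over after records", idx)
    return b"".join(parts)
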