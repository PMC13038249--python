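"""Byte-exact archive serialization: header, block records, metadata.

The on-disk dialect is documented in docs/FORMAT.md.  All multi-byte
integers are little-endian; variable-length integers are unsigned LEB128
capped at 64 bits.  Within a block record the streams appear in fixed
order — metadata, raw, dna, mix, flags — because the decoder needs the
metadata first.  A terminator pseudo-record (index 0xFFFFFFFF) marks the
end of the block sequence, which lets archives be produced by streaming
compressors that do not know the input size up front.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

from .backend import BackendProfile
from .errors import (
    CorruptMetadataError,
    FormatError,
    TruncationError,
    UnsupportedVersionError,
)
from .segmenter import LayoutRecord, ParsedBlock, RecordKind, Segment, SegmentType

__all__ = [
    "MAGIC",
    "FORMAT_VERSION",
    "INPUT_SIZE_UNKNOWN",
    "TERMINATOR_INDEX",
    "STREAM_META",
    "STREAM_RAW",
    "STREAM_DNA",
    "STREAM_MIX",
    "STREAM_FLAGS",
    "STREAM_ORDER",
    "ArchiveHeader",
    "StreamPayload",
    "BlockRecord",
    "write_header",
    "read_header",
    "write_block_record",
    "read_block_record",
    "write_terminator",
    "serialize_metadata",
    "deserialize_metadata",
]

MAGIC = b"FAPK"
FORMAT_VERSION = 1
INPUT_SIZE_UNKNOWN = 0xFFFF_FFFF_FFFF_FFFF
TERMINATOR_INDEX = 0xFFFF_FFFF
MIN_BLOCK_SIZE = 64 * 1024

STREAM_META = 0
STREAM_RAW = 1
STREAM_DNA = 2
STREAM_MIX = 3
STREAM_FLAGS = 4
STREAM_ORDER = (STREAM_META, STREAM_RAW, STREAM_DNA, STREAM_MIX, STREAM_FLAGS)

_FLAG_DNA_BACKEND = 0x01
_FLAG_CRC32 = 0x02
_FLAG_LONG_MATCHING = 0x04

_HEADER_STRUCT = struct.Struct("<4sHBBBIQ")


@dataclass(frozen=True)
class ArchiveHeader:
    """Global archive configuration, written once at the front of the file."""

    block_size: int
    dna_backend: bool
    backend_profile: BackendProfile = BackendProfile()
    input_size: int = INPUT_SIZE_UNKNOWN
    checksum: bool = True
    format_version: int = FORMAT_VERSION


@dataclass(frozen=True)
class StreamPayload:
    """One stored stream of a block: payload bytes plus its original size."""

    uncompressed_length: int
    data: bytes
    compressed: bool

    @property
    def stored_length(self) -> int:
        return len(self.data)


@dataclass
class BlockRecord:
    """Serialized form of one block; decodes independently of all others."""

    index: int
    original_length: int
    streams: dict[int, StreamPayload] = field(default_factory=dict)
    crc32: int | None = None


# ---------------------------------------------------------------------------
# varints (unsigned LEB128, 64-bit cap)

def _put_uvarint(buf: bytearray, value: int) -> None:
    if value < 0:
        raise ValueError("varint value must be non-negative")
    while True:
        b = value & 0x7F
        value >>= 7
        if value:
            buf.append(b | 0x80)
        else:
            buf.append(b)
            return


def _get_uvarint(view, pos: int) -> tuple[int, int]:
    result = 0
    shift = 0
    while True:
        if pos >= len(view):
            raise CorruptMetadataError("varint runs past end of buffer")
        b = view[pos]
        pos += 1
        result |= (b & 0x7F) << shift
        if not b & 0x80:
            return result, pos
        shift += 7
        if shift > 63:
            raise CorruptMetadataError("varint overflow (more than 64 bits)")


def _read_uvarint(fh, block_index: int | None = None) -> int:
    result = 0
    shift = 0
    while True:
        byte = fh.read(1)
        if not byte:
            raise TruncationError("archive truncated inside a varint", block_index)
        b = byte[0]
        result |= (b & 0x7F) << shift
        if not b & 0x80:
            return result
        shift += 7
        if shift > 63:
            raise CorruptMetadataError("varint overflow (more than 64 bits)", block_index)


def _read_exact(fh, n: int, block_index: int | None = None) -> bytes:
    data = fh.read(n)
    if len(data) != n:
        raise TruncationError(
            f"archive truncated: wanted {n} bytes, got {len(data)}", block_index
        )
    return data


# ---------------------------------------------------------------------------
# header

def write_header(fh, header: ArchiveHeader) -> int:
    flags = 0
    if header.dna_backend:
        flags |= _FLAG_DNA_BACKEND
    if header.checksum:
        flags |= _FLAG_CRC32
    if header.backend_profile.long_matching:
        flags |= _FLAG_LONG_MATCHING
    blob = _HEADER_STRUCT.pack(
        MAGIC,
        header.format_version,
        flags,
        header.backend_profile.level,
        header.backend_profile.window_log,
        header.block_size,
        header.input_size,
    )
    fh.write(blob)
    return len(blob)


def read_header(fh) -> ArchiveHeader:
    blob = _read_exact(fh, _HEADER_STRUCT.size)
    magic, version, flags, level, window_log, block_size, input_size = (
        _HEADER_STRUCT.unpack(blob)
    )
    if magic != MAGIC:
        raise FormatError(f"not a fapack archive (magic {magic!r})")
    if version != FORMAT_VERSION:
        raise UnsupportedVersionError(
            f"archive format version {version} not supported (this build reads {FORMAT_VERSION})"
        )
    if block_size < MIN_BLOCK_SIZE or block_size & (block_size - 1):
        raise FormatError(f"invalid block size {block_size} in header")
    return ArchiveHeader(
        block_size=block_size,
        dna_backend=bool(flags & _FLAG_DNA_BACKEND),
        backend_profile=BackendProfile(
            level=level,
            long_matching=bool(flags & _FLAG_LONG_MATCHING),
            window_log=window_log,
        ),
        input_size=input_size,
        checksum=bool(flags & _FLAG_CRC32),
    )


# ---------------------------------------------------------------------------
# block records

def write_block_record(fh, record: BlockRecord, header: ArchiveHeader) -> int:
    buf = bytearray()
    buf += struct.pack("<I", record.index)
    _put_uvarint(buf, record.original_length)
    flags = 0
    for i, sid in enumerate(STREAM_ORDER):
        entry = record.streams.get(sid)
        if entry is not None:
            flags |= 1 << i
            if entry.compressed:
                flags |= 1 << (8 + i)
    buf += struct.pack("<H", flags)
    if header.checksum:
        if record.crc32 is None:
            raise ValueError("checksums enabled but block record has none")
        buf += struct.pack("<I", record.crc32)
    for sid in STREAM_ORDER:
        entry = record.streams.get(sid)
        if entry is None:
            continue
        _put_uvarint(buf, entry.uncompressed_length)
        _put_uvarint(buf, entry.stored_length)
        buf += entry.data
    fh.write(bytes(buf))
    return len(buf)


def block_record_size(record: BlockRecord, checksum: bool) -> int:
    """Exact serialized size of a block record, without writing it."""
    buf = bytearray()
    _put_uvarint(buf, record.original_length)
    size = 4 + len(buf) + 2 + (4 if checksum else 0)
    for entry in record.streams.values():
        buf = bytearray()
        _put_uvarint(buf, entry.uncompressed_length)
        _put_uvarint(buf, entry.stored_length)
        size += len(buf) + entry.stored_length
    return size


def write_terminator(fh) -> int:
    fh.write(struct.pack("<I", TERMINATOR_INDEX))
    return 4


def read_block_record(fh, header: ArchiveHeader) -> BlockRecord | None:
    """Read the next block record; None at the terminator."""
    prefix = _read_exact(fh, 4)
    (index,) = struct.unpack("<I", prefix)
    if index == TERMINATOR_INDEX:
        return None
    original_length = _read_uvarint(fh, index)
    (flags,) = struct.unpack("<H", _read_exact(fh, 2, index))
    crc = None
    if header.checksum:
        (crc,) = struct.unpack("<I", _read_exact(fh, 4, index))
    streams: dict[int, StreamPayload] = {}
    for i, sid in enumerate(STREAM_ORDER):
        if not flags & (1 << i):
            continue
        ulen = _read_uvarint(fh, index)
        slen = _read_uvarint(fh, index)
        data = _read_exact(fh, slen, index)
        streams[sid] = StreamPayload(ulen, data, bool(flags & (1 << (8 + i))))
    return BlockRecord(index=index, original_length=original_length, streams=streams, crc32=crc)


# ---------------------------------------------------------------------------
# block metadata (serialized inside the metadata stream)

def serialize_metadata(parsed: ParsedBlock) -> bytes:
    buf = bytearray()
    _put_uvarint(buf, parsed.line_length)
    _put_uvarint(buf, len(parsed.records))
    for rec in parsed.records:
        buf.append(int(rec.kind))
        if rec.kind is RecordKind.RAW:
            _put_uvarint(buf, rec.byte_length)
        else:
            _put_uvarint(buf, rec.n_symbols)
            _put_uvarint(buf, rec.first_span)
            _put_uvarint(buf, rec.n_eols_removed)
    _put_uvarint(buf, len(parsed.segments))
    for seg in parsed.segments:
        buf.append(int(seg.type))
        _put_uvarint(buf, seg.length)
    return bytes(buf)


def deserialize_metadata(blob: bytes) -> tuple[int, list[LayoutRecord], list[Segment]]:
    view = memoryview(blob)
    line_length, pos = _get_uvarint(view, 0)
    n_records, pos = _get_uvarint(view, pos)
    records: list[LayoutRecord] = []
    for _ in range(n_records):
        if pos >= len(view):
            raise CorruptMetadataError("metadata truncated inside record list")
        kind = view[pos]
        pos += 1
        if kind == int(RecordKind.RAW):
            blen, pos = _get_uvarint(view, pos)
            records.append(LayoutRecord(RecordKind.RAW, byte_length=blen))
        elif kind == int(RecordKind.SEQ):
            n_sym, pos = _get_uvarint(view, pos)
            first_span, pos = _get_uvarint(view, pos)
            n_rem, pos = _get_uvarint(view, pos)
            records.append(
                LayoutRecord(
                    RecordKind.SEQ,
                    n_symbols=n_sym,
                    first_span=first_span,
                    n_eols_removed=n_rem,
                )
            )
        else:
            raise CorruptMetadataError(f"unknown layout record kind {kind}")
    n_segments, pos = _get_uvarint(view, pos)
    segments: list[Segment] = []
    for _ in range(n_segments):
        if pos >= len(view):
            raise CorruptMetadataError("metadata truncated inside segment list")
        stype = view[pos]
        pos += 1
        length, pos = _get_uvarint(view, pos)
        if stype > 2:
            raise CorruptMetadataError(f"unknown segment type {stype}")
        segments.append(Segment(SegmentType(stype), length))
    if pos != len(view):
        raise CorruptMetadataError("trailing bytes after block metadata")
    return line_length, records, segments
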