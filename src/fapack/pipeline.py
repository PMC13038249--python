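"""End-to-end block compression and decompression.

The compressor cuts the input into fixed-size blocks (4 MiB by default;
the last one may be shorter), parses each block into typed streams, packs
DNA to 2 bits/symbol, and serializes the per-block records in index
order.  The packed-DNA backend choice is fixed once by the first-block
probe and applied uniformly; blocks prepared before the decision is fixed
are buffered so the archive header is written exactly once.

Scheduling contract: with a look-back window of ``threads`` blocks, work
on block *i* may not begin before block *i - threads* has completed, and
records are emitted strictly in index order.  This implementation uses a
serial executor, which satisfies the contract trivially and guarantees
that archive bytes never depend on the thread count.
"""

from __future__ import annotations

import io
import zlib
from dataclasses import dataclass

from . import codecs, container
from .backend import (
    DEFAULT_PROFILE,
    PROBE_MIN_PACKED,
    PROBE_THRESHOLD,
    BackendProfile,
    ProbeDecision,
    compress_stream,
    decompress_stream,
    probe_dna,
)
from .container import (
    STREAM_DNA,
    STREAM_FLAGS,
    STREAM_META,
    STREAM_MIX,
    STREAM_RAW,
    ArchiveHeader,
    BlockRecord,
    StreamPayload,
)
from .errors import ChecksumError, CorruptMetadataError, ValidationError
from .segmenter import (
    BoundaryContext,
    LayoutRecord,
    ParsedBlock,
    RawBlock,
    RecordKind,
    SegmentType,
    parse_block,
    scan_boundary_context,
    unparse_block,
)

import numpy as np

_EMPTY_FLAGS = np.empty(0, dtype=np.uint8)

__all__ = [
    "DEFAULT_BLOCK_SIZE",
    "PipelineConfig",
    "Summary",
    "compress_file",
    "decompress_file",
    "encode_block",
    "decode_block",
    "inspect_archive",
]

DEFAULT_BLOCK_SIZE = 4 * 1024 * 1024


@dataclass(frozen=True)
class PipelineConfig:
    """Tunables of the compressor.

    ``block_size`` must be a power of two of at least 64 KiB.  ``threads``
    is the scheduling look-back window (t >= 1); archive bytes are
    independent of it by construction.  ``dna_backend_override`` skips the
    probe entirely when set.
    """

    block_size: int = DEFAULT_BLOCK_SIZE
    threads: int = 4
    probe_threshold: float = PROBE_THRESHOLD
    backend_profile: BackendProfile = DEFAULT_PROFILE
    checksum: bool = True
    dna_backend_override: bool | None = None

    def __post_init__(self):
        if self.threads < 1:
            raise ValidationError(f"threads must be >= 1, got {self.threads}")
        bs = self.block_size
        if bs < container.MIN_BLOCK_SIZE or bs & (bs - 1):
            raise ValidationError(
                f"block size must be a power of two >= 64 KiB, got {bs}"
            )
        if self.probe_threshold <= 0:
            raise ValidationError("probe threshold must be positive")


@dataclass
class Summary:
    """Result of a compression or decompression run.

    ``ratio`` is original size / archive size (larger is better) in both
    directions.
    """

    blocks: int
    input_size: int
    output_size: int
    ratio: float
    dna_backend: bool
    probe_ratio: float | None = None


@dataclass
class _Prepared:
    raw: RawBlock
    parsed: ParsedBlock
    meta: bytes
    packed_dna: bytes
    packed_flags: bytes


def _prepare_block(raw: RawBlock, ctx: BoundaryContext) -> _Prepared:
    parsed = parse_block(raw, ctx)
    meta = container.serialize_metadata(parsed)
    packed_dna = codecs.pack_dna(parsed.dna_payload).data
    packed_flags = (
        codecs.pack_bits(parsed.case_flags) if parsed.case_flags.size else b""
    )
    return _Prepared(raw, parsed, meta, packed_dna, packed_flags)


def _encode_stream(data: bytes, profile: BackendProfile) -> StreamPayload | None:
    """Backend-compress one stream, storing it raw when that is smaller."""
    if not data:
        return None
    blob = compress_stream(data, profile)
    if len(blob) < len(data):
        return StreamPayload(len(data), blob, True)
    return StreamPayload(len(data), data, False)


def _finalize_block(
    prep: _Prepared, dna_backend: bool, config: PipelineConfig
) -> BlockRecord:
    profile = config.backend_profile
    streams: dict[int, StreamPayload] = {}
    meta = _encode_stream(prep.meta, profile)
    if meta is None:  # metadata is never empty, but keep the record well-formed
        meta = StreamPayload(0, b"", False)
    streams[STREAM_META] = meta
    for sid, data in (
        (STREAM_RAW, prep.parsed.raw_payload),
        (STREAM_MIX, prep.parsed.mix_payload),
        (STREAM_FLAGS, prep.packed_flags),
    ):
        entry = _encode_stream(data, profile)
        if entry is not None:
            streams[sid] = entry
    if prep.packed_dna:
        # the DNA flag mirrors the archive-wide probe decision, uniformly
        if dna_backend:
            streams[STREAM_DNA] = StreamPayload(
                len(prep.packed_dna), compress_stream(prep.packed_dna, profile), True
            )
        else:
            streams[STREAM_DNA] = StreamPayload(
                len(prep.packed_dna), prep.packed_dna, False
            )
    crc = zlib.crc32(prep.raw.data) if config.checksum else None
    record = BlockRecord(
        index=prep.raw.index,
        original_length=len(prep.raw.data),
        streams=streams,
        crc32=crc,
    )
    # whole-block verbatim escape: when the typed encoding enlarges the
    # block (e.g. incompressible binary paying for case flags), store it
    # as a single RAW record instead — expansion stays bounded per block
    size = container.block_record_size(record, config.checksum)
    if size > len(prep.raw.data):
        fallback = _verbatim_record(prep.raw, config)
        if container.block_record_size(fallback, config.checksum) < size:
            return fallback
    return record


def _verbatim_record(raw: RawBlock, config: PipelineConfig) -> BlockRecord:
    parsed = ParsedBlock(
        index=raw.index,
        records=[LayoutRecord(RecordKind.RAW, byte_length=len(raw.data))],
        segments=[],
        line_length=0,
        raw_payload=raw.data,
        dna_payload=b"",
        mix_payload=b"",
        case_flags=_EMPTY_FLAGS,
    )
    profile = config.backend_profile
    streams = {STREAM_META: _encode_stream(container.serialize_metadata(parsed), profile)}
    raw_entry = _encode_stream(raw.data, profile)
    if raw_entry is not None:
        streams[STREAM_RAW] = raw_entry
    return BlockRecord(
        index=raw.index,
        original_length=len(raw.data),
        streams=streams,
        crc32=zlib.crc32(raw.data) if config.checksum else None,
    )


def encode_block(
    raw: RawBlock, ctx: BoundaryContext, dna_backend: bool, config: PipelineConfig | None = None
) -> BlockRecord:
    """Parse and encode one block under a fixed DNA-backend decision."""
    config = config or PipelineConfig()
    return _finalize_block(_prepare_block(raw, ctx), dna_backend, config)


def decode_block(record: BlockRecord) -> bytes:
    """Reconstruct one block's original bytes from its record alone."""
    idx = record.index

    def stream_bytes(sid: int) -> bytes:
        entry = record.streams.get(sid)
        if entry is None:
            return b""
        if entry.compressed:
            return decompress_stream(entry.data, entry.uncompressed_length)
        if len(entry.data) != entry.uncompressed_length:
            raise CorruptMetadataError(
                f"stream {sid} stored length {len(entry.data)} != declared "
                f"{entry.uncompressed_length}",
                idx,
            )
        return entry.data

    meta = stream_bytes(STREAM_META)
    line_length, records, segments = container.deserialize_metadata(meta)
    n_dna = sum(s.length for s in segments if s.type is SegmentType.DNA)
    n_sym = sum(s.length for s in segments)
    packed_dna = stream_bytes(STREAM_DNA)
    if len(packed_dna) * 4 != n_dna:
        raise CorruptMetadataError(
            f"packed DNA stream holds {len(packed_dna) * 4} symbols, "
            f"{n_dna} expected from segments",
            idx,
        )
    dna_payload = codecs.unpack_dna(codecs.PackedDna(packed_dna, n_dna))
    mix_payload = stream_bytes(STREAM_MIX)
    flags = codecs.unpack_bits(stream_bytes(STREAM_FLAGS), n_sym)
    parsed = ParsedBlock(
        index=idx,
        records=records,
        segments=segments,
        line_length=line_length,
        raw_payload=stream_bytes(STREAM_RAW),
        dna_payload=dna_payload,
        mix_payload=mix_payload,
        case_flags=flags,
    )
    data = unparse_block(parsed)
    if len(data) != record.original_length:
        raise CorruptMetadataError(
            f"block decoded to {len(data)} bytes, {record.original_length} expected",
            idx,
        )
    if record.crc32 is not None and zlib.crc32(data) != record.crc32:
        raise ChecksumError(f"CRC32 mismatch in block {idx}", idx)
    return data


# ---------------------------------------------------------------------------
# file-level drivers

def _open_source(src):
    if hasattr(src, "read"):
        return src, False
    return open(src, "rb"), True


def _open_sink(dst):
    if dst is None:
        return io.BytesIO(), True  # discard sink (verify mode)
    if hasattr(dst, "write"):
        return dst, False
    return open(dst, "wb"), True


def _source_size(fh) -> int | None:
    """Bytes remaining in a seekable source; None when unknowable (pipes)."""
    try:
        if fh.seekable():
            cur = fh.tell()
            end = fh.seek(0, 2)
            fh.seek(cur)
            return end - cur
    except (OSError, AttributeError, io.UnsupportedOperation):
        pass
    return None


def _read_block(fh, size: int) -> bytes:
    parts = []
    need = size
    while need:
        chunk = fh.read(need)
        if not chunk:
            break
        parts.append(chunk)
        need -= len(chunk)
    return b"".join(parts)


def compress_file(src, dst, config: PipelineConfig | None = None) -> Summary:
    """Compress ``src`` (path or binary file object) into an archive at ``dst``.

    Returns a :class:`Summary`; the archive bytes are a pure function of
    the input bytes and the configuration.
    """
    config = config or PipelineConfig()
    fin, close_in = _open_source(src)
    fout, close_out = _open_sink(dst)
    try:
        return _compress(fin, fout, config)
    finally:
        if close_in:
            fin.close()
        if close_out:
            fout.close()


def _compress(fin, fout, config: PipelineConfig) -> Summary:
    known_size = _source_size(fin)
    profile = config.backend_profile
    pending: list[_Prepared] = []
    probe_chunks: list[bytes] = []
    probe_bytes = 0
    decision: ProbeDecision | None = None
    if config.dna_backend_override is not None:
        decision = ProbeDecision(config.dna_backend_override, None)

    archive_size = 0
    total_in = 0
    n_blocks = 0
    header: ArchiveHeader | None = None
    ctx = BoundaryContext()
    index = 0

    def flush_header(input_ended: bool) -> None:
        nonlocal header, archive_size
        if header is not None:
            return
        if known_size is not None:
            size_field = known_size
        elif input_ended:
            size_field = total_in
        else:
            size_field = container.INPUT_SIZE_UNKNOWN
        header = ArchiveHeader(
            block_size=config.block_size,
            dna_backend=decision.dna_backend,
            backend_profile=profile,
            input_size=size_field,
            checksum=config.checksum,
        )
        archive_size += container.write_header(fout, header)
        for prep in pending:
            rec = _finalize_block(prep, decision.dna_backend, config)
            archive_size += container.write_block_record(fout, rec, header)
        pending.clear()

    while True:
        data = _read_block(fin, config.block_size)
        if not data:
            break
        raw = RawBlock(index, data, is_last=len(data) < config.block_size)
        prep = _prepare_block(raw, ctx)
        total_in += len(data)
        n_blocks += 1
        if decision is None:
            pending.append(prep)
            probe_chunks.append(prep.packed_dna)
            probe_bytes += len(prep.packed_dna)
            if probe_bytes >= PROBE_MIN_PACKED:
                decision = probe_dna(
                    b"".join(probe_chunks), profile, config.probe_threshold
                )
                flush_header(input_ended=False)
        else:
            flush_header(input_ended=False)
            rec = _finalize_block(prep, decision.dna_backend, config)
            archive_size += container.write_block_record(fout, rec, header)
        ctx = scan_boundary_context(data)
        index += 1

    if decision is None:
        # input ended before the probe minimum: probe what there is, or
        # default to no DNA backend when no packed DNA ever appeared
        decision = ProbeDecision(False, None)
    flush_header(input_ended=True)
    archive_size += container.write_terminator(fout)
    if known_size is not None and known_size != total_in:
        raise OSError(
            f"input size changed during compression ({known_size} -> {total_in})"
        )
    return Summary(
        blocks=n_blocks,
        input_size=total_in,
        output_size=archive_size,
        ratio=total_in / archive_size if archive_size else 0.0,
        dna_backend=decision.dna_backend,
        probe_ratio=decision.probe_ratio,
    )


def decompress_file(src, dst, config: PipelineConfig | None = None) -> Summary:
    """Decode an archive back to the original bytes, verifying checksums.

    ``dst`` may be None to verify without writing output.
    """
    fin, close_in = _open_source(src)
    fout, close_out = _open_sink(dst)
    discard = dst is None
    try:
        header = container.read_header(fin)
        total_out = 0
        archive_size = container._HEADER_STRUCT.size
        n_blocks = 0
        expected = 0
        while True:
            record = container.read_block_record(fin, header)
            if record is None:
                archive_size += 4
                break
            if record.index != expected:
                raise CorruptMetadataError(
                    f"block {record.index} out of order ({expected} expected)",
                    record.index,
                )
            archive_size += container.block_record_size(record, header.checksum)
            data = decode_block(record)
            if not discard:
                fout.write(data)
            total_out += len(data)
            n_blocks += 1
            expected += 1
        if (
            header.input_size != container.INPUT_SIZE_UNKNOWN
            and header.input_size != total_out
        ):
            raise CorruptMetadataError(
                f"archive decodes to {total_out} bytes, header declares "
                f"{header.input_size}"
            )
        return Summary(
            blocks=n_blocks,
            input_size=total_out,
            output_size=archive_size,
            ratio=total_out / archive_size if archive_size else 0.0,
            dna_backend=header.dna_backend,
        )
    finally:
        if close_in:
            fin.close()
        if close_out:
            fout.close()


def inspect_archive(src) -> dict:
    """Header fields, per-block stream sizes and a segment-type histogram.

    Decodes only the metadata stream of each block, not the payloads.
    """
    fin, close_in = _open_source(src)
    try:
        header = container.read_header(fin)
        info = {
            "format_version": header.format_version,
            "block_size": header.block_size,
            "dna_backend": header.dna_backend,
            "checksum": header.checksum,
            "input_size": (
                None
                if header.input_size == container.INPUT_SIZE_UNKNOWN
                else header.input_size
            ),
            "backend_profile": {
                "level": header.backend_profile.level,
                "long_matching": header.backend_profile.long_matching,
                "window_log": header.backend_profile.window_log,
            },
            "blocks": [],
            "segment_histogram": {
                t.name: {"segments": 0, "symbols": 0} for t in SegmentType
            },
        }
        while True:
            record = container.read_block_record(fin, header)
            if record is None:
                break
            entry = record.streams.get(STREAM_META)
            meta = (
                decompress_stream(entry.data, entry.uncompressed_length)
                if entry.compressed
                else entry.data
            )
            line_length, _records, segments = container.deserialize_metadata(meta)
            names = {
                STREAM_META: "metadata",
                STREAM_RAW: "raw",
                STREAM_DNA: "dna",
                STREAM_MIX: "mix",
                STREAM_FLAGS: "flags",
            }
            block_info = {
                "index": record.index,
                "original_length": record.original_length,
                "line_length": line_length,
                "streams": {
                    names[sid]: {
                        "stored": s.stored_length,
                        "uncompressed": s.uncompressed_length,
                        "compressed": s.compressed,
                    }
                    for sid, s in record.streams.items()
                },
            }
            info["blocks"].append(block_info)
            for seg in segments:
                bucket = info["segment_histogram"][seg.type.name]
                bucket["segments"] += 1
                bucket["symbols"] += seg.length
        return info
    finally:
        if close_in:
            fin.close()
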