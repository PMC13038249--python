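"""General-purpose backend compression (zstd) and the adaptive DNA probe.

Every stream except packed DNA is backend-compressed per block by default
(with a store-uncompressed escape when compression would enlarge it).
The packed DNA stream — usually the dominant one — is only *probed* once,
on the earliest block(s): backend compression is applied archive-wide iff
the trial shrinks the packed bytes by at least a factor of 1.25.  A single
genome is hardly compressible beyond 2-bit packing, so the probe keeps it
fast; redundant collections (e.g. virus strains) clear the threshold and
gain multi-fold reductions.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import zstandard as zstd

from .errors import ArchiveError, CorruptMetadataError

__all__ = [
    "BackendProfile",
    "ProbeDecision",
    "DEFAULT_PROFILE",
    "PROBE_THRESHOLD",
    "PROBE_MIN_PACKED",
    "compress_stream",
    "decompress_stream",
    "probe_dna",
    "decide_from_sizes",
]

#: inclusive ratio (packed size / backend size) required to enable the
#: DNA backend for the whole archive
PROBE_THRESHOLD = 1.25

#: minimum packed-DNA bytes accumulated before the probe runs; DNA-poor
#: early blocks are pooled until this is reached or the input ends
PROBE_MIN_PACKED = 4096


@dataclass(frozen=True)
class BackendProfile:
    """zstd parameters: level 1, long-distance matching, 4 MiB window."""

    level: int = 1
    long_matching: bool = True
    window_log: int = 22


DEFAULT_PROFILE = BackendProfile()


@dataclass(frozen=True)
class ProbeDecision:
    """Outcome of the one-time DNA probe.

    ``probe_ratio`` is packed size / backend-compressed size, or None if
    the probe never ran (no packed DNA reached the minimum).
    """

    dna_backend: bool
    probe_ratio: float | None = None


@lru_cache(maxsize=8)
def _compressor(profile: BackendProfile) -> zstd.ZstdCompressor:
    params = zstd.ZstdCompressionParameters(
        compression_level=profile.level,
        enable_ldm=profile.long_matching,
        window_log=profile.window_log,
    )
    return zstd.ZstdCompressor(compression_params=params)


def compress_stream(data: bytes, profile: BackendProfile = DEFAULT_PROFILE) -> bytes:
    """Compress ``data`` into a standard zstd frame (content size recorded)."""
    return _compressor(profile).compress(data)


def decompress_stream(blob: bytes, expected_size: int) -> bytes:
    """Inverse of :func:`compress_stream`; the output size is verified."""
    try:
        out = zstd.ZstdDecompressor().decompress(blob, max_output_size=max(expected_size, 1))
    except zstd.ZstdError as exc:
        raise ArchiveError(f"backend stream corrupt: {exc}") from exc
    if len(out) != expected_size:
        raise CorruptMetadataError(
            f"backend stream decoded to {len(out)} bytes, {expected_size} expected"
        )
    return out


def decide_from_sizes(
    packed_size: int, compressed_size: int, threshold: float = PROBE_THRESHOLD
) -> bool:
    """Probe decision from the two sizes: true iff packed >= threshold * backend.

    The comparison is inclusive — a reduction by exactly the threshold
    factor enables the backend.
    """
    return packed_size >= threshold * compressed_size


def probe_dna(
    packed_first: bytes,
    profile: BackendProfile = DEFAULT_PROFILE,
    threshold: float = PROBE_THRESHOLD,
) -> ProbeDecision:
    """Trial-compress the earliest packed DNA and fix the archive-wide choice.

    Deterministic: the same bytes and profile always yield the same
    decision, which is recorded once in the archive header and applied
    uniformly to every block's DNA stream.
    """
    if not packed_first:
        return ProbeDecision(dna_backend=False, probe_ratio=None)
    compressed = compress_stream(packed_first, profile)
    ratio = len(packed_first) / len(compressed)
    return ProbeDecision(
        dna_backend=decide_from_sizes(len(packed_first), len(compressed), threshold),
        probe_ratio=ratio,
    )
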