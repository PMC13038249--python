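"""Bit-level codecs for the typed sequence streams.

Three codecs, all exactly invertible:

* 2-bit DNA packing — A=0, C=1, G=2, T=3, four symbols per byte, first
  symbol in the least-significant bits.
* case-flag bit packing — one bit per sequence symbol (1 = the original
  byte was lowercase), LSB-first within each byte, zero-padded.
* N-run lengths — an NNN segment stores no payload at all, only its
  length, which the segmenter guarantees to be a positive multiple of 8.

The bit orders are normative for the container format (docs/FORMAT.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CorruptMetadataError, EncodingError

__all__ = [
    "PackedDna",
    "NnnLengths",
    "pack_dna",
    "unpack_dna",
    "pack_bits",
    "unpack_bits",
    "encode_nnn",
    "decode_nnn",
]

_BASE_ORDER = b"ACGT"

# byte value -> 2-bit code, 255 marks an illegal byte
_PACK_LUT = np.full(256, 255, dtype=np.uint8)
for _code, _b in enumerate(_BASE_ORDER):
    _PACK_LUT[_b] = _code

# packed byte -> its four symbols, code j in bits 2j..2j+1
_UNPACK_LUT = np.empty((256, 4), dtype=np.uint8)
for _v in range(256):
    for _j in range(4):
        _UNPACK_LUT[_v, _j] = _BASE_ORDER[(_v >> (2 * _j)) & 3]


@dataclass(frozen=True)
class PackedDna:
    """2-bit packed ACGT payload: ``len(data) == n_symbols / 4``."""

    data: bytes
    n_symbols: int


@dataclass(frozen=True)
class NnnLengths:
    """Run lengths of the N-only segments of a block, in segment order."""

    lengths: tuple[int, ...] = field(default_factory=tuple)


def pack_dna(symbols: bytes) -> PackedDna:
    """Pack an ACGT byte string into 2-bit codes.

    ``symbols`` must have a length divisible by 4 (segment lengths are
    multiples of 8, so whole bytes are always produced) and contain only
    uppercase A/C/G/T; anything else indicates an upstream segmenter bug.
    """
    n = len(symbols)
    if n % 4 != 0:
        raise EncodingError(f"DNA payload length {n} is not a multiple of 4")
    codes = _PACK_LUT[np.frombuffer(symbols, dtype=np.uint8)]
    if codes.size and codes.max() > 3:
        bad = int(np.frombuffer(symbols, dtype=np.uint8)[codes == 255][0])
        raise EncodingError(f"non-ACGT byte 0x{bad:02x} in DNA payload")
    q = codes.reshape(-1, 4)
    packed = q[:, 0] | (q[:, 1] << 2) | (q[:, 2] << 4) | (q[:, 3] << 6)
    return PackedDna(packed.astype(np.uint8).tobytes(), n)


def unpack_dna(packed: PackedDna) -> bytes:
    """Exact inverse of :func:`pack_dna` (table-driven, 4 symbols per byte)."""
    if len(packed.data) * 4 < packed.n_symbols:
        raise CorruptMetadataError(
            f"packed DNA holds {len(packed.data) * 4} symbols, {packed.n_symbols} expected"
        )
    arr = np.frombuffer(packed.data, dtype=np.uint8)
    return _UNPACK_LUT[arr].reshape(-1)[: packed.n_symbols].tobytes()


def pack_bits(flags) -> bytes:
    """Pack a 0/1 sequence into bytes, bit i -> bit (i mod 8) of byte i//8.

    LSB-first; pad bits in the last byte are 0.
    """
    arr = np.asarray(flags, dtype=np.uint8)
    return np.packbits(arr, bitorder="little").tobytes()


def unpack_bits(data: bytes, n_bits: int) -> np.ndarray:
    """Inverse of :func:`pack_bits`; returns a uint8 0/1 array of length n_bits."""
    if n_bits < 0 or n_bits > 8 * len(data):
        raise CorruptMetadataError(
            f"cannot read {n_bits} bits from {len(data)} flag bytes"
        )
    return np.unpackbits(
        np.frombuffer(data, dtype=np.uint8), count=n_bits, bitorder="little"
    )


def encode_nnn(segments) -> NnnLengths:
    """Collect the lengths of the NNN segments; no payload bytes are stored."""
    from .segmenter import SegmentType  # local import to avoid a cycle

    out = []
    for seg in segments:
        if seg.type is SegmentType.NNN:
            _check_nnn_length(seg.length)
            out.append(seg.length)
    return NnnLengths(tuple(out))


def decode_nnn(lengths, k: int) -> bytes:
    """Re-materialize the k-th N-run as ``lengths[k]`` bytes of 'N'."""
    seq = lengths.lengths if isinstance(lengths, NnnLengths) else lengths
    n = seq[k]
    _check_nnn_length(n)
    return b"N" * n


def _check_nnn_length(n: int) -> None:
    if n <= 0 or n % 8 != 0:
        raise CorruptMetadataError(f"NNN run length {n} is not a positive multiple of 8")
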