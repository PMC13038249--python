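"""Word-parallel (SWAR) byte classification on 8-byte chunks.

Classifying sequence content byte-by-byte is the hot loop of any FASTA
preprocessor.  These primitives operate on a whole 8-byte chunk at once by
loading it into a single 64-bit integer and using carry-free bit arithmetic
("SIMD within a register").  Both functions have naive per-byte
counterparts, kept here as test oracles.

The per-byte zero detector used below is the exact variant:

    nonzero = ((v & 0x7f..7f) + 0x7f..7f) | v

sets bit 7 of every byte of ``nonzero`` that is non-zero in ``v``, with no
false positives from borrow propagation, so ``~nonzero & 0x80..80`` flags
exactly the zero bytes.
"""

from __future__ import annotations

__all__ = [
    "is_acgt_word",
    "is_acgt_word_naive",
    "find_eol_in_word",
    "find_eol_in_word_naive",
]

_MASK64 = 0xFFFF_FFFF_FFFF_FFFF
_LOW7 = 0x7F7F_7F7F_7F7F_7F7F
_HIGH = 0x8080_8080_8080_8080
_ONES = 0x0101_0101_0101_0101

_EOL = 0x0A
_ACGT_CODES = (0x41, 0x43, 0x47, 0x54)  # 'A', 'C', 'G', 'T'


def _zero_byte_flags(v: int) -> int:
    """Bit 7 of byte i of the result is set iff byte i of ``v`` is zero."""
    nonzero = (((v & _LOW7) + _LOW7) | v) & _MASK64
    return ~nonzero & _HIGH


def is_acgt_word(word: bytes) -> bool:
    """True iff all 8 bytes of ``word`` are uppercase 'A', 'C', 'G' or 'T'.

    Word-parallel: the chunk is tested against each of the four codes with
    an XOR + exact zero-byte detection, and the four per-byte match masks
    are OR-combined; the word is ACGT iff every byte matched some code.
    """
    if len(word) != 8:
        raise ValueError(f"is_acgt_word requires exactly 8 bytes, got {len(word)}")
    v = int.from_bytes(word, "little")
    matched = 0
    for code in _ACGT_CODES:
        matched |= _zero_byte_flags(v ^ (code * _ONES))
    return matched == _HIGH


def is_acgt_word_naive(word: bytes) -> bool:
    """Per-byte oracle for :func:`is_acgt_word`."""
    if len(word) != 8:
        raise ValueError(f"is_acgt_word requires exactly 8 bytes, got {len(word)}")
    return all(b in (0x41, 0x43, 0x47, 0x54) for b in word)


def find_eol_in_word(word: bytes) -> int | None:
    """Smallest index of a 0x0A byte in the 8-byte chunk, or None.

    Classic word-parallel zero-byte search on ``word XOR 0x0A..0A``; the
    least-significant set flag (lowest byte index, as the word is loaded
    little-endian) wins.
    """
    if len(word) != 8:
        raise ValueError(f"find_eol_in_word requires exactly 8 bytes, got {len(word)}")
    flags = _zero_byte_flags(int.from_bytes(word, "little") ^ (_EOL * _ONES))
    if flags == 0:
        return None
    return ((flags & -flags).bit_length() - 1) // 8


def find_eol_in_word_naive(word: bytes) -> int | None:
    """Per-byte oracle for :func:`find_eol_in_word`."""
    if len(word) != 8:
        raise ValueError(f"find_eol_in_word requires exactly 8 bytes, got {len(word)}")
    idx = word.find(b"\n")
    return None if idx < 0 else idx
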