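"""Deterministic synthetic FASTA corpora and adversarial inputs.

Everything the compressor exploits in real data can be dialled in here:
multi-record files, regular and irregular line wrapping, soft-masked
(lowercase) runs, N-runs, IUPAC ambiguity codes, redundant
genome collections (near-identical copies, as in viral strain sets), a
protein alphabet, and arbitrary binary.  Generation is a pure function of
the spec — the same seed always yields the same bytes — so fixtures are
generated at test time rather than stored.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np

from .errors import ValidationError

__all__ = [
    "CorpusSpec",
    "generate_fasta",
    "generate_adversarial",
    "ADVERSARIAL_KINDS",
    "build_manifest",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_AMBIG = np.frombuffer(b"RYKMSWBDHV", dtype=np.uint8)
_AMINO = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)
_EOL = 0x0A


@dataclass(frozen=True)
class CorpusSpec:
    """Recipe for one synthetic FASTA corpus.

    ``softmask_rate`` and ``n_run_rate`` are expected run starts per base;
    run lengths are geometric with the given means.  ``n_copies > 1``
    switches to a redundant collection: one base sequence of
    ``total_bases`` bases, emitted ``n_copies`` times with independent
    substitutions at ``mutation_rate`` per base (``n_records`` is then the
    copy count).  ``header_length`` is a fixed int or an inclusive
    (lo, hi) range for the random description after the record name.
    """

    seed: int = 0
    n_records: int = 1
    header_length: int | tuple[int, int] = (8, 24)
    line_width: int = 60
    width_mode: str = "fixed"  # fixed | per_record | irregular
    total_bases: int = 10_000
    gc_fraction: float = 0.41
    softmask_rate: float = 0.0
    softmask_mean_len: float = 150.0
    n_run_rate: float = 0.0
    n_run_mean_len: float = 100.0
    ambiguity_rate: float = 0.0
    n_copies: int = 1
    mutation_rate: float = 0.0
    alphabet: str = "nucleotide"  # nucleotide | protein
    trailing_newline: bool = True


def _validate(spec: CorpusSpec) -> None:
    if spec.total_bases < 0 or spec.n_records < 0 or spec.n_copies < 1:
        raise ValidationError("sizes and copy counts must be non-negative")
    if spec.total_bases > 0 and spec.n_records == 0 and spec.n_copies == 1:
        raise ValidationError("total_bases > 0 requires at least one record")
    for name in ("gc_fraction", "softmask_rate", "n_run_rate", "ambiguity_rate", "mutation_rate"):
        v = getattr(spec, name)
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"{name} must be in [0, 1], got {v}")
    if spec.line_width < 1:
        raise ValidationError("line width must be >= 1")
    if spec.width_mode not in ("fixed", "per_record", "irregular"):
        raise ValidationError(f"unknown width mode {spec.width_mode!r}")
    if spec.alphabet not in ("nucleotide", "protein"):
        raise ValidationError(f"unknown alphabet {spec.alphabet!r}")
    if spec.alphabet == "protein" and (
        spec.n_run_rate > 0 or spec.ambiguity_rate > 0 or spec.n_copies > 1
    ):
        raise ValidationError("N-runs, ambiguity codes and redundancy are nucleotide-only")
    if isinstance(spec.header_length, tuple):
        lo, hi = spec.header_length
        if lo < 0 or hi < lo:
            raise ValidationError(f"bad header_length range {spec.header_length}")
    elif spec.header_length < 0:
        raise ValidationError("header_length must be non-negative")


def _random_runs(rng, n: int, rate: float, mean_len: float):
    """Start positions and lengths for random runs over an n-base sequence."""
    if n == 0 or rate <= 0.0:
        return np.empty(0, np.intp), np.empty(0, np.intp)
    count = rng.binomial(n, rate)
    starts = rng.integers(0, n, size=count)
    lengths = rng.geometric(min(1.0, 1.0 / max(mean_len, 1.0)), size=count)
    return starts.astype(np.intp), lengths.astype(np.intp)


def _base_sequence(rng, n: int, spec: CorpusSpec) -> np.ndarray:
    if spec.alphabet == "protein":
        return _AMINO[rng.integers(0, _AMINO.size, size=n)]
    gc = spec.gc_fraction
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = _BASES[rng.choice(4, size=n, p=p)]
    starts, lengths = _random_runs(rng, n, spec.n_run_rate, spec.n_run_mean_len)
    for s, ln in zip(starts, lengths):
        seq[s : s + ln] = 0x4E  # 'N'
    if spec.ambiguity_rate > 0:
        pos = np.flatnonzero(rng.random(n) < spec.ambiguity_rate)
        seq[pos] = _AMBIG[rng.integers(0, _AMBIG.size, size=pos.size)]
    return seq


def _softmask(rng, seq: np.ndarray, spec: CorpusSpec) -> np.ndarray:
    starts, lengths = _random_runs(rng, seq.size, spec.softmask_rate, spec.softmask_mean_len)
    if starts.size:
        mask = np.zeros(seq.size, dtype=bool)
        for s, ln in zip(starts, lengths):
            mask[s : s + ln] = True
        upper = (seq >= 0x41) & (seq <= 0x5A)
        seq = seq.copy()
        seq[mask & upper] += 32
    return seq


def _mutate(rng, seq: np.ndarray, rate: float) -> np.ndarray:
    """Substitute bases at ``rate`` per position; every hit changes the byte."""
    if rate <= 0:
        return seq
    out = seq.copy()
    pos = np.flatnonzero(rng.random(seq.size) < rate)
    if pos.size:
        subs = _BASES[rng.integers(0, 4, size=pos.size)]
        clash = subs == out[pos]
        if clash.any():
            # shift clashes to the next base so a mutation always changes the byte
            idx = np.searchsorted(_BASES, out[pos][clash])
            subs[clash] = _BASES[(idx + 1) % 4]
        out[pos] = subs
    return out


def _wrap(rng, seq: np.ndarray, spec: CorpusSpec, width: int) -> np.ndarray:
    n = seq.size
    if n == 0:
        return seq
    if spec.width_mode == "irregular":
        max_lines = n // max(1, width // 2) + 2
        widths = rng.integers(max(1, width // 2), 2 * width + 1, size=max_lines)
        pos = np.cumsum(widths)
        pos = pos[pos < n]
    else:
        pos = np.arange(width, n, width)
    return np.insert(seq, pos, _EOL)


def _header(rng, name: str, spec: CorpusSpec) -> bytes:
    if isinstance(spec.header_length, tuple):
        lo, hi = spec.header_length
        ln = int(rng.integers(lo, hi + 1))
    else:
        ln = spec.header_length
    letters = bytes(rng.integers(97, 123, size=ln)) if ln else b""
    sep = b" " if letters else b""
    return b">" + name.encode() + sep + letters + b"\n"


def generate_fasta(spec: CorpusSpec) -> bytes:
    """Generate a syntactically valid FASTA corpus honoring every spec field."""
    _validate(spec)
    rng = np.random.default_rng(spec.seed)
    parts: list[bytes] = []

    if spec.n_copies > 1:
        base = _base_sequence(rng, spec.total_bases, spec)
        per_record = [None] * spec.n_copies  # placeholder; copies derive from base
        names = [f"copy{i}" for i in range(spec.n_copies)]
    else:
        sizes = [spec.total_bases // spec.n_records] * spec.n_records if spec.n_records else []
        for i in range(spec.total_bases % spec.n_records if spec.n_records else 0):
            sizes[i] += 1
        names = [f"r{i}" for i in range(spec.n_records)]
        per_record = sizes
        base = None

    for i, name in enumerate(names):
        if base is not None:
            seq = _softmask(rng, _mutate(rng, base, spec.mutation_rate), spec)
        else:
            seq = _softmask(rng, _base_sequence(rng, per_record[i], spec), spec)
        width = (
            int(rng.integers(max(1, spec.line_width // 2), 2 * spec.line_width + 1))
            if spec.width_mode == "per_record"
            else spec.line_width
        )
        parts.append(_header(rng, name, spec))
        if seq.size:
            parts.append(_wrap(rng, seq, spec, width).tobytes())
            parts.append(b"\n")
    blob = b"".join(parts)
    if not spec.trailing_newline and blob.endswith(b"\n"):
        blob = blob[:-1]
    return blob


# ---------------------------------------------------------------------------
# adversarial inputs

ADVERSARIAL_KINDS = (
    "empty",
    "no_trailing_eol",
    "header_spanning_block",
    "line_spanning_block",
    "crlf",
    "all_N",
    "all_EOL",
    "binary",
    "giant_header",
    "width_change_mid_sequence",
)


def generate_adversarial(kind: str, block_size: int = 65536) -> bytes:
    """Deterministic pathological inputs, each targeting one parsing rule.

    Block-relative kinds (header/line spanning, giant header) place their
    feature at the boundary implied by ``block_size``.
    """
    if kind == "empty":
        return b""
    if kind == "no_trailing_eol":
        return b">r0 demo\n" + b"ACGTacgtNNNNNNNN" * 40 + b"\nACGTACG"
    if kind == "header_spanning_block":
        # a header line opens 10 bytes before the block boundary
        prefix = b">a\n" + b"ACGT" * ((block_size - 10 - 4) // 4)
        prefix += b"A" * (block_size - 10 - len(prefix) - 1) + b"\n"
        assert len(prefix) == block_size - 10
        return prefix + b">" + b"h" * 80 + b" spans the boundary\n" + b"ACGT" * 24 + b"\n"
    if kind == "line_spanning_block":
        # one sequence line crosses the boundary mid-symbols
        return b">a\n" + b"ACGT" * (block_size // 4 + 64) + b"\n"
    if kind == "crlf":
        lines = [b">r0 dos file\r"] + [b"ACGTACGTACGTACGT\r"] * 50 + [b"ACGTAC\r"]
        return b"\n".join(lines) + b"\n"
    if kind == "all_N":
        body = b"N" * 60
        n_lines = (5 * block_size // 2) // 61
        return b">n\n" + (body + b"\n") * n_lines
    if kind == "all_EOL":
        return b"\n" * (block_size // 2)
    if kind == "binary":
        rng = np.random.default_rng(0xB10B)
        return rng.integers(0, 256, size=block_size + 12345, dtype=np.uint8).tobytes()
    if kind == "giant_header":
        return b">" + b"x" * (block_size + 100) + b"\n" + b"ACGT" * 32 + b"\n"
    if kind == "width_change_mid_sequence":
        rng = np.random.default_rng(7)
        seq1 = _BASES[rng.integers(0, 4, size=600)]
        seq2 = _BASES[rng.integers(0, 4, size=700)]
        w60 = np.insert(seq1, np.arange(60, seq1.size, 60), _EOL).tobytes()
        w70 = np.insert(seq2, np.arange(70, seq2.size, 70), _EOL).tobytes()
        return b">r0 rewrapped\n" + w60 + b"\n" + w70 + b"\n"
    raise ValidationError(f"unknown adversarial kind {kind!r}")


def build_manifest(named_specs: dict[str, CorpusSpec]) -> dict:
    """JSON-ready manifest: each spec's fields plus a digest of its output."""
    manifest = {}
    for name, spec in named_specs.items():
        blob = generate_fasta(spec)
        manifest[name] = {
            "spec": asdict(spec),
            "bytes": len(blob),
            "sha256": hashlib.sha256(blob).hexdigest(),
        }
    # round-trip through JSON so the manifest is serializable by construction
    return json.loads(json.dumps(manifest))
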