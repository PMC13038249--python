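"""Block parsing: layout, segmentation, case flags, and the round-trip law."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fapack.segmenter import (
    BoundaryContext,
    LayoutRecord,
    ParsedBlock,
    RawBlock,
    RecordKind,
    Segment,
    SegmentType,
    classify_segments,
    detect_line_length,
    extract_case_flags,
    parse_block,
    scan_boundary_context,
    unparse_block,
)
from fapack.synthgen import ADVERSARIAL_KINDS, CorpusSpec, generate_adversarial, generate_fasta

CTX0 = BoundaryContext()


def parse_rt(data: bytes, ctx: BoundaryContext = CTX0) -> ParsedBlock:
    parsed = parse_block(RawBlock(0, data), ctx)
    assert unparse_block(parsed) == data
    return parsed


def record_shapes(parsed):
    return [
        (r.kind.name, r.byte_length)
        if r.kind is RecordKind.RAW
        else (r.kind.name, r.n_symbols, r.first_span, r.n_eols_removed)
        for r in parsed.records
    ]


class TestBoundaryContext:
    @pytest.mark.parametrize(
        "tail,in_header",
        [
            (b">chr1 some description", True),
            (b">chr1\nACGTACGT", False),
            (b"ACGTACGT", False),
            (b"", False),
        ],
    )
    def test_scan(self, tail, in_header):
        assert scan_boundary_context(tail).starts_in_header is in_header

    def test_line_start_detection(self):
        assert scan_boundary_context(b"").at_line_start
        assert scan_boundary_context(b"ACGT\n").at_line_start
        assert not scan_boundary_context(b"ACGT").at_line_start


class TestDetectLineLength:
    @pytest.mark.parametrize(
        "block,start,expected",
        [
            (b"ACGT\nACGT\nAC\n", 0, 4),
            (b"ACGTACGT", 0, 0),
            (b"GT\nACGT\nACGT\n", 0, 4),  # mid-line start: second gap defines L
            (b"ACGTA\n", 0, 5),  # sole EOL
            (b"ACGT\n>x\nACGT", 0, 4),  # next line is a header, not sequence
        ],
    )
    def test_examples(self, block, start, expected):
        assert detect_line_length(block, start) == expected


class TestCaseFlags:
    @pytest.mark.parametrize(
        "symbols,upper,flags",
        [
            (b"acgTN", b"ACGTN", [1, 1, 1, 0, 0]),
            (b"ACGT", b"ACGT", [0, 0, 0, 0]),
            (b"nnnn", b"NNNN", [1, 1, 1, 1]),
            (b"\x00a0Z", b"\x00A0Z", [0, 1, 0, 0]),
        ],
    )
    def test_examples(self, symbols, upper, flags):
        u, f = extract_case_flags(symbols)
        assert u == upper
        assert list(f) == flags


class TestClassifySegments:
    @pytest.mark.parametrize(
        "symbols,expected",
        [
            (b"A" * 16 + b"N" * 16, [("DNA", 16), ("NNN", 16)]),
            (b"A" * 13, [("DNA", 8), ("MIX", 5)]),
            (b"ACGTRYKM", [("MIX", 8)]),
            (b"", []),
            (b"N" * 7, [("MIX", 7)]),
            (b"ACGT" * 2 + b"RY" + b"N" * 8 + b"ACG", [("DNA", 8), ("MIX", 2 + 8 + 3)]),
        ],
    )
    def test_examples(self, symbols, expected):
        assert [(s.type.name, s.length) for s in classify_segments(symbols)] == expected

    def test_alignment_is_global(self):
        # a run broken off the 8-byte grid falls into MIX word-wise
        segs = classify_segments(b"NNNN" + b"A" * 12)
        assert [(s.type.name, s.length) for s in segs] == [("MIX", 8), ("DNA", 8)]


class TestParseBlock:
    def test_regular_record(self):
        parsed = parse_rt(b">s\nACGTACGT\nACGTACGT\n")
        assert record_shapes(parsed) == [("RAW", 3), ("SEQ", 16, 8, 2)]
        assert [(s.type.name, s.length) for s in parsed.segments] == [("DNA", 16)]
        assert parsed.line_length == 8
        assert parsed.raw_payload == b">s\n"
        assert parsed.dna_payload == b"ACGTACGTACGTACGT"

    def test_non_fasta_bytes(self):
        data = bytes(b % 256 for b in range(256) if b not in (0x0A, 0x3E)) * 2
        parsed = parse_rt(data)
        assert record_shapes(parsed) == [("SEQ", len(data), 0, 0)]
        assert [(s.type.name, s.length) for s in parsed.segments] == [("MIX", len(data))]

    def test_single_short_line(self):
        parsed = parse_rt(b">s\nACGTA\n")
        assert record_shapes(parsed) == [("RAW", 3), ("SEQ", 5, 5, 1)]
        assert [(s.type.name, s.length) for s in parsed.segments] == [("MIX", 5)]

    def test_starts_in_header_context(self):
        ctx = BoundaryContext(starts_in_header=True, at_line_start=False)
        parsed = parse_rt(b"tail of header\nACGTACGT\n", ctx)
        assert parsed.records[0] == LayoutRecord(RecordKind.RAW, byte_length=15)

    def test_mid_line_start_keeps_eol_phase(self):
        # block begins mid-line: first span shorter than the width
        parsed = parse_rt(b"GT\nACGTACGT\nACGTACGT\n", BoundaryContext(at_line_start=False))
        assert record_shapes(parsed) == [("SEQ", 18, 2, 3)]
        assert parsed.line_length == 8

    def test_inconsistent_suffix_goes_raw(self):
        # wrap width changes 4 -> 3: the non-conforming EOL lands in RAW
        parsed = parse_rt(b">s\nACGT\nACGT\nACG\nACG\n")
        kinds = [r.kind.name for r in parsed.records]
        assert kinds.count("RAW") >= 2  # header plus at least one verbatim EOL

    def test_case_preserved_through_roundtrip(self):
        parse_rt(b">s\nacgtACGTnnnnNNNN\nacgtacgtACGTACGT\n")

    def test_lowercase_n_runs_flagged(self):
        parsed = parse_rt(b">s\n" + b"n" * 16 + b"\n")
        assert [(s.type.name, s.length) for s in parsed.segments] == [("NNN", 16)]
        assert parsed.case_flags.sum() == 16

    def test_header_without_trailing_eol(self):
        parsed = parse_rt(b">s no newline at all")
        assert record_shapes(parsed) == [("RAW", 20)]

    def test_gt_mid_line_is_sequence(self):
        parsed = parse_rt(b">s\nAC>T\n")
        assert record_shapes(parsed)[0] == ("RAW", 3)
        assert parsed.records[1].kind is RecordKind.SEQ

    def test_conservation_invariant(self):
        for data in [
            b">s\nACGT\nAC\n>t\nNNNNNNNN\n",
            generate_adversarial("binary")[:5000],
            generate_fasta(CorpusSpec(seed=3, width_mode="irregular")),
        ]:
            parsed = parse_rt(data)
            total = sum(
                r.byte_length if r.kind is RecordKind.RAW else r.n_symbols + r.n_eols_removed
                for r in parsed.records
            )
            assert total == len(data)

    def test_segment_mod8_invariant(self):
        parsed = parse_rt(generate_fasta(CorpusSpec(seed=8, n_run_rate=0.001, softmask_rate=0.001)))
        for seg in parsed.segments:
            if seg.type in (SegmentType.DNA, SegmentType.NNN):
                assert seg.length % 8 == 0
        assert all(c in b"ACGT" for c in parsed.dna_payload)


@given(st.binary(min_size=0, max_size=4096))
@settings(max_examples=200, derandomize=True)
def test_roundtrip_arbitrary_bytes(data):
    for ctx in (
        CTX0,
        BoundaryContext(at_line_start=False),
        BoundaryContext(starts_in_header=True, at_line_start=False),
    ):
        if data:
            parse_rt(data, ctx)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=50, derandomize=True)
def test_roundtrip_synthetic_fasta(seed):
    rng = np.random.default_rng(seed)
    spec = CorpusSpec(
        seed=seed,
        n_records=int(rng.integers(1, 4)),
        total_bases=int(rng.integers(0, 3000)),
        line_width=int(rng.integers(10, 100)),
        softmask_rate=float(rng.choice([0.0, 0.002])),
        n_run_rate=float(rng.choice([0.0, 0.001])),
        ambiguity_rate=float(rng.choice([0.0, 0.01])),
        trailing_newline=bool(rng.integers(0, 2)),
    )
    data = generate_fasta(spec)
    if data:
        parse_rt(data)


@pytest.mark.parametrize("kind", [k for k in ADVERSARIAL_KINDS if k != "empty"])
def test_roundtrip_adversarial(kind):
    parse_rt(generate_adversarial(kind, 65536))
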