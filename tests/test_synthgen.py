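"""The synthetic corpus generator: determinism, statistics, adversarial shapes."""

import numpy as np
import pytest

from fapack.errors import ValidationError
from fapack.segmenter import BoundaryContext, RawBlock, RecordKind, parse_block
from fapack.synthgen import (
    ADVERSARIAL_KINDS,
    CorpusSpec,
    build_manifest,
    generate_adversarial,
    generate_fasta,
)


class TestDeterminism:
    def test_same_seed_same_bytes(self):
        spec = CorpusSpec(seed=123, softmask_rate=0.001, n_run_rate=0.001)
        assert generate_fasta(spec) == generate_fasta(spec)

    def test_different_seed_different_bytes(self):
        assert generate_fasta(CorpusSpec(seed=1)) != generate_fasta(CorpusSpec(seed=2))

    def test_adversarial_deterministic(self):
        for kind in ADVERSARIAL_KINDS:
            assert generate_adversarial(kind) == generate_adversarial(kind)


class TestStructure:
    def test_header_only_record(self):
        blob = generate_fasta(CorpusSpec(seed=0, n_records=1, total_bases=0))
        assert blob.startswith(b">r0")
        assert blob.endswith(b"\n")
        assert blob.count(b"\n") == 1

    def test_record_count(self):
        blob = generate_fasta(CorpusSpec(seed=1, n_records=7, total_bases=7000))
        assert blob.count(b">") == 7

    def test_line_width_honored(self):
        blob = generate_fasta(CorpusSpec(seed=2, n_records=1, total_bases=1000, line_width=50))
        lines = blob.split(b"\n")
        assert all(len(ln) == 50 for ln in lines[1:-2])

    def test_no_trailing_newline(self):
        blob = generate_fasta(CorpusSpec(seed=3, trailing_newline=False))
        assert not blob.endswith(b"\n")

    def test_protein_alphabet(self):
        blob = generate_fasta(CorpusSpec(seed=4, alphabet="protein", total_bases=2000))
        body = b"".join(blob.split(b"\n")[1:])
        assert set(body) <= set(b"ACDEFGHIKLMNPQRSTVWY")


class TestValidation:
    def test_rejects_bases_without_records(self):
        with pytest.raises(ValidationError):
            generate_fasta(CorpusSpec(n_records=0, total_bases=100))

    def test_rejects_bad_rates(self):
        with pytest.raises(ValidationError):
            generate_fasta(CorpusSpec(gc_fraction=1.5))

    def test_rejects_protein_with_n_runs(self):
        with pytest.raises(ValidationError):
            generate_fasta(CorpusSpec(alphabet="protein", n_run_rate=0.01))

    def test_rejects_unknown_kind(self):
        with pytest.raises(ValidationError):
            generate_adversarial("nonsense")


class TestRedundancy:
    def test_copy_mismatch_counts_binomial(self):
        n, rate, copies = 20_000, 0.001, 30
        spec = CorpusSpec(seed=9, n_copies=copies, total_bases=n, mutation_rate=rate)
        blob = generate_fasta(spec)
        seqs = []
        for chunk in blob.split(b">")[1:]:
            lines = chunk.split(b"\n")
            seqs.append(b"".join(lines[1:]))
        assert len(seqs) == copies
        base = np.frombuffer(seqs[0], np.uint8)
        mismatches = [
            int((np.frombuffer(s, np.uint8) != base).sum()) for s in seqs[1:]
        ]
        # each copy differs from copy 0 at ~2*n*rate positions (both mutated)
        mean = np.mean(mismatches)
        expect = 2 * n * rate * (1 - rate)
        assert abs(mean - expect) < 6 * np.sqrt(expect)


class TestStatistics:
    def test_gc_fraction_within_3_sigma(self):
        n = 500_000
        gc = 0.6
        blob = generate_fasta(CorpusSpec(seed=11, total_bases=n, gc_fraction=gc))
        body = np.frombuffer(b"".join(blob.split(b"\n")[1:]), np.uint8)
        observed = ((body == ord("G")) | (body == ord("C"))).sum() / body.size
        sigma = np.sqrt(gc * (1 - gc) / n)
        assert abs(observed - gc) < 3 * sigma

    def test_run_length_means(self):
        n = 2_000_000
        spec = CorpusSpec(
            seed=12, total_bases=n, n_run_rate=0.01, n_run_mean_len=8.0, line_width=10**9
        )
        blob = generate_fasta(spec)
        body = np.frombuffer(blob.split(b"\n")[1], np.uint8)
        is_n = (body == ord("N")).astype(np.int8)
        d = np.diff(np.concatenate(([0], is_n, [0])))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        lengths = ends - starts
        assert lengths.size >= 10_000
        # overlapping runs shorten the observed mean a little; 10% tolerance
        assert abs(lengths.mean() - 8.0) / 8.0 < 0.10


class TestAdversarialShapes:
    def test_empty(self):
        assert generate_adversarial("empty") == b""

    def test_header_spans_boundary(self):
        bs = 65536
        blob = generate_adversarial("header_spanning_block", bs)
        assert len(blob) > bs
        # the boundary byte lies inside the header line that opens before it
        start = blob.rfind(b">", 0, bs)
        end = blob.find(b"\n", start)
        assert start < bs <= end

    def test_line_spans_boundary(self):
        bs = 65536
        blob = generate_adversarial("line_spanning_block", bs)
        assert b"\n" not in blob[3 : bs + 1]

    def test_giant_header_exceeds_block(self):
        bs = 65536
        blob = generate_adversarial("giant_header", bs)
        assert blob.find(b"\n") > bs

    def test_width_change_routes_suffix_through_raw(self):
        blob = generate_adversarial("width_change_mid_sequence")
        parsed = parse_block(RawBlock(0, blob), BoundaryContext())
        raws = [r for r in parsed.records if r.kind is RecordKind.RAW]
        # header plus the verbatim EOLs of the re-wrapped suffix
        assert len(raws) >= 2
        assert parsed.line_length == 60

    def test_all_eol_and_crlf_shapes(self):
        assert set(generate_adversarial("all_EOL")) == {0x0A}
        assert b"\r\n" in generate_adversarial("crlf")


def test_manifest_is_json_ready():
    manifest = build_manifest({"small": CorpusSpec(seed=1, total_bases=100)})
    entry = manifest["small"]
    assert entry["spec"]["seed"] == 1
    assert len(entry["sha256"]) == 64
    assert entry["bytes"] > 100
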