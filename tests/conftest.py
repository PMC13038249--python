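import io

import pytest

from fapack.pipeline import PipelineConfig, compress_file, decompress_file


def roundtrip(data: bytes, config: PipelineConfig | None = None) -> tuple[bytes, object]:
    """Compress + decompress in memory; assert bit-exact recovery.

    Returns (archive bytes, compression summary).
    """
    arc = io.BytesIO()
    summary = compress_file(io.BytesIO(data), arc, config)
    arc.seek(0)
    out = io.BytesIO()
    decompress_file(arc, out)
    assert out.getvalue() == data, (
        f"round-trip mismatch: {len(data)} bytes in, {len(out.getvalue())} out"
    )
    return arc.getvalue(), summary


@pytest.fixture
def rt():
    return roundtrip
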