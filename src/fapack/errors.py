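"""Exception hierarchy for archive reading/writing and stream codecs."""


class FapackError(Exception):
    """Base class for all fapack errors."""


class EncodingError(FapackError):
    """A stream encoder received input violating its contract.

    Raised e.g. when the DNA packer sees a non-ACGT byte; this signals a
    segmenter bug rather than bad user input.
    """


class ArchiveError(FapackError):
    """Base class for errors while reading an archive."""


class FormatError(ArchiveError):
    """The input is not a fapack archive (bad magic)."""


class UnsupportedVersionError(ArchiveError):
    """The archive declares a format version this build cannot read."""


class TruncationError(ArchiveError):
    """The archive ends in the middle of a structure."""

    def __init__(self, message: str, block_index: int | None = None):
        super().__init__(message)
        self.block_index = block_index


class ChecksumError(ArchiveError):
    """A per-block CRC32 does not match the decoded bytes."""

    def __init__(self, message: str, block_index: int | None = None):
        super().__init__(message)
        self.block_index = block_index


class CorruptMetadataError(ArchiveError):
    """Block metadata is structurally inconsistent with its payloads."""

    def __init__(self, message: str, block_index: int | None = None):
        super().__init__(message)
        self.block_index = block_index


class ValidationError(FapackError, ValueError):
    """Invalid configuration or generator specification."""
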