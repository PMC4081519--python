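"""Exception hierarchy shared across the pipeline stages."""


class RgkScanError(Exception):
    """Base class for all package errors."""


class UsageError(RgkScanError, ValueError):
    """A caller violated a documented precondition."""


class FastaParseError(RgkScanError):
    """Malformed FASTA input (bad header, empty sequence, duplicate id)."""


class AlignmentFormatError(RgkScanError):
    """Alignment rows of unequal length or an unknown format token."""


class PatternSyntaxError(RgkScanError):
    """Invalid position-class pattern text.

    Carries ``offset``, the 0-based position in the source text where
    parsing failed.
    """

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


class NoDomainError(RgkScanError):
    """G-domain extraction failed; ``missing`` names the absent motif(s)."""

    def __init__(self, record_id: str, missing: list[str]):
        super().__init__(
            f"no G-domain in {record_id!r}: missing motif(s) {', '.join(missing)}"
        )
        self.record_id = record_id
        self.missing = missing


class DegenerateNullError(RgkScanError):
    """The empirical null distribution has zero spread."""


class UndefinedResultError(RgkScanError):
    """A statistic is undefined for the given input (e.g. no co-aligned columns)."""
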