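"""Exception hierarchy for spliceratio."""


class SpliceRatioError(Exception):
    """Base class for all package-specific errors."""


class GFF3ParseError(SpliceRatioError):
    """A GFF3 record could not be parsed.

    Carries the 1-based line number of the offending record when known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class GenomeLengthError(SpliceRatioError):
    """No sequence length could be derived for a sequence bearing features."""


class UndefinedASRError(SpliceRatioError):
    """The splicing ratio is undefined (no coding positions).

    Distinct from an ASR of exactly 1, which means coding DNA exists but
    no nucleotide is reused by a second isoform.
    """


class OracleSizeError(SpliceRatioError):
    """The dense co-occurrence matrix was requested for too large an input.

    The matrix construction is quadratic in the number of gene positions and
    exists as a small-instance oracle; use the interval-based genome-wide
    computation for real annotations.
    """
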