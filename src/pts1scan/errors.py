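"""Exception hierarchy shared across the pipeline.

Every error that reflects bad *input data* (rather than a programming
mistake) derives from :class:`Pts1ScanError` so callers can catch the
whole family at a pipeline boundary.
"""


class Pts1ScanError(Exception):
    """Base class for all data-level errors raised by this package."""


class TranscriptValidationError(Pts1ScanError):
    """A transcript record violates a structural invariant.

    Carries ``transcript_id`` so batch loaders can report which record
    failed without parsing the message.
    """

    def __init__(self, transcript_id: str, message: str):
        self.transcript_id = transcript_id
        super().__init__(f"{transcript_id}: {message}")


class UnknownChromosomeError(Pts1ScanError):
    """A transcript references a chromosome absent from the genome."""

    def __init__(self, transcript_id: str, chromosome: str):
        self.transcript_id = transcript_id
        self.chromosome = chromosome
        super().__init__(
            f"transcript {transcript_id} references chromosome "
            f"{chromosome!r} not present in the genome"
        )


class UnsupportedTranscriptError(Pts1ScanError):
    """Transcript cannot be analysed (e.g. protein shorter than 3 aa)."""


class ReferenceMismatchError(Pts1ScanError):
    """A variant's REF base disagrees with the genome sequence."""


class VcfParseError(Pts1ScanError):
    """A VCF record could not be normalised; carries the record context."""


class MatrixFormatError(Pts1ScanError):
    """A scoring-matrix file violates the strict TSV layout."""


class SequenceError(Pts1ScanError):
    """A protein or nucleotide sequence contains unsupported characters
    or has the wrong length for the requested operation."""


class CorrelationError(Pts1ScanError):
    """Correlation undefined (too few points or zero variance)."""


class ConfigError(Pts1ScanError):
    """A simulation or run configuration is infeasible."""
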