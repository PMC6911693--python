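"""Exception hierarchy."""


class PseuditsError(Exception):
    """Base class for all package errors."""


class FastaFormatError(PseuditsError):
    """Malformed or empty FASTA input, or disallowed residue characters."""


class AlignmentError(PseuditsError):
    """Invalid alignment input (empty/gapped sequences, <2 records)."""


class AnnotationError(PseuditsError):
    """ITS region boundaries could not be transferred."""


class SaturationError(PseuditsError):
    """K2P distance undefined (log argument <= 0)."""


class ScanError(PseuditsError):
    """Recombination scan precondition violated."""


class ConcordanceError(PseuditsError):
    """Connection-pattern / category classification input invalid."""


class PipelineError(PseuditsError):
    """Pipeline stage failure; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
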