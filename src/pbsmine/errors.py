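"""Exception hierarchy shared across the pipeline.

All pipeline-raised errors derive from :class:`PBSError` so CLI entry points
can distinguish user/input problems (exit code 1) from genuine bugs (exit 2).
"""


class PBSError(Exception):
    """Base class for all errors raised by pbsmine."""


class FormatError(PBSError):
    """A file violates its declared format (FASTA/GFF3/TSV)."""


class ValidationError(PBSError):
    """Structurally valid input fails a domain invariant."""


class SpecError(PBSError):
    """A synthetic-strain specification is internally inconsistent."""


class ClassificationError(PBSError):
    """A sequence cannot be classified and guessing is not allowed."""
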