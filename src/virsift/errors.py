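"""Exception hierarchy for virsift.

All validation failures raise a subclass of :class:`VirsiftError`, so the CLI
can map any domain error onto a single validation exit code.
"""


class VirsiftError(Exception):
    """Base class for every error raised by virsift."""


class FormatError(VirsiftError):
    """A file violates the syntax of its declared format (FASTA/FASTQ/SAM/GFF3)."""


class ConsistencyError(VirsiftError):
    """Two inputs that must agree do not (e.g. SAM header vs. reference lengths)."""


class SpecError(VirsiftError):
    """A generator or parameter specification is internally impossible."""


class InputError(VirsiftError):
    """A function argument is outside its documented domain."""


class CoordinateError(InputError):
    """A genomic span violates a coordinate constraint (e.g. not codon-sized)."""


class StructureError(VirsiftError):
    """A genome annotation is structurally invalid (e.g. overlapping cistrons)."""


class CompositionError(VirsiftError):
    """Base composition is undefined for the given sequence (e.g. all N)."""


class DegenerateTestError(VirsiftError):
    """A statistical test cannot be computed (too few pairs or zero variance)."""


class StageError(VirsiftError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
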