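"""Exception taxonomy shared across the package.

The CLI maps these onto exit codes: ConfigError -> 2, InputFormatError -> 3,
StageError -> 4.
"""


class RegulonKitError(Exception):
    """Base class for all package errors."""


class ConfigError(RegulonKitError):
    """Invalid or incomplete run/simulation configuration."""


class InputFormatError(RegulonKitError):
    """A malformed input file (BED/GFF3/FASTA/TSV)."""


class AnnotationError(RegulonKitError):
    """Inconsistent genome annotation (missing chromosome, bad span...)."""


class StageError(RegulonKitError):
    """A pipeline stage failed; message names the stage and input."""
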