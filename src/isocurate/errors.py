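"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: ConfigError -> 2, FormatError -> 3,
InvariantError -> 4.
"""


class IsocurateError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(IsocurateError):
    """Invalid run configuration (missing files, bad parameter values)."""


class FormatError(IsocurateError):
    """Malformed input file (BED/GTF/FASTA/junction records)."""


class InvariantError(IsocurateError):
    """An internal data-model invariant was violated."""
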