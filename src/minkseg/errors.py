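"""Exception hierarchy shared across the package.

``ValidationError`` covers bad user input (malformed files, inconsistent
configuration); ``PipelineError`` covers failures at run time. The CLI maps
these to distinct exit codes.
"""


class MinksegError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MinksegError):
    """Invalid input data or configuration."""


class PipelineError(MinksegError):
    """Runtime failure while executing a pipeline stage."""


class UnsupportedVariantError(MinksegError):
    """Variant class the annotator does not handle (indels, MNVs)."""
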