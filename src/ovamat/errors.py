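"""Exception hierarchy shared by all stages.

Validation errors (bad parameters, malformed files) and computation errors
(degenerate inputs discovered mid-run) are distinguished so the CLI can map
them to distinct exit codes.
"""


class OvamatError(Exception):
    """Base class for all package errors."""


class ParameterError(OvamatError, ValueError):
    """A parameter or input fails validation before any computation runs."""


class RangeError(ParameterError):
    """A requested spectral/spatial range is empty or degenerate."""


class DegenerateSpectrumError(OvamatError):
    """A spectrum cannot be processed (e.g. non-positive area: dead pixel)."""


class FormatError(OvamatError, ValueError):
    """A file does not conform to the expected on-disk layout."""
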