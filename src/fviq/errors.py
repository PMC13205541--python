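"""Exception hierarchy shared across the package.

Each subclass carries the CLI exit code used when the error escapes to the
command line (0 success, 2 validation, 3 I/O, 4 configuration).
"""


class FviqError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(FviqError):
    """Invalid domain data: bad polygon, mismatched views, out-of-range item."""

    exit_code = 2


class InputError(FviqError):
    """Unreadable or missing input file."""

    exit_code = 3


class ConfigurationError(FviqError):
    """Invalid settings: unknown filter name, threshold outside [0, 1], ..."""

    exit_code = 4


class DegenerateRoiError(ValidationError):
    """ROI with no intensity variation; automatic thresholding is undefined.

    Raised instead of silently returning a threshold so the operator knows a
    manual override is required for that patch.
    """


class GenerationError(FviqError):
    """Synthetic-data generator could not satisfy the requested geometry."""

    exit_code = 2
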