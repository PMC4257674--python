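"""Exception hierarchy.

Everything user-facing derives from :class:`ClemdockError`; the CLI maps
validation failures to exit status 2 and anything else to 1.
"""


class ClemdockError(Exception):
    """Base class for all package errors."""


class ValidationError(ClemdockError, ValueError):
    """Invalid input that a user can fix (bad table, bad parameters)."""


class FormatError(ValidationError):
    """Malformed landmark/fiber/scheme file."""


class RangeError(ValidationError):
    """Index or coordinate outside the valid domain."""


class PairingError(ValidationError):
    """Landmark pairing cannot be built or is too small for the fit."""


class DegenerateConfigurationError(ValidationError):
    """Landmark configuration is collinear/coplanar/coincident for the
    requested transform family."""


class CoverageError(ValidationError):
    """Sectioning scheme does not reach the requested depth window."""


class GenerationError(ClemdockError):
    """Synthetic tissue could not be generated under the given constraints."""
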