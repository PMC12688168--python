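"""Exception hierarchy.

Validation errors signal malformed user input (exit code 1 at the CLI);
everything else propagates as a runtime failure (exit code 2).
"""


class ChemoresistomeError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ChemoresistomeError):
    """Input data violates a structural invariant (duplicate ids, bad enum, ...)."""


class ConfigurationError(ChemoresistomeError):
    """A configuration object is internally inconsistent."""
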