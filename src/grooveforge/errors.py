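"""Exception hierarchy.

``InputError`` and its subclasses map to exit code 2 in the CLI; everything
else is a programming or configuration fault.
"""


class GrooveforgeError(Exception):
    """Base class for all package errors."""


class InputError(GrooveforgeError):
    """Invalid user-supplied data (bad sequence, malformed file, bad trace)."""


class UnknownResidueError(InputError):
    """A letter that is not a standard one-letter amino-acid code."""


class MutationConflictError(InputError):
    """Two mutations target the same position."""


class MutationConsistencyError(InputError):
    """A mutation's from-residue does not match the reference sequence."""


class ScoreLookupError(InputError):
    """A sequence is missing from a score table."""


class ConfigurationError(GrooveforgeError):
    """Inconsistent parameters (bad face indices, unstable time step, ...)."""


class TraceFormatError(InputError):
    """A pulling trace violates its format or protocol contract."""
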