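"""Exception hierarchy.

All package errors derive from :class:`LZRepError` so callers (and the CLI)
can separate data problems from programming errors.
"""


class LZRepError(Exception):
    """Base class for all lzrep errors."""


class AlphabetError(LZRepError):
    """A sequence contains characters outside the declared alphabet."""


class SchemeError(LZRepError):
    """A node-encoding scheme is invalid for the given alphabet or operation."""


class GenerationError(LZRepError):
    """Stochastic sequence generation failed (cycle risk or exhausted restarts)."""


class ConvergenceError(LZRepError):
    """An iterative solver did not reach its tolerance."""


class SerializationError(LZRepError):
    """A graph document on disk is unreadable or from an incompatible schema."""


class RepertoireIOError(LZRepError):
    """A repertoire file is missing required columns or yields no valid rows."""
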