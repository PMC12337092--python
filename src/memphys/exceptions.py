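"""Exception hierarchy.

Everything derives from :class:`MemphysError` so callers can catch the
package's own failures separately from programming errors.  Domain violations
(negative volumes, angles past 90 degrees, ...) raise :class:`DomainError`,
which is also a ``ValueError``.
"""


class MemphysError(Exception):
    """Base class for all package errors."""


class DomainError(MemphysError, ValueError):
    """Input outside the physical domain of an operation."""


class SchemaError(MemphysError, ValueError):
    """Delimited-text table does not match the expected schema."""


class UnidentifiableError(MemphysError):
    """The requested parameter cannot be identified from the data
    (e.g. zero osmotic gradient throughout a trajectory)."""


class ConvergenceError(MemphysError):
    """An iterative fit failed to converge; carries the last iterate."""

    def __init__(self, message, last_iterate=None, residual=None):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.residual = residual


class NumericalError(MemphysError):
    """Non-finite state encountered during integration; carries the time."""

    def __init__(self, message, t=None):
        super().__init__(message)
        self.t = t


class AmbiguousPeakError(MemphysError):
    """A single-peak metric was requested on a multi-peak curve."""
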