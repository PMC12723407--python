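"""Exception hierarchy for opmcal.

All toolkit errors derive from :class:`OpmcalError` so callers can catch the
whole family; the leaf classes mirror the distinct failure modes of the
geometry, calibration and fitting code paths.
"""


class OpmcalError(Exception):
    """Base class for all opmcal errors."""


class InvalidArgumentError(OpmcalError, ValueError):
    """An argument violates a precondition (wrong range, shape or count)."""


class DegenerateGeometryError(OpmcalError):
    """A field was requested inside the guard radius of a point source."""


class DeadChannelError(OpmcalError):
    """A channel produced no usable calibration response (|g| ~ 0)."""


class InvalidDesignError(OpmcalError):
    """The calibration design matrix is singular or rank deficient."""


class DegenerateOrientationError(OpmcalError):
    """The gradient design rows span fewer than three dimensions."""


class ProtocolMismatchError(OpmcalError):
    """Recorded data are inconsistent with the stated stimulus protocol."""


class FitFailureError(OpmcalError):
    """Nonlinear dipole fit failed to converge from every start point."""


class UndefinedSNRError(OpmcalError, ZeroDivisionError):
    """Envelope SNR is undefined (zero variance in the rest window)."""


class ParseError(OpmcalError, ValueError):
    """A file does not conform to its schema; message names the field path."""
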