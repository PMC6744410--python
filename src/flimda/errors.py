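"""Exception hierarchy.

Contract violations (bad arguments) are distinguished from empty-result
conditions (valid arguments, nothing to compute) and file-format problems so
callers can branch on them.
"""


class FlimdaError(Exception):
    """Base class for all package errors."""


class ContractError(FlimdaError, ValueError):
    """An argument violates a documented precondition."""


class EmptyResultError(FlimdaError):
    """The inputs were valid but left nothing to operate on (e.g. every
    pixel fell below the photon threshold)."""


class DegenerateReferenceError(FlimdaError):
    """A calibration reference whose mean phasor sits at the origin; no
    rotation/scaling can map it onto the semicircle."""


class FormatError(FlimdaError):
    """A file on disk is inconsistent with its sidecar or truncated. The
    message names the offending field."""


class OptimizationError(FlimdaError):
    """Weight optimization cannot proceed (degenerate training groups)."""
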