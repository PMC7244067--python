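"""Exception hierarchy.

Everything derives from :class:`RBCAgeError` (itself a ``ValueError``) so
callers can catch the package's validation failures with one clause.
"""


class RBCAgeError(ValueError):
    """Base class for all rbcage validation and modelling errors."""


class InvalidParameterError(RBCAgeError):
    """A model or configuration parameter is outside its domain."""


class InvalidMeasurementError(RBCAgeError):
    """A measured quantity (EC, half-life) is outside its physical domain."""


class InvalidModelError(RBCAgeError):
    """A model evaluates to something unusable (e.g. non-positive mean EC)."""


class InsufficientDataError(RBCAgeError):
    """Too few observations for the requested fit."""


class DegenerateDesignError(RBCAgeError):
    """The regression design has no variance in the predictor."""


class NonInvertibleError(RBCAgeError):
    """A calibration with zero slope cannot be inverted."""


class NoSolutionError(RBCAgeError):
    """A root-finding problem has no solution in the admissible bracket."""


class FormatError(RBCAgeError):
    """Malformed tabular input (missing columns, bad rows, unknown units)."""
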