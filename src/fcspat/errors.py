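"""Exception hierarchy for fcspat.

All domain errors derive from :class:`FCSpatError` so callers can catch the
package's failures with a single except clause while still discriminating on
the specific condition.
"""


class FCSpatError(ValueError):
    """Base class for all fcspat domain errors."""


# -- point pattern construction -------------------------------------------

class EmptyInputError(FCSpatError):
    """An operation received zero points (or values) where at least one is required."""


class DuplicatePointsError(FCSpatError):
    """Two coordinates coincide exactly; mapped objects are physical and distinct."""


class OutOfWindowError(FCSpatError):
    """One or more points fall outside the observation window."""


class TooFewPointsError(FCSpatError):
    """A distance-based statistic needs at least two points."""


class GeographicCoordinatesError(FCSpatError):
    """Coordinates look like lon/lat degrees; project to planar meters first."""


# -- Monte-Carlo tests and envelopes --------------------------------------

class BadSimCountError(FCSpatError):
    """Too few Monte-Carlo simulations for a meaningful rank test."""


class BadRankError(FCSpatError):
    """Envelope rank outside 1..n_sim/2."""


class UnknownCorrectionError(FCSpatError):
    """Unrecognized edge-correction name."""


class BadBandwidthError(FCSpatError):
    """Kernel bandwidth must be positive (or the string 'auto')."""


class StatisticMismatchError(FCSpatError):
    """Pattern classification needs an envelope of the pair-correlation function g."""


# -- synthetic generators --------------------------------------------------

class SpacingTooLargeError(FCSpatError):
    """Lattice spacing leaves fewer than 10 points in the window."""


class PackingInfeasibleError(FCSpatError):
    """Requested hard-core packing cannot fit in the window."""


class MaxAttemptsExceededError(FCSpatError):
    """Sequential inhibition gave up before placing all points."""


class BadTruncationError(FCSpatError):
    """Truncation bounds are inverted or degenerate."""


class UnknownRegionError(FCSpatError):
    """Study-fixture region must be one of Giribes, Brandberg, Garub."""


# -- field comparisons -----------------------------------------------------

class NonPositiveError(FCSpatError):
    """Diameters and infiltration times must be strictly positive."""


class EmptyGroupError(FCSpatError):
    """A summary group contains no observations."""


class DivisionByZeroError(FCSpatError):
    """Denominator mean must be positive."""


# -- io --------------------------------------------------------------------

class MissingColumnError(FCSpatError):
    """A named coordinate column is absent from the input table."""


class UnparseableRowError(FCSpatError):
    """A row holds a non-numeric coordinate; the message names the row."""


class ImplausibleExtentError(FCSpatError):
    """Data bounding box is inconsistent with the declared window."""


class WriteFailureError(FCSpatError):
    """A report file could not be written."""
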