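"""Exception hierarchy shared across the toolkit.

Everything derives from :class:`OpsinSpecError` so callers can catch the
package's failures with one clause; most errors are also ``ValueError``
subclasses because they signal invalid inputs.
"""


class OpsinSpecError(Exception):
    """Base class for all opsinspec errors."""


class ParseError(OpsinSpecError, ValueError):
    """A delimited input file could not be parsed (message names the line)."""


class EmptyInputError(ParseError):
    """An input file contained no data rows."""


class GridError(OpsinSpecError, ValueError):
    """Wavelength grids are incompatible (disjoint, out of range, mismatched)."""


class DegenerateInputError(OpsinSpecError, ValueError):
    """Input is formally valid but carries no usable signal (e.g. all zeros)."""


class ParameterError(OpsinSpecError, ValueError):
    """A parameter is outside its documented domain."""


class NoSignalError(OpsinSpecError, ValueError):
    """No positive lobe found inside the fit window."""


class WindowError(OpsinSpecError, ValueError):
    """Fit window is unusable (too few points, rank deficient)."""


class NoPhotochemistryError(OpsinSpecError, ValueError):
    """Light source does not overlap the absorbance of either pigment state."""


class UnassignedPeakError(OpsinSpecError, ValueError):
    """A chromatogram peak above threshold has no species assignment."""


class InsufficientDataError(OpsinSpecError, ValueError):
    """Too few data points for the requested fit."""


class MissingReferenceError(OpsinSpecError, ValueError):
    """A required reference condition (e.g. 'dark') is absent."""


class ConfigError(OpsinSpecError, ValueError):
    """Run configuration failed validation."""
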