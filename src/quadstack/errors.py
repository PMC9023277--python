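"""Exception hierarchy shared across the toolkit.

Input-side problems (bad files, bad argument values, out-of-range requests)
and numeric/geometry failures are kept distinct so the CLI can map them to
different exit codes.
"""


class QuadstackError(Exception):
    """Base class for all toolkit errors."""


class InputError(QuadstackError):
    """Malformed or empty input data (sequences, files, spectra)."""


class ParameterError(QuadstackError):
    """An argument value outside its documented domain."""


class RangeError(QuadstackError):
    """A request outside the range covered by the data (e.g. interpolation)."""


class FitError(QuadstackError):
    """A regression or optimisation that cannot produce a valid result."""


class NumericError(QuadstackError):
    """Singular systems, vanishing integrals and similar numeric failures."""


class GeometryError(QuadstackError):
    """Degenerate geometry (coincident beads, empty models)."""


class BuoyancyError(QuadstackError):
    """Non-positive buoyant mass M(1 - vbar*rho)."""


#: errors caused by what the user handed in
INPUT_ERRORS = (InputError, ParameterError, RangeError)
#: errors arising while computing
NUMERIC_ERRORS = (FitError, NumericError, GeometryError, BuoyancyError)
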