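"""Exception hierarchy used across the package.

``ParameterError`` flags an invalid configuration value (a bad sigma, an even
window, a grid with no cells); ``InputError`` flags invalid data (shape
mismatches, single-class training sets); ``DegenerateInputError`` flags data
that is structurally valid but carries no usable signal (a constant image
handed to Otsu).
"""


class DesertVegError(ValueError):
    """Base class for all package errors."""


class ParameterError(DesertVegError):
    """An algorithm parameter is outside its valid domain."""


class InputError(DesertVegError):
    """Input data violates a precondition (shape, dtype, class content)."""


class DegenerateInputError(InputError):
    """Input data is degenerate for the requested operation."""
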