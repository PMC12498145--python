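"""Exception hierarchy shared across the package."""


class HsfliError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(HsfliError, ValueError):
    """An acquisition or run configuration violates its invariants."""


class FormatError(HsfliError, ValueError):
    """A file is missing required structure or metadata."""


class DegenerateIRFError(HsfliError, ValueError):
    """An instrument response with no signal was supplied."""


class ShapeMismatchError(HsfliError, ValueError):
    """Arrays that must be co-registered have inconsistent shapes."""


class ZeroModulationError(HsfliError, ValueError):
    """A source pattern triplet carries no spatial modulation."""


class UndersamplingError(HsfliError, ValueError):
    """Requested spatial frequency exceeds the pixel-grid Nyquist limit."""


class EmptyRoiError(HsfliError, ValueError):
    """A region-of-interest selection contains no usable pixels."""
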