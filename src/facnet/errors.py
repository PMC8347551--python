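"""Exception types shared across the package."""


class FacNetError(Exception):
    """Base class for package errors."""


class DimensionError(FacNetError):
    """Input spatial size violates a divisibility or positivity constraint."""


class ShapeError(FacNetError):
    """Tensor shapes are inconsistent with an operation's contract."""


class ConfigurationError(FacNetError):
    """A configuration value is out of its valid range."""
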