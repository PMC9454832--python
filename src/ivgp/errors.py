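"""Exception hierarchy for the ivgp pipeline."""


class IvgpError(Exception):
    """Base class for all ivgp errors."""


class FormatError(IvgpError):
    """A file does not conform to the expected tabular dialect."""


class DataError(IvgpError):
    """Structurally valid input with inconsistent content (e.g. duplicate times)."""


class ValidationError(IvgpError):
    """A record violates a declared invariant."""


class ConfigError(IvgpError):
    """Run configuration is missing or inconsistent."""


class FitError(IvgpError):
    """Curve fitting cannot proceed (degenerate data)."""


class SelectionError(IvgpError):
    """Model selection has no converged candidate."""


class RangeError(IvgpError):
    """A requested evaluation point lies outside the observed range."""
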