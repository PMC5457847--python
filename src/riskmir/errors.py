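"""Exception types shared across the pipeline stages."""


class RiskmirError(ValueError):
    """Base class for all riskmir errors."""


class ParseError(RiskmirError):
    """A file did not conform to its declared format."""


class LabelingError(RiskmirError):
    """A sample in an expression matrix has no case/control label."""


class DesignError(RiskmirError):
    """A study design is too small or degenerate for the requested operation."""


class ConfigError(RiskmirError):
    """A configuration value is out of range or infeasible."""
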