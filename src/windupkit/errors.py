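"""Exception hierarchy shared across the pipelines."""


class WindupKitError(Exception):
    """Base class for all package errors."""


class ParameterError(WindupKitError, ValueError):
    """An argument or simulation/config parameter is out of its valid range."""


class FormatError(WindupKitError, ValueError):
    """An input table or trace violates the documented schema."""


class CoverageError(WindupKitError, ValueError):
    """A trace does not cover the time span an operation needs."""


class ShapeError(WindupKitError, ValueError):
    """Array arguments have incompatible shapes or lengths."""


class NormalizationError(WindupKitError, ValueError):
    """dF/F normalisation is undefined (non-positive F0)."""


class SequenceError(WindupKitError, ValueError):
    """An up-down testing sequence violates the method's transition rules."""


class AggregationError(WindupKitError, ValueError):
    """A grouping operation received an empty group."""


class ConfigError(WindupKitError, ValueError):
    """Pipeline configuration is invalid."""
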