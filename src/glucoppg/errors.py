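"""Exception hierarchy shared across the package."""


class GlucoPPGError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(GlucoPPGError, ValueError):
    """An invalid configuration value (ranges, rates, thresholds)."""


class FeatureExtractionError(GlucoPPGError, RuntimeError):
    """A feature block could not be computed for a channel."""


class SolverError(GlucoPPGError, RuntimeError):
    """An optimisation backend failed or reported an unusable status."""


class InsufficientDataError(GlucoPPGError, ValueError):
    """Too few samples, peaks, intervals or rows for the requested operation."""
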