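"""Exception types shared across the package."""


class CycletrackError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CycletrackError, ValueError):
    """A configuration value is missing, non-finite, or out of range."""


class InputError(CycletrackError, ValueError):
    """Input data violates a pipeline contract (e.g. channel frame-count mismatch)."""


class DegenerateProfileError(CycletrackError, ValueError):
    """A concentration/intensity profile is constant and cannot be normalised."""


class InsufficientDataError(CycletrackError, ValueError):
    """Too few observations for the requested statistic."""
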