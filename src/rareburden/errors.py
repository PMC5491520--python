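"""Exception types shared across the pipeline."""


class RareBurdenError(Exception):
    """Base class for package errors."""


class SimulationError(RareBurdenError):
    """Raised when a simulation cannot satisfy its design (e.g. unattainable
    case/control counts under the requested prevalence)."""


class ConfigurationError(RareBurdenError):
    """Raised for invalid or incomplete pipeline configuration, including
    missing reference panels and missing clinically-relevant transcripts."""


class FittingError(RareBurdenError):
    """Raised when a model fit fails (degenerate phenotype, separation)."""
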