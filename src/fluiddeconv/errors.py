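"""Exception hierarchy used across the pipeline."""


class FluidDeconvError(Exception):
    """Base class for package errors."""


class DataError(FluidDeconvError):
    """Malformed or degenerate input data (zero-total sample, no shared genes, ...)."""


class ConfigError(FluidDeconvError):
    """Invalid configuration (unknown keys, thresholds for absent metrics, ...)."""


class DesignError(FluidDeconvError):
    """Rank-deficient / collinear model design."""


class DependencyError(FluidDeconvError):
    """A pipeline step was requested before its prerequisites."""
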